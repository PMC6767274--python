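"""Train the 3D convolutional clip classifier on a toy labeled set.

Generates a balanced set of 20-frame clips (bolus events vs. coughing-style
jitter and head shifts), trains the deeper inception variant with cosine
learning-rate decay, and prints held-out accuracy plus a positive/negative
score pair.
"""

from vfssdet.net import (NetworkConfig, TOY_SCHEDULE, TrainSchedule,
                         build_network, classify_clip, count_parameters,
                         evaluate_accuracy, train)
from vfssdet.synthetic import generate_clip_dataset

train_set = generate_clip_dataset(16, 16, seed=0, frame_size=(48, 48))
held_out = generate_clip_dataset(8, 8, seed=1, frame_size=(48, 48))

cfg = NetworkConfig(variant="proposed", stream="rgb",
                    channel_schedule=dict(TOY_SCHEDULE), input_size=48)
net = build_network(cfg, seed=0)
print(f"built {cfg.variant}/{cfg.stream} with "
      f"{count_parameters(net):,} parameters (toy widths)")

sched = TrainSchedule(total_iterations=250, warmup_iterations=50, seed=0)
losses = train(net, train_set.rgb, train_set.labels, sched)
print(f"cross-entropy {losses[0]:.3f} -> {losses[-1]:.3f} "
      f"over {len(losses)} iterations (lr 0.1, batch 6, cosine decay)")

acc = evaluate_accuracy(net, held_out.rgb, held_out.labels)
pos = held_out.rgb[held_out.labels == 1][0]
neg = held_out.rgb[held_out.labels == 0][0]
print(f"held-out accuracy: {acc:.2f}")
print(f"P(pharyngeal) for an event clip: {classify_clip(net, pos):.2f}; "
      f"for a distractor clip: {classify_clip(net, neg):.2f}")
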