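"""End-to-end orchestration: synthesize, harvest, train, detect, evaluate.

Each stage is importable on its own; ``run_all`` ties them into a
reproducible run directory with a resolved config, NDJSON log, checkpoint
and metrics.  Determinism: every random draw descends from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time

import numpy as np

from . import __version__
from .candidates import harvest_training_clips, label_candidates
from .config import PipelineConfig
from .detect import detect as _detect
from .errors import VfssError
from .evalmetrics import evaluate, miss_rate, temporal_iou
from .net import (NetworkConfig, TrainSchedule, build_network, count_parameters,
                  evaluate_accuracy, save_checkpoint, train)
from .net.model import DEFAULT_SCHEDULE, TOY_SCHEDULE
from .synthetic import Distractor, SynthSpec, default_distractors, generate_video
from .video_io import write_intervals


def _jsonable(obj):
    """Recursively cast numpy scalars so json.dump accepts the payload."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return None if np.isnan(obj) else float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


class JsonlLogger:
    """Newline-delimited JSON event log; silent when no path is given."""

    def __init__(self, path=None, echo=False):
        self.path, self.echo = path, echo
        self._fh = open(path, "a") if path else None

    def log(self, stage, **fields):
        rec = _jsonable({"t": round(time.time(), 3), "stage": stage, **fields})
        if self._fh:
            self._fh.write(json.dumps(rec) + "\n")
            self._fh.flush()
        if self.echo:
            print(json.dumps(rec))

    def close(self):
        if self._fh:
            self._fh.close()


def _video_spec(cfg: PipelineConfig, seed: int, hard_negative: bool,
                rng) -> SynthSpec:
    distractors = default_distractors()
    if hard_negative:
        # a non-swallow recording stretch: above-threshold "coughing" jitter
        # fires the vote stage, providing the classifier's negative examples
        distractors.append(Distractor("oscillation", 5.0, n_windows=2,
                                      window_len=16))
        n_events = 0
    else:
        n_events = int(rng.integers(1, cfg.n_events_max + 1))
    return SynthSpec(
        seed=seed,
        duration_frames=cfg.duration_frames,
        fps=cfg.fps,
        n_events=n_events,
        event_duration_frames=(8, cfg.event_duration_max),
        event_speed_px=(5.0, cfg.event_speed_max),
        distractors=distractors,
        frame_size=(cfg.frame_size, cfg.frame_size),
    )


def make_study(cfg: PipelineConfig, seed: int):
    """Synthesize the train/test video sets for one study replicate."""
    rng = np.random.default_rng(seed)
    train_videos, test_videos = [], []
    n_hard = int(round(cfg.hard_negative_fraction * cfg.n_train_videos))
    for i in range(cfg.n_train_videos):
        sub = int(rng.integers(0, 2**31 - 1))
        train_videos.append(generate_video(_video_spec(cfg, sub, i < n_hard, rng)))
    for _ in range(cfg.n_test_videos):
        sub = int(rng.integers(0, 2**31 - 1))
        test_videos.append(generate_video(_video_spec(cfg, sub, False, rng)))
    return train_videos, test_videos


def _window_label(start, gt_intervals):
    """Label an arbitrary 20-frame training window against the ground truth.

    1 when the window contains the core of an event (>= 60% of its frames),
    0 when it barely touches any event (<= 2 overlapping frames), and None
    for the ambiguous fringe in between, which is not trained on.
    """
    from .video_io import CLIP_LEN

    end = start + CLIP_LEN - 1
    best = 0.0
    best_overlap = 0
    for g in gt_intervals:
        overlap = min(end, g.end_frame) - max(start, g.start_frame) + 1
        if overlap <= 0:
            continue
        best = max(best, overlap / (g.end_frame - g.start_frame + 1))
        best_overlap = max(best_overlap, overlap)
    if best >= 0.6:
        return 1
    if best_overlap <= 2:
        return 0
    return None


def harvest_study(videos, cfg: PipelineConfig, log=None, jitter: int = 5):
    """Candidate stage over a video set.

    Returns (clips, labels, candidates-per-video, event coverage), where
    coverage is the fraction of true events overlapped by >= 1 candidate.
    Besides each candidate window, two temporally jittered copies
    (start +- ``jitter``) are extracted and labeled against the ground truth,
    so the classifier sees events at off-center clip positions — the
    geometry the detection stage's stride produces.
    """
    from .video_io import CLIP_LEN, extract_clip

    clips, labels, per_video = [], [], []
    n_events = n_covered = 0
    for seq, gt in videos:
        cands, _ = harvest_training_clips(
            seq, size=cfg.input_size, streams=("rgb",),
            fth=cfg.fth, vth=cfg.vth, max_candidates=cfg.max_candidates,
            center_fraction=cfg.center_fraction, radius=cfg.radius,
            num_warp=cfg.num_warp, num_iter=cfg.num_iter)
        label_candidates(cands, gt.intervals, min_iou=cfg.iou_th)
        per_video.append(cands)
        for g in gt.intervals:
            n_events += 1
            n_covered += any(
                temporal_iou((c.start_frame, c.end_frame),
                             (g.start_frame, g.end_frame)) > 0
                for c in cands)
        for c in cands:
            clips.append(c.rgb)
            labels.append(1 if c.label == "pharyngeal" else 0)
            for off in (-jitter, jitter):
                s = int(np.clip(c.start_frame + off, 0, len(seq) - CLIP_LEN))
                if s == c.start_frame:
                    continue
                lab = _window_label(s, gt.intervals)
                if lab is None:
                    continue
                clips.append(extract_clip(seq, s, "rgb",
                                          size=cfg.input_size).frames)
                labels.append(lab)
        if not gt.intervals:
            # event-free recording: background windows (static stretches,
            # horizontal head shifts) the vote stage never proposes
            taken = {c.start_frame for c in cands}
            for s in (0, (len(seq) - CLIP_LEN) // 2, len(seq) - CLIP_LEN):
                if s not in taken:
                    clips.append(extract_clip(seq, s, "rgb",
                                              size=cfg.input_size).frames)
                    labels.append(0)
        if log:
            log.log("candidates", video=seq.source_id, n=len(cands),
                    events=len(gt.intervals))
    coverage = n_covered / n_events if n_events else float("nan")
    clips = np.stack(clips).astype(np.float32) if clips else np.empty((0,))
    return clips, np.array(labels, dtype=np.int64), per_video, coverage


def train_study(clips, labels, cfg: PipelineConfig, seed: int):
    """Build and train the configured classifier on harvested clips."""
    schedule = TOY_SCHEDULE if cfg.schedule == "toy" else DEFAULT_SCHEDULE
    net_cfg = NetworkConfig(variant=cfg.variant, stream=cfg.stream,
                            channel_schedule=dict(schedule),
                            input_size=cfg.input_size)
    net = build_network(net_cfg, seed=seed)
    sched = TrainSchedule(total_iterations=cfg.iterations,
                          warmup_iterations=cfg.warmup, initial_lr=cfg.lr,
                          batch_size=cfg.batch_size, seed=seed)
    losses = train(net, clips, labels, sched)
    return net, losses


def detect_study(test_videos, net, cfg: PipelineConfig):
    """Detection pass over the test videos; returns [(dets, gts), ...]."""
    out = []
    for seq, gt in test_videos:
        dets = _detect(seq, net, window=cfg.window, stride=cfg.stride,
                       scoreth=cfg.scoreth, frameth=cfg.frameth, lam=cfg.lam,
                       smooth_width=cfg.smooth_width, size=cfg.input_size)
        out.append((dets, gt.intervals))
    return out


def run_seed(cfg: PipelineConfig, seed: int, log=None):
    """One full study replicate; returns the measured quantities."""
    t0 = time.time()
    train_videos, test_videos = make_study(cfg, seed)
    clips, labels, per_video_cands, coverage = harvest_study(
        train_videos, cfg, log=log)
    if log:
        log.log("harvest", n_clips=len(labels),
                n_pos=int(labels.sum()), coverage=round(coverage, 3),
                dt=round(time.time() - t0, 1))
    t1 = time.time()
    net, losses = train_study(clips, labels, cfg, seed)
    if log:
        log.log("train", iterations=len(losses),
                final_loss=round(float(losses[-1]), 4),
                params=count_parameters(net), dt=round(time.time() - t1, 1))
    t2 = time.time()
    from .synthetic import generate_clip_dataset
    holdout = generate_clip_dataset(20, 20, seed + 1000,
                                    frame_size=(cfg.input_size,) * 2)
    clip_acc = evaluate_accuracy(net, holdout.rgb, holdout.labels)
    per_video = detect_study(test_videos, net, cfg)
    report, matches = evaluate(per_video, iou_th=cfg.iou_th, fps=cfg.fps)
    if log:
        log.log("detect", clip_accuracy=round(clip_acc, 3),
                f1=round(report.f1, 3) if not np.isnan(report.f1) else None,
                dt=round(time.time() - t2, 1))
    return {
        "coverage": coverage,
        "clip_accuracy": clip_acc,
        "report": report,
        "matches": matches,
        "per_video_detections": per_video,
        "candidates": per_video_cands,
        "net": net,
        "losses": losses,
        "train_videos": train_videos,
        "test_videos": test_videos,
    }


def run_all(cfg: PipelineConfig, out_dir: str, log_echo: bool = False) -> dict:
    """Full pipeline into a run directory; returns the metrics dict."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        fh.write(cfg.to_yaml())
    log = JsonlLogger(os.path.join(out_dir, "log.jsonl"), echo=log_echo)
    t0 = time.time()
    try:
        res = run_seed(cfg, cfg.seed, log=log)
    except VfssError as e:
        log.log("error", error_type=type(e).__name__, message=str(e))
        log.close()
        raise

    cand_rows = []
    for (seq, _), cands in zip(res["train_videos"], res["candidates"]):
        for c in cands:
            cand_rows.append({"video_id": seq.source_id,
                              "start_frame": c.start_frame,
                              "end_frame": c.end_frame,
                              "confidence": c.vote_score})
    write_intervals(cand_rows, os.path.join(out_dir, "candidates.csv"))
    det_rows = [d for dets, _ in res["per_video_detections"] for d in dets]
    write_intervals(det_rows, os.path.join(out_dir, "detections.csv"))
    save_checkpoint(res["net"], os.path.join(out_dir, "checkpoint.npz"))

    report = res["report"]
    metrics = _jsonable({
        "candidate_event_coverage": round(float(res["coverage"]), 4),
        "clip_accuracy": round(res["clip_accuracy"], 4),
        **report.as_dict(),
        "miss_rate_pct": miss_rate(res["matches"]),
        "n_detections": len(det_rows),
    })
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=1)
    manifest = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "package_version": __version__,
        "elapsed_s": round(time.time() - t0, 1),
        "n_train_videos": cfg.n_train_videos,
        "n_test_videos": cfg.n_test_videos,
        "n_training_clips": int(len(res["losses"]) and len(res["candidates"])
                                and sum(len(c) for c in res["candidates"])),
        "parameter_count": count_parameters(res["net"]),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1)
    log.log("done", **{k: v for k, v in metrics.items() if v is not None})
    log.close()
    return metrics
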