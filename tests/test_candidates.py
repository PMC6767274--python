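import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vfssdet.candidates import (ClipCorpusSummary, center_region,
                                harvest_training_clips, select_candidates,
                                vote_frames)
from vfssdet.errors import ContractError
from vfssdet.flow import MotionMap, normalize_flow
from vfssdet.synthetic import Distractor, SynthSpec, generate_video

from oracles import select_candidates_ref


def motion_from_y(y, normalized=True):
    """MotionMap with a given per-step constant Y field."""
    y = np.asarray(y, dtype=np.float32)
    flow = np.zeros((len(y), 8, 8, 2), dtype=np.float32)
    flow[..., 1] = y[:, None, None]
    return MotionMap(flow, normalized=normalized)


class TestCenterRegion:
    def test_half_of_224(self):
        assert center_region(224, 224, 0.5) == (56, 167, 56, 167)

    def test_full_frame(self):
        assert center_region(10, 20, 1.0) == (0, 9, 0, 19)

    def test_small_odd_case(self):
        assert center_region(10, 10, 0.5) == (2, 6, 2, 6)

    def test_invalid(self):
        with pytest.raises(ContractError):
            center_region(0, 10, 0.5)
        with pytest.raises(ContractError):
            center_region(10, 10, 0.0)


class TestVoteFrames:
    def test_zero_flow_zero_votes(self):
        votes = vote_frames(motion_from_y(np.zeros(12)))
        assert (votes == 0).all()

    def test_single_trigger_spreads_radius_4(self):
        y = np.zeros(30)
        y[10] = 0.9
        votes = vote_frames(motion_from_y(y))
        expected = np.zeros(30)
        expected[6:15] = 1
        np.testing.assert_array_equal(votes, expected)

    def test_three_adjacent_triggers(self):
        y = np.zeros(30)
        y[10:13] = 0.9
        votes = vote_frames(motion_from_y(y))
        assert votes.max() == 3
        assert (votes[10:13] == 3).all()
        assert (votes[8:15] >= 2).all()

    def test_negative_y_counts_via_absolute_value(self):
        y = np.zeros(12)
        y[5] = -0.9
        assert vote_frames(motion_from_y(y)).max() == 1

    def test_at_threshold_does_not_trigger(self):
        y = np.full(9, 0.4)  # strictly-greater comparison
        assert vote_frames(motion_from_y(y)).max() == 0

    def test_requires_normalized(self):
        with pytest.raises(ContractError):
            vote_frames(motion_from_y(np.zeros(5), normalized=False))

    def test_vote_bound_radius_4(self):
        rng = np.random.default_rng(3)
        votes = vote_frames(motion_from_y(rng.uniform(-1, 1, 60)))
        assert votes.max() <= 9


class TestSelectCandidates:
    def test_empty_tally(self):
        assert select_candidates(np.zeros(99), seq_len=100) == []

    def test_single_plateau(self):
        tally = np.zeros(99)
        tally[8:15] = 3
        cands = select_candidates(tally, seq_len=100)
        assert len(cands) == 1
        c = cands[0]
        assert c.start_frame <= 8 and c.end_frame >= 14
        assert c.peak_frame == 8  # plateau tie broken by earliest step

    def test_two_separated_plateaus(self):
        tally = np.zeros(99)
        tally[12:19] = 3   # centered at 15
        tally[57:64] = 3   # centered at 60
        spans = [(c.start_frame, c.end_frame)
                 for c in select_candidates(tally, seq_len=100)]
        assert spans == [(2, 21), (47, 66)]

    def test_boundary_clamping(self):
        tally = np.zeros(39)
        tally[2] = 5
        tally[36] = 4
        cands = select_candidates(tally, seq_len=40)
        assert cands[0].start_frame == 0
        assert cands[-1].end_frame == 39

    def test_at_most_five(self):
        tally = np.full(299, 9.0)
        assert len(select_candidates(tally, seq_len=300)) == 5

    def test_peaks_outside_previously_accepted_spans(self):
        # acceptance order is descending tally (earlier step on ties); each
        # accepted peak must lie outside every span accepted before it.
        # (A later clip clamped at a boundary may cover an earlier peak.)
        rng = np.random.default_rng(0)
        for _ in range(30):
            tally = rng.integers(0, 10, size=80).astype(float)
            cands = select_candidates(tally, seq_len=81)
            by_acceptance = sorted(cands,
                                   key=lambda c: (-c.vote_score, c.peak_frame))
            for i, c in enumerate(by_acceptance):
                for earlier in by_acceptance[:i]:
                    assert not (earlier.start_frame <= c.peak_frame
                                <= earlier.end_frame)

    @given(st.integers(0, 2**32 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_exhaustive_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        tally = rng.integers(0, 10, size=n).astype(float)
        seq_len = n + 1
        got = [(c.start_frame, c.end_frame, c.peak_frame)
               for c in select_candidates(tally, seq_len=seq_len)]
        ref = select_candidates_ref(tally.tolist(), 2.5, 5, 20, seq_len)
        assert got == ref


class TestHarvest:
    def test_clean_event_yields_one_overlapping_candidate(self):
        spec = SynthSpec(seed=5, duration_frames=60, n_events=1,
                         event_duration_frames=(10, 10),
                         event_speed_px=(6.0, 6.0),
                         distractors=[], frame_size=(48, 48))
        seq, gt = generate_video(spec)
        cands, _ = harvest_training_clips(seq, size=48, streams=("rgb",))
        assert len(cands) == 1
        g = gt.intervals[0]
        c = cands[0]
        assert c.start_frame <= g.end_frame and g.start_frame <= c.end_frame
        assert c.rgb.shape == (20, 48, 48, 3)

    def test_static_video_yields_nothing(self):
        spec = SynthSpec(seed=5, duration_frames=40, n_events=0,
                         distractors=[], frame_size=(48, 48))
        seq, _ = generate_video(spec)
        cands, _ = harvest_training_clips(seq, size=48, streams=("rgb",))
        assert cands == []

    def test_horizontal_distractor_casts_no_votes(self):
        spec = SynthSpec(seed=5, duration_frames=60, n_events=1,
                         event_duration_frames=(10, 10),
                         event_speed_px=(6.0, 6.0),
                         distractors=[Distractor("horizontal_shift", 6.0)],
                         frame_size=(48, 48))
        seq, gt = generate_video(spec)
        cands, _ = harvest_training_clips(seq, size=48, streams=("rgb",))
        g = gt.intervals[0]
        assert len(cands) == 1
        assert cands[0].start_frame <= g.end_frame
        assert g.start_frame <= cands[0].end_frame

    def test_flow_stream_clip_shape(self):
        spec = SynthSpec(seed=5, duration_frames=60, n_events=1,
                         event_duration_frames=(10, 10),
                         event_speed_px=(6.0, 6.0),
                         distractors=[], frame_size=(48, 48))
        seq, _ = generate_video(spec)
        cands, _ = harvest_training_clips(seq, size=48)
        assert cands[0].flow.shape == (20, 48, 48, 2)
        assert np.abs(cands[0].flow).max() <= 1.0


class TestCorpusSummary:
    def test_consistent_partition(self):
        s = ClipCorpusSummary(10, 12, 18, 4)
        assert s.total == 22 and s.consistent()

    def test_inconsistent_split_detected(self):
        assert not ClipCorpusSummary(10, 12, 18, 5).consistent()

    def test_from_labels(self):
        s = ClipCorpusSummary.from_labels([1, 0, "pharyngeal", 0], n_train=3)
        assert (s.n_pharyngeal, s.n_other, s.n_val) == (2, 2, 1)
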