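"""Consensus disorder calling: vote binarization, summing, regions, summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxidtools.disorder import (
    BinaryTrack,
    ConsensusProfile,
    DisorderTrack,
    binarize_track,
    call_disorder,
    combine_tracks,
    consensus_pipeline,
    extract_regions,
    summarize_disorder,
)


@pytest.mark.parametrize(
    "scores, expected",
    [
        ([0.7, 0.4, 0.51], [1, -1, 1]),
        ([0.5, 0.5], [-1, -1]),  # boundary score votes ordered: strictly > cutoff
        ([0.0] * 5, [-1] * 5),
        ([1.0, 0.0], [1, -1]),
    ],
)
def test_binarize_votes(scores, expected):
    track = DisorderTrack("p", "x", np.array(scores))
    assert binarize_track(track).votes.tolist() == expected


def test_binarize_custom_cutoff():
    track = DisorderTrack("p", "x", np.array([0.3, 0.31]))
    assert binarize_track(track, cutoff=0.3).votes.tolist() == [-1, 1]


def test_score_out_of_range_names_residue():
    with pytest.raises(ValueError, match="residue 2"):
        DisorderTrack("p", "x", np.array([0.5, 1.2]))


def test_combine_sums_votes():
    tracks = [
        BinaryTrack("p", f"t{i}", np.array(v))
        for i, v in enumerate([[1, 1, -1], [1, -1, -1], [1, 1, -1]])
    ]
    profile = combine_tracks(tracks)
    assert profile.summed_votes.tolist() == [3, 1, -3]
    assert profile.n_predictors == 3


def test_combine_single_track_identity():
    t = BinaryTrack("p", "t", np.array([1, -1, 1]))
    assert combine_tracks([t]).summed_votes.tolist() == t.votes.tolist()


@pytest.mark.parametrize(
    "tracks",
    [
        [],
        [BinaryTrack("p", "a", np.array([1])), BinaryTrack("q", "b", np.array([1]))],
        [BinaryTrack("p", "a", np.array([1])), BinaryTrack("p", "b", np.array([1, 1]))],
    ],
    ids=["empty", "mixed-protein", "length-mismatch"],
)
def test_combine_rejects_bad_input(tracks):
    with pytest.raises(ValueError):
        combine_tracks(tracks)


def test_call_disorder_unanimity_default():
    profile = ConsensusProfile("p", 3, np.array([3, 1, -3]))
    assert call_disorder(profile).tolist() == [True, False, False]


def test_call_disorder_relaxed_threshold():
    profile = ConsensusProfile("p", 3, np.array([1]))
    assert call_disorder(profile, required=1).tolist() == [True]


def test_call_disorder_required_too_high():
    profile = ConsensusProfile("p", 3, np.array([3]))
    with pytest.raises(ValueError):
        call_disorder(profile, required=4)


@pytest.mark.parametrize(
    "mask, min_length, expected",
    [
        ([True, True, False, True], 1, [(1, 2), (4, 4)]),
        ([True, True, False, True], 2, [(1, 2)]),
        ([False] * 4, 1, []),
        ([True] * 3, 1, [(1, 3)]),
    ],
)
def test_extract_regions(mask, min_length, expected):
    regions = extract_regions(mask, min_length)
    assert [(r.start, r.end) for r in regions] == expected


def test_extract_regions_rejects_bad_config():
    with pytest.raises(ValueError):
        extract_regions([True], min_length=0)
    with pytest.raises(ValueError):
        extract_regions([])


@pytest.mark.parametrize(
    "n_true, n_total, expected",
    [
        (24, 61, 39.34),  # 39.3442... rounds to the printed two-decimal value
        (3, 624, 0.48),
        (61, 61, 100.00),
        (0, 10, 0.00),
    ],
)
def test_percent_disordered_reporting(n_true, n_total, expected):
    mask = np.zeros(n_total, dtype=bool)
    mask[:n_true] = True
    regions = extract_regions(mask) if n_true else []
    summary = summarize_disorder(mask, regions)
    assert summary.percent_disordered == pytest.approx(expected)
    assert summary.percent_disordered_raw == pytest.approx(100 * n_true / n_total)


def test_summarize_zero_length_mask_rejected():
    with pytest.raises(ValueError):
        summarize_disorder(np.array([], dtype=bool), [])


# ---------------------------------------------------------------------------
# properties

score_arrays = st.integers(1, 200).flatmap(
    lambda n: st.lists(
        st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n
    )
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.integers(1, 5).flatmap(
        lambda n_pred: st.integers(1, 120).flatmap(
            lambda length: st.lists(
                st.lists(st.floats(0, 1, allow_nan=False, width=32),
                         min_size=length, max_size=length),
                min_size=n_pred, max_size=n_pred,
            )
        )
    ),
    cutoff=st.floats(0.1, 0.9),
)
def test_consensus_matches_bruteforce_oracle(data, cutoff):
    """Consensus mask == per-residue count of super-cutoff predictors == N."""
    tracks = [DisorderTrack("p", f"t{i}", np.array(s)) for i, s in enumerate(data)]
    mask, _, _ = consensus_pipeline(tracks, cutoff=cutoff)
    n = len(tracks)
    expected = [
        sum(1 for t in tracks if t.scores[i] > cutoff) == n
        for i in range(len(tracks[0]))
    ]
    assert mask.tolist() == expected


@settings(max_examples=40, deadline=None, derandomize=True)
@given(scores=score_arrays, n_copies=st.integers(1, 5))
def test_identical_tracks_idempotent(scores, n_copies):
    """N copies of one track give the same mask as binarizing it alone."""
    tracks = [
        DisorderTrack("p", f"t{i}", np.array(scores)) for i in range(n_copies)
    ]
    mask, _, _ = consensus_pipeline(tracks)
    single = binarize_track(tracks[0]).votes == 1
    assert mask.tolist() == single.tolist()


@settings(max_examples=40, deadline=None, derandomize=True)
@given(scores=score_arrays, idx=st.data())
def test_raising_a_score_is_monotone(scores, idx):
    """Raising one score never removes a residue from the consensus mask."""
    track = DisorderTrack("p", "t", np.array(scores))
    mask_before, _, _ = consensus_pipeline([track])
    i = idx.draw(st.integers(0, len(scores) - 1))
    raised = np.array(scores)
    raised[i] = 1.0
    mask_after, _, _ = consensus_pipeline([DisorderTrack("p", "t", raised)])
    assert (mask_before <= mask_after).all()


@settings(max_examples=40, deadline=None, derandomize=True)
@given(mask=st.lists(st.booleans(), min_size=1, max_size=200))
def test_regions_partition_true_residues(mask):
    """With min_length 1, region lengths sum to the number of True residues."""
    regions = extract_regions(mask)
    assert sum(r.length for r in regions) == sum(mask)
    # maximality: no two adjacent regions touch
    for a, b in zip(regions, regions[1:]):
        assert b.start > a.end + 1
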