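"""Consensus intrinsic-disorder calling from per-residue predictor scores.

Multiple disorder predictors (e.g. PrDOS, IUPred2A, PONDR) each emit one
score per residue in [0, 1].  Each predictor's track is binarized into
per-residue votes (+1 disordered for score > cutoff, -1 ordered otherwise),
the votes are summed across predictors, and a residue is called disordered
when the summed vote reaches a required level — by default unanimity
(+N of N predictors, the classical +3-of-3 rule).  Contiguous runs of
disordered residues form intrinsically disordered regions (IDRs), and the
percent-disordered score is 100 x (disordered residues) / (protein length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .utils import round_half_up

__all__ = [
    "DisorderTrack",
    "BinaryTrack",
    "ConsensusProfile",
    "DisorderedRegion",
    "DisorderSummary",
    "binarize_track",
    "combine_tracks",
    "call_disorder",
    "extract_regions",
    "summarize_disorder",
    "consensus_pipeline",
]


@dataclass(frozen=True)
class DisorderTrack:
    """One predictor's per-residue disorder scores for one protein.

    Scores are unitless values in [0, 1], ordered N- to C-terminus
    (residue 1 is ``scores[0]``).
    """

    protein_id: str
    predictor_name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D sequence")
        bad = np.flatnonzero((scores < 0.0) | (scores > 1.0) | ~np.isfinite(scores))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"score {scores[i]!r} at residue {i + 1} of "
                f"{self.protein_id}/{self.predictor_name} is outside [0, 1]"
            )
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class BinaryTrack:
    """Per-residue +1 (disordered) / -1 (ordered) votes from one predictor."""

    protein_id: str
    predictor_name: str
    votes: np.ndarray

    def __post_init__(self) -> None:
        votes = np.asarray(self.votes, dtype=int)
        if votes.ndim != 1 or votes.size == 0:
            raise ValueError("votes must be a non-empty 1-D sequence")
        if not np.isin(votes, (-1, 1)).all():
            raise ValueError("votes must be drawn from {+1, -1}")
        object.__setattr__(self, "votes", votes)

    def __len__(self) -> int:
        return int(self.votes.size)


@dataclass(frozen=True)
class ConsensusProfile:
    """Summed per-residue votes over ``n_predictors`` tracks."""

    protein_id: str
    n_predictors: int
    summed_votes: np.ndarray

    def __post_init__(self) -> None:
        votes = np.asarray(self.summed_votes, dtype=int)
        n = self.n_predictors
        if n < 1:
            raise ValueError("n_predictors must be positive")
        if np.abs(votes).max(initial=0) > n:
            raise ValueError("|summed vote| cannot exceed the number of predictors")
        if ((votes - n) % 2).any():
            raise ValueError("summed votes must share parity with n_predictors")
        object.__setattr__(self, "summed_votes", votes)

    def __len__(self) -> int:
        return int(self.summed_votes.size)


@dataclass(frozen=True)
class DisorderedRegion:
    """A maximal run of consensus-disordered residues, 1-based inclusive."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region bounds ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DisorderSummary:
    protein_id: str
    n_regions: int
    n_disordered_residues: int
    n_residues: int
    percent_disordered_raw: float = field(repr=False, default=0.0)

    @property
    def percent_disordered(self) -> float:
        """Percent disordered, rounded half-up to two decimals for reporting."""
        return round_half_up(self.percent_disordered_raw, 2)


def binarize_track(track: DisorderTrack, cutoff: float = 0.5) -> BinaryTrack:
    """Binarize scores into votes: +1 iff score > cutoff, else -1.

    A score exactly equal to the cutoff votes ordered (-1): only strictly
    super-threshold scores count as disordered.
    """
    votes = np.where(track.scores > cutoff, 1, -1)
    return BinaryTrack(track.protein_id, track.predictor_name, votes)


def combine_tracks(tracks: Sequence[BinaryTrack]) -> ConsensusProfile:
    """Sum per-residue votes across predictors for one protein."""
    if len(tracks) == 0:
        raise ValueError("need at least one binary track")
    protein_ids = {t.protein_id for t in tracks}
    if len(protein_ids) != 1:
        raise ValueError(f"tracks mix protein ids: {sorted(protein_ids)}")
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"tracks have mismatched lengths: {sorted(lengths)}")
    summed = np.sum([t.votes for t in tracks], axis=0)
    return ConsensusProfile(tracks[0].protein_id, len(tracks), summed)


def call_disorder(profile: ConsensusProfile, required: int | None = None) -> np.ndarray:
    """Boolean disorder mask: residue i is disordered iff summed vote >= required.

    ``required`` defaults to ``n_predictors`` (unanimous consensus, the
    +3-of-3 rule when three predictors are used).
    """
    if required is None:
        required = profile.n_predictors
    if required > profile.n_predictors:
        raise ValueError(
            f"required consensus {required} exceeds the "
            f"{profile.n_predictors} available predictors"
        )
    return profile.summed_votes >= required


def extract_regions(
    mask: Sequence[bool] | np.ndarray,
    min_length: int = 1,
    protein_id: str = "",
) -> list[DisorderedRegion]:
    """Maximal runs of True in ``mask`` as 1-based inclusive intervals.

    Runs shorter than ``min_length`` are dropped; output is sorted by start.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        raise ValueError("mask must be non-empty")
    padded = np.concatenate(([False], m, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2] + 1, edges[1::2]  # 1-based inclusive
    return [
        DisorderedRegion(protein_id, int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s + 1 >= min_length
    ]


def summarize_disorder(
    mask: Sequence[bool] | np.ndarray,
    regions: Sequence[DisorderedRegion],
    protein_id: str = "",
) -> DisorderSummary:
    """Count disordered residues/regions and the percent-disordered score."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        raise ValueError("cannot summarize a zero-length mask")
    n_true = int(m.sum())
    return DisorderSummary(
        protein_id=protein_id,
        n_regions=len(regions),
        n_disordered_residues=n_true,
        n_residues=int(m.size),
        percent_disordered_raw=100.0 * n_true / m.size,
    )


def consensus_pipeline(
    tracks: Sequence[DisorderTrack],
    cutoff: float = 0.5,
    required: int | None = None,
    min_length: int = 1,
) -> tuple[np.ndarray, list[DisorderedRegion], DisorderSummary]:
    """Run binarize -> combine -> call -> regions -> summary in one step."""
    binary = [binarize_track(t, cutoff) for t in tracks]
    profile = combine_tracks(binary)
    mask = call_disorder(profile, required)
    regions = extract_regions(mask, min_length, profile.protein_id)
    summary = summarize_disorder(mask, regions, profile.protein_id)
    return mask, regions, summary
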