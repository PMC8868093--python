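"""Residue composition and positional conservation across ortholog sets.

Cysteine content is a simple composition statistic (percent of residues
that are C), computed per species and averaged across an ortholog set.
Positional conservation of reference-protein cysteines is read off a
precomputed multiple sequence alignment: each reference position is mapped
to its alignment column and the species whose aligned letter matches are
counted (gaps and substitutions count as non-matching).  A position is
"completely" conserved when every species matches, "highly" conserved when
the match count reaches a caller-supplied threshold, and "low" otherwise.
Alignments are consumed, never built; identity is the only similarity
notion used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .utils import round_half_up

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(AMINO_ACIDS + "X")
GAP = "-"

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "OrthologSet",
    "Msa",
    "CompositionReport",
    "ConservationRecord",
    "residue_percent",
    "residue_count",
    "composition_report",
    "residue_positions",
    "map_positions",
    "classify_conservation",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One species' protein sequence (20 amino acids plus X, uppercase)."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"empty sequence for {self.id}")
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(f"invalid letters {sorted(bad)} in {self.id}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrthologSet:
    records: tuple[ProteinRecord, ...]
    reference_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValueError("ortholog set is empty")
        species = [r.species for r in self.records]
        if len(set(species)) != len(species):
            raise ValueError("species labels must be unique")
        if self.reference_id not in {r.id for r in self.records}:
            raise ValueError(f"reference {self.reference_id!r} not in set")

    @property
    def reference(self) -> ProteinRecord:
        return next(r for r in self.records if r.id == self.reference_id)


@dataclass(frozen=True)
class Msa:
    """Aligned ortholog sequences over the 21-letter alphabet plus '-' gaps."""

    records: tuple[ProteinRecord, ...]  # ungapped sequences
    aligned: tuple[str, ...]  # same order as records; '-' for gaps
    reference_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "aligned", tuple(s.upper() for s in self.aligned))
        if len(self.records) != len(self.aligned) or not self.records:
            raise ValueError("one aligned sequence per record required")
        widths = {len(s) for s in self.aligned}
        if len(widths) != 1:
            raise ValueError("aligned sequences must have equal length")
        for rec, ali in zip(self.records, self.aligned):
            if ali.replace(GAP, "") != rec.sequence:
                raise ValueError(f"alignment for {rec.id} does not match its sequence")
        if self.reference_id not in {r.id for r in self.records}:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    @property
    def n_species(self) -> int:
        return len(self.records)

    @property
    def width(self) -> int:
        return len(self.aligned[0])

    def aligned_for(self, record_id: str) -> str:
        for rec, ali in zip(self.records, self.aligned):
            if rec.id == record_id:
                return ali
        raise KeyError(record_id)


@dataclass(frozen=True)
class CompositionReport:
    """Per-species residue percents (2 dp) and their unweighted mean."""

    residue: str
    per_species: dict[str, float]
    mean_percent: float


@dataclass(frozen=True)
class ConservationRecord:
    reference_position: int  # 1-based index in the ungapped reference
    alignment_column: int  # 1-based alignment column
    residue: str
    n_matching: int  # species (reference included) with this letter at the column
    conservation_class: str  # complete | high | low


def residue_count(record: ProteinRecord, residue: str = "C") -> int:
    if residue not in AMINO_ACIDS:
        raise ValueError(f"{residue!r} is not a standard amino-acid letter")
    return record.sequence.count(residue)


def residue_percent(record: ProteinRecord, residue: str = "C") -> float:
    """Percent of residues equal to ``residue`` (half-up, 2 dp).

    'X' placeholders count toward length but never match.
    """
    return round_half_up(100.0 * residue_count(record, residue) / len(record), 2)


def composition_report(orthologs: OrthologSet, residue: str = "C") -> CompositionReport:
    """Per-species percents and their unweighted arithmetic mean.

    The cross-species mean averages per-species percents, not pooled
    residue counts, so short and long orthologs weigh equally.
    """
    per_species = {r.species: residue_percent(r, residue) for r in orthologs.records}
    raw = [
        100.0 * residue_count(r, residue) / len(r) for r in orthologs.records
    ]
    return CompositionReport(
        residue=residue,
        per_species=per_species,
        mean_percent=round_half_up(sum(raw) / len(raw), 2),
    )


def residue_positions(record: ProteinRecord, residue: str = "C") -> list[int]:
    """All 1-based positions of ``residue`` in the sequence."""
    if residue not in AMINO_ACIDS:
        raise ValueError(f"{residue!r} is not a standard amino-acid letter")
    return [i + 1 for i, a in enumerate(record.sequence) if a == residue]


def map_positions(msa: Msa, positions: Sequence[int]) -> list[int]:
    """Map ungapped 1-based reference positions to 1-based alignment columns."""
    ref = msa.aligned_for(msa.reference_id)
    # column of the p-th non-gap letter of the reference, for each p
    col_of: list[int] = [c + 1 for c, a in enumerate(ref) if a != GAP]
    out = []
    for p in positions:
        if not 1 <= p <= len(col_of):
            raise ValueError(
                f"position {p} outside the reference's {len(col_of)} residues"
            )
        out.append(col_of[p - 1])
    return out


def classify_conservation(
    msa: Msa,
    positions: Sequence[int],
    residue: str = "C",
    high_threshold: int | None = None,
) -> list[ConservationRecord]:
    """Classify conservation of reference positions through the alignment.

    ``high_threshold`` is the minimum number of matching species (reference
    included) for the "high" class and must be given explicitly: published
    analyses have used different cutoffs for different proteins (13-of-15
    vs 12-of-15), so no default is safe.  ``complete`` means all species
    match; gaps never match.
    """
    if high_threshold is None:
        raise ValueError("high_threshold must be provided explicitly")
    if high_threshold > msa.n_species:
        raise ValueError("high_threshold cannot exceed the number of species")
    columns = map_positions(msa, positions)
    records = []
    for pos, col in zip(positions, columns):
        letters = [ali[col - 1] for ali in msa.aligned]
        n_match = sum(1 for a in letters if a == residue)
        if n_match == msa.n_species:
            klass = "complete"
        elif n_match >= high_threshold:
            klass = "high"
        else:
            klass = "low"
        records.append(
            ConservationRecord(
                reference_position=pos,
                alignment_column=col,
                residue=residue,
                n_matching=n_match,
                conservation_class=klass,
            )
        )
    return records
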