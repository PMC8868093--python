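"""Readers and writers for the pipeline's on-disk formats.

Tracks are two-column TSV (``residue_index``, ``score``; 1-based indices).
Sequences and alignments are FASTA / aligned-FASTA via Biopython.  Regions
are exported as BED, converting 1-based inclusive residue intervals to
BED's 0-based half-open convention (start-1, end).  Images are single- or
two-page TIFF via tifffile.  All tables are tab-separated with one header
line; percents print with two decimals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import (
    CompositionReport,
    ConservationRecord,
    Msa,
    OrthologSet,
    ProteinRecord,
)
from .disorder import DisorderedRegion, DisorderSummary, DisorderTrack
from .inclusions import CellRecord, ImagePair, InclusionSummary

__all__ = [
    "read_track_tsv",
    "write_track_tsv",
    "read_fasta",
    "write_fasta",
    "read_species_map",
    "read_ortholog_fasta",
    "read_msa_fasta",
    "write_msa_fasta",
    "regions_to_bed",
    "write_regions_bed",
    "write_disorder_summary",
    "write_composition_tsv",
    "write_conservation_tsv",
    "read_image_pair",
    "write_image_pair",
    "write_cells_tsv",
    "write_inclusion_summary",
]


# ---------------------------------------------------------------------------
# score tracks


def read_track_tsv(path: str | Path, protein_id: str, predictor_name: str | None = None) -> DisorderTrack:
    """Read one predictor's per-residue scores from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    expected = ["residue_index", "score"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    idx = df["residue_index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError(f"{path}: residue_index must run 1..L without gaps")
    name = predictor_name if predictor_name is not None else Path(path).stem
    return DisorderTrack(protein_id, name, df["score"].to_numpy(dtype=float))


def write_track_tsv(track: DisorderTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {"residue_index": np.arange(1, len(track) + 1), "score": track.scores}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# sequences and alignments


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence} (uppercased, gaps preserved if any)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str] | Iterable[ProteinRecord], path: str | Path) -> None:
    if isinstance(sequences, dict):
        items = sequences.items()
    else:
        items = ((r.id, r.sequence) for r in sequences)
    records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in items]
    SeqIO.write(records, str(path), "fasta")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (record id, species label) -> {id: species}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "species"], dtype=str)
    return dict(zip(df["id"], df["species"]))


def read_ortholog_fasta(
    path: str | Path,
    reference_id: str,
    species_map: dict[str, str] | None = None,
) -> OrthologSet:
    """Unaligned multi-FASTA -> OrthologSet.

    Without a species map each record id doubles as its species label.
    """
    seqs = read_fasta(path)
    records = tuple(
        ProteinRecord(id=rid, species=(species_map or {}).get(rid, rid), sequence=seq)
        for rid, seq in seqs.items()
    )
    return OrthologSet(records=records, reference_id=reference_id)


def read_msa_fasta(
    path: str | Path,
    reference_id: str,
    species_map: dict[str, str] | None = None,
) -> Msa:
    """Aligned FASTA (gap '-') -> Msa; ungapped sequences are rederived."""
    aligned = read_fasta(path)
    records = tuple(
        ProteinRecord(
            id=rid,
            species=(species_map or {}).get(rid, rid),
            sequence=seq.replace("-", ""),
        )
        for rid, seq in aligned.items()
    )
    return Msa(records=records, aligned=tuple(aligned.values()), reference_id=reference_id)


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    write_fasta({r.id: a for r, a in zip(msa.records, msa.aligned)}, path)


# ---------------------------------------------------------------------------
# regions / summaries


def regions_to_bed(regions: Sequence[DisorderedRegion]) -> pd.DataFrame:
    """1-based inclusive [start, end] -> BED 0-based half-open [start-1, end)."""
    return pd.DataFrame(
        {
            "chrom": [r.protein_id for r in regions],
            "chromStart": [r.start - 1 for r in regions],
            "chromEnd": [r.end for r in regions],
            "name": [f"IDR_{i + 1}" for i in range(len(regions))],
        }
    )


def write_regions_bed(regions: Sequence[DisorderedRegion], path: str | Path) -> None:
    regions_to_bed(regions).to_csv(path, sep="\t", index=False, header=False)


def write_disorder_summary(summary: DisorderSummary, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": summary.protein_id,
                "n_residues": summary.n_residues,
                "n_regions": summary.n_regions,
                "n_disordered_residues": summary.n_disordered_residues,
                "percent_disordered": f"{summary.percent_disordered:.2f}",
            }
        ]
    ).to_csv(path, sep="\t", index=False)


def write_composition_tsv(report: CompositionReport, path: str | Path) -> None:
    rows = [
        {"species": sp, "percent": f"{pct:.2f}"}
        for sp, pct in report.per_species.items()
    ]
    rows.append({"species": "MEAN", "percent": f"{report.mean_percent:.2f}"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_conservation_tsv(records: Sequence[ConservationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "reference_position": r.reference_position,
                "alignment_column": r.alignment_column,
                "residue": r.residue,
                "n_matching": r.n_matching,
                "conservation_class": r.conservation_class,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# images


def read_image_pair(
    nucleus_path: str | Path, protein_path: str | Path | None = None
) -> ImagePair:
    """Read a two-page TIFF (nucleus page 1, protein page 2) or two TIFFs."""
    if protein_path is None:
        stack = tifffile.imread(str(nucleus_path))
        if stack.ndim != 3 or stack.shape[0] != 2:
            raise ValueError(
                f"{nucleus_path}: expected a two-page TIFF, got shape {stack.shape}"
            )
        nucleus, protein = stack[0], stack[1]
    else:
        nucleus = tifffile.imread(str(nucleus_path))
        protein = tifffile.imread(str(protein_path))
    return ImagePair(nucleus=np.asarray(nucleus, float), protein=np.asarray(protein, float))


def write_image_pair(pair: ImagePair, path: str | Path) -> None:
    """Write both channels as one two-page 16-bit TIFF (values clipped)."""
    stack = np.stack(
        [
            np.clip(np.rint(pair.nucleus), 0, 65535).astype(np.uint16),
            np.clip(np.rint(pair.protein), 0, 65535).astype(np.uint16),
        ]
    )
    tifffile.imwrite(str(path), stack)


def write_cells_tsv(cells: Sequence[CellRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "label": c.label,
                "centroid_row": f"{c.centroid[0]:.2f}",
                "centroid_col": f"{c.centroid[1]:.2f}",
                "n_foci": c.n_foci,
                "has_inclusions": int(c.has_inclusions),
            }
            for c in cells
        ]
    ).to_csv(path, sep="\t", index=False)


def write_inclusion_summary(summary: InclusionSummary, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "n_cells_counted": summary.n_cells_counted,
                "n_cells_with_inclusions": summary.n_cells_with_inclusions,
                "percent_with_inclusions": f"{summary.percent_with_inclusions:.2f}",
            }
        ]
    ).to_csv(path, sep="\t", index=False)
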