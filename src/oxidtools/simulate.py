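"""Seeded synthetic inputs with ground truth for every analysis stage.

Three generators emulate the study's three input kinds:

* predictor score tracks — clipped-normal scores centered high inside the
  true disordered segments and low outside, one track per predictor;
* ortholog sets — a cysteine-bearing reference plus species that retain
  each cysteine independently with probability ``p_conserve``, optionally
  aligned through inserted gap columns;
* two-channel micrographs — non-overlapping disk nuclei (a controlled
  fraction clipped by the frame edge), diffuse cytoplasmic protein signal,
  and Gaussian foci in a controlled fraction of countable cells, plus
  additive Gaussian noise.

Each generator is a pure function of (config, seed) and returns its truth
object alongside the data, so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conservation import AMINO_ACIDS, Msa, OrthologSet, ProteinRecord
from .disorder import DisorderTrack
from .inclusions import ImagePair

__all__ = [
    "TrackSimConfig",
    "OrthologSimConfig",
    "ImageSimConfig",
    "TrackTruth",
    "OrthologTruth",
    "ImageTruth",
    "simulate_tracks",
    "simulate_orthologs",
    "simulate_images",
    "nrf2_standin",
    "keap1_standin",
]

_NON_CYS = AMINO_ACIDS.replace("C", "")


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class TrackSimConfig:
    protein_length: int
    true_regions: tuple[tuple[int, int], ...]
    n_predictors: int = 3
    mu_disordered: float = 0.8
    mu_ordered: float = 0.2
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "true_regions", tuple(tuple(r) for r in self.true_regions)
        )
        if self.protein_length < 1 or self.n_predictors < 1:
            raise ValueError("protein_length and n_predictors must be positive")
        if not (0 <= self.mu_ordered <= 1 and 0 <= self.mu_disordered <= 1):
            raise ValueError("mu values must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        prev_end = 0
        for start, end in sorted(self.true_regions):
            if not 1 <= start <= end <= self.protein_length:
                raise ValueError(f"region ({start}, {end}) outside the protein")
            if start <= prev_end:
                raise ValueError("true regions overlap")
            prev_end = end


@dataclass(frozen=True)
class OrthologSimConfig:
    n_species: int = 15
    reference_length: int = 300
    cys_positions: tuple[int, ...] = ()
    p_conserve: float = 0.9
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cys_positions", tuple(self.cys_positions))
        if self.n_species < 1 or self.reference_length < 1:
            raise ValueError("n_species and reference_length must be positive")
        if len(set(self.cys_positions)) != len(self.cys_positions):
            raise ValueError("cys_positions must be distinct")
        for p in self.cys_positions:
            if not 1 <= p <= self.reference_length:
                raise ValueError(f"cysteine position {p} outside the reference")
        if not 0 <= self.p_conserve <= 1:
            raise ValueError("p_conserve must lie in [0, 1]")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must lie in [0, 1)")


@dataclass(frozen=True)
class ImageSimConfig:
    height: int = 640
    width: int = 640
    n_nuclei: int = 45
    nucleus_radius_px: int = 8
    fraction_border: float = 0.2
    fraction_with_inclusions: float = 0.5
    foci_per_cell: int = 3
    spot_amplitude: float = 60.0
    spot_sigma_px: float = 1.5
    background_level: float = 20.0
    cytoplasm_level: float = 15.0
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width) < 8 * self.nucleus_radius_px:
            raise ValueError("canvas too small for the nucleus radius")
        if not 0 <= self.fraction_border <= 1:
            raise ValueError("fraction_border must lie in [0, 1]")
        if not 0 <= self.fraction_with_inclusions <= 1:
            raise ValueError("fraction_with_inclusions must lie in [0, 1]")
        if self.foci_per_cell < 1:
            raise ValueError("foci_per_cell must be >= 1")
        if self.spot_amplitude < 0 or self.spot_sigma_px < 0:
            raise ValueError("spot amplitude and sigma must be non-negative")
        if self.noise_sigma < 0 or self.background_level < 0:
            raise ValueError("noise and background must be non-negative")


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class TrackTruth:
    true_regions: tuple[tuple[int, int], ...]
    true_mask: np.ndarray
    percent_disordered: float


@dataclass(frozen=True)
class OrthologTruth:
    position_to_column: dict[int, int]
    n_matching: dict[int, int]  # per reference cysteine position


@dataclass(frozen=True)
class CellTruth:
    center: tuple[float, float]  # (row, col)
    touches_border: bool
    has_inclusions: bool
    spots: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class ImageTruth:
    cells: tuple[CellTruth, ...]
    n_countable: int
    n_with_inclusions: int

    @property
    def percent_with_inclusions(self) -> float:
        return 100.0 * self.n_with_inclusions / self.n_countable


# ---------------------------------------------------------------------------
# generators


def simulate_tracks(cfg: TrackSimConfig) -> tuple[list[DisorderTrack], TrackTruth]:
    """Per-predictor clipped-normal score tracks around known IDR segments."""
    rng = np.random.default_rng(cfg.seed)
    mask = np.zeros(cfg.protein_length, dtype=bool)
    for start, end in cfg.true_regions:
        mask[start - 1 : end] = True
    mu = np.where(mask, cfg.mu_disordered, cfg.mu_ordered)
    tracks = []
    for k in range(cfg.n_predictors):
        scores = np.clip(rng.normal(mu, cfg.sigma), 0.0, 1.0)
        tracks.append(DisorderTrack("simprot", f"predictor{k + 1}", scores))
    truth = TrackTruth(
        true_regions=cfg.true_regions,
        true_mask=mask,
        percent_disordered=100.0 * mask.sum() / cfg.protein_length,
    )
    return tracks, truth


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(list(_NON_CYS), size=length)


def simulate_orthologs(
    cfg: OrthologSimConfig,
) -> tuple[OrthologSet, Msa, OrthologTruth]:
    """Ortholog set with controlled per-position cysteine conservation.

    The reference carries C exactly at ``cys_positions``; every other
    species keeps each C independently with probability ``p_conserve`` and
    otherwise substitutes a random non-C letter.  Non-cysteine positions
    are shared across species.  With ``indel_rate`` > 0, insertion columns
    (gap in the reference, random letters elsewhere) are interleaved and
    the true position-to-column map reflects them.
    """
    rng = np.random.default_rng(cfg.seed)
    ref_letters = _random_protein(rng, cfg.reference_length)
    ref_letters[[p - 1 for p in cfg.cys_positions]] = "C"

    species_letters = [ref_letters]
    n_matching = {p: 1 for p in cfg.cys_positions}
    for _ in range(cfg.n_species - 1):
        letters = ref_letters.copy()
        for p in cfg.cys_positions:
            if rng.random() < cfg.p_conserve:
                n_matching[p] += 1
            else:
                letters[p - 1] = rng.choice(list(_NON_CYS))
        species_letters.append(letters)

    # interleave insertion columns: gap in the reference row
    n_insert = rng.binomial(cfg.reference_length + 1, cfg.indel_rate)
    insert_after = np.sort(
        rng.integers(0, cfg.reference_length + 1, size=n_insert)
    )  # 0 = before residue 1
    columns_per_slot = np.bincount(insert_after, minlength=cfg.reference_length + 1)

    aligned_rows: list[list[str]] = [[] for _ in species_letters]
    position_to_column: dict[int, int] = {}
    col = 0
    for slot in range(cfg.reference_length + 1):
        for _ in range(columns_per_slot[slot]):
            col += 1
            aligned_rows[0].append("-")
            for row in aligned_rows[1:]:
                row.append(str(rng.choice(list(_NON_CYS))))
        if slot < cfg.reference_length:
            col += 1
            position_to_column[slot + 1] = col
            for i, row in enumerate(aligned_rows):
                row.append(str(species_letters[i][slot]))

    records = []
    aligned = []
    for i in range(len(species_letters)):
        sp = "reference" if i == 0 else f"species{i:02d}"
        row = "".join(aligned_rows[i])
        # ungapped sequence includes any letters this species carries in
        # insertion columns, so it is derived from the aligned row
        records.append(
            ProteinRecord(id=f"ortho_{sp}", species=sp, sequence=row.replace("-", ""))
        )
        aligned.append(row)

    orthologs = OrthologSet(records=tuple(records), reference_id="ortho_reference")
    msa = Msa(records=tuple(records), aligned=tuple(aligned), reference_id="ortho_reference")
    truth = OrthologTruth(position_to_column=position_to_column, n_matching=n_matching)
    return orthologs, msa, truth


def _place_centers(
    rng: np.random.Generator, cfg: ImageSimConfig
) -> tuple[list[tuple[float, float]], list[bool]]:
    """Sample non-overlapping nucleus centers; a set fraction clip the edge."""
    r = cfg.nucleus_radius_px
    min_sep = 4.5 * r  # keeps each cell's foci inside its own Voronoi region
    n_border = int(round(cfg.fraction_border * cfg.n_nuclei))
    centers: list[tuple[float, float]] = []
    flags: list[bool] = []

    def ok(c: tuple[float, float]) -> bool:
        return all(math.dist(c, c0) >= min_sep for c0 in centers)

    for i in range(cfg.n_nuclei):
        border = i < n_border
        for _ in range(1000):
            if border:
                side = rng.integers(4)
                along = rng.uniform(2 * r, (cfg.height if side < 2 else cfg.width) - 2 * r)
                off = rng.uniform(0, r - 1)  # center within r of the edge: disk clips
                if side == 0:
                    c = (along, off)
                elif side == 1:
                    c = (along, cfg.width - 1 - off)
                elif side == 2:
                    c = (off, along)
                else:
                    c = (cfg.height - 1 - off, along)
            else:
                c = (
                    rng.uniform(r + 2, cfg.height - r - 3),
                    rng.uniform(r + 2, cfg.width - r - 3),
                )
            if ok(c):
                centers.append(c)
                flags.append(border)
                break
        else:
            raise ValueError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei "
                f"on a {cfg.height}x{cfg.width} canvas"
            )
    return centers, flags


def simulate_images(cfg: ImageSimConfig) -> tuple[ImagePair, ImageTruth]:
    """Render a two-channel field with known per-cell inclusion labels."""
    rng = np.random.default_rng(cfg.seed)
    centers, border_flags = _place_centers(rng, cfg)
    h, w, r = cfg.height, cfg.width, cfg.nucleus_radius_px
    rows, cols = np.indices((h, w))

    nucleus = np.full((h, w), cfg.background_level)
    protein = np.full((h, w), cfg.background_level)

    countable = [i for i, b in enumerate(border_flags) if not b]
    n_incl = int(round(cfg.fraction_with_inclusions * len(countable)))
    incl_idx = set(rng.choice(countable, size=n_incl, replace=False).tolist()) if n_incl else set()

    cells = []
    for i, (cr, cc) in enumerate(centers):
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        nucleus += 120.0 * (d2 <= r * r)
        # diffuse cytoplasmic halo (smooth: removed by the band-pass)
        protein += cfg.cytoplasm_level * np.exp(-d2 / (2 * (2.5 * r) ** 2))
        spots: list[tuple[float, float]] = []
        if i in incl_idx:
            for _ in range(cfg.foci_per_cell):
                for _attempt in range(100):
                    rho = rng.uniform(1.2 * r, 1.9 * r)
                    theta = rng.uniform(0, 2 * math.pi)
                    sr, sc = cr + rho * math.sin(theta), cc + rho * math.cos(theta)
                    margin = 3 * cfg.spot_sigma_px
                    if margin <= sr <= h - 1 - margin and margin <= sc <= w - 1 - margin:
                        break
                sd2 = (rows - sr) ** 2 + (cols - sc) ** 2
                protein += cfg.spot_amplitude * np.exp(-sd2 / (2 * cfg.spot_sigma_px**2))
                spots.append((sr, sc))
        cells.append(
            CellTruth(
                center=(cr, cc),
                touches_border=border_flags[i],
                has_inclusions=bool(spots),
                spots=tuple(spots),
            )
        )

    if cfg.noise_sigma > 0:
        nucleus = nucleus + rng.normal(0, cfg.noise_sigma, (h, w))
        protein = protein + rng.normal(0, cfg.noise_sigma, (h, w))
    nucleus = np.clip(nucleus, 0, None)
    protein = np.clip(protein, 0, None)

    truth = ImageTruth(
        cells=tuple(cells),
        n_countable=len(countable),
        n_with_inclusions=n_incl,
    )
    return ImagePair(nucleus=nucleus, protein=protein), truth


# ---------------------------------------------------------------------------
# canonical-protein stand-ins

# Canonical human lengths and literature-documented cysteine positions.
_NRF2_LENGTH = 605
_NRF2_CYS = (119, 235, 311, 316, 414, 506)
_KEAP1_LENGTH = 624
_KEAP1_CYS = (
    13, 14, 23, 38, 77, 151, 171, 196, 226, 241, 249, 257, 273, 288,
    297, 319, 368, 395, 406, 434, 489, 513, 518, 583, 613, 622, 624,
)


def _standin(name: str, length: int, cys_positions: tuple[int, ...]) -> ProteinRecord:
    letters = [_NON_CYS[i % len(_NON_CYS)] for i in range(length)]
    for p in cys_positions:
        letters[p - 1] = "C"
    return ProteinRecord(id=name, species="human", sequence="".join(letters))


def nrf2_standin() -> ProteinRecord:
    """Synthetic stand-in for canonical human Nrf2 (NFE2L2).

    Matches the canonical length (605 aa) and the six documented cysteine
    positions; every other residue is a deterministic synthetic filler, so
    only length- and cysteine-dependent statistics are meaningful.
    """
    return _standin("NRF2_HUMAN_synthetic", _NRF2_LENGTH, _NRF2_CYS)


def keap1_standin() -> ProteinRecord:
    """Synthetic stand-in for canonical human Keap1.

    Matches the canonical length (624 aa) and the 27 documented cysteine
    positions (including sensors C151/C273/C288); all other residues are
    deterministic synthetic filler.
    """
    return _standin("KEAP1_HUMAN_synthetic", _KEAP1_LENGTH, _KEAP1_CYS)
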