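# Methods

## Consensus disorder calling

Each predictor contributes one score per residue in [0, 1]. Binarization
is strict: a residue votes +1 (disordered) only when its score exceeds the
cutoff (default 0.5); a score exactly at the cutoff votes −1. Published
practice defines only the two open intervals (> 0.5 disordered, < 0.5
ordered), so the boundary had to be assigned; keeping "disordered" strict
is the conservative choice and the cutoff is configurable.

Votes are summed across predictors and a residue is called disordered when
the sum reaches a required level. The default is unanimity (+N of N),
which reproduces the +3-of-3 convention for three predictors; relaxed
thresholds (any value ≤ N with reachable parity) are supported but off by
default. Regions are maximal runs of consensus-disordered residues with
no minimum length by default (`min_length` is exposed; nothing in common
usage imposes a floor, and a floor would silently change region counts).

Percentages are reported half-up at two decimals (so 100·24/61 prints as
39.34); the unrounded value is retained on the summary object and used in
tests with tolerance 5e-3. BED export converts 1-based inclusive residue
intervals to 0-based half-open coordinates (start−1, end), preserving
interval widths.

Headline percent-disordered values for real proteins depend on which
external predictor versions produced the input tracks (PONDR in particular
exists in several variants); the package therefore treats such numbers as
input-dependent and validates the caller itself by (a) equivalence with a
brute-force per-residue oracle on randomized tracks and (b) exact recovery
of ground truth in the noise-free simulation limit.

## Composition and conservation

Cysteine content is 100 · count(C) / length per species; the cross-species
figure is the unweighted mean of per-species percents, so orthologs of
different lengths weigh equally. 'X' placeholders count toward length but
never match a target residue, which biases percents downward rather than
inventing matches.

Conservation is classified per reference cysteine through a consumed
alignment (the package never builds alignments). A reference position p
maps to the alignment column holding the p-th non-gap reference letter;
the species whose letter at that column equals the target residue are
counted, reference included, with gaps and substitutions both non-matching.
Classes: *complete* when all n species match; *high* when the count is at
least `high_threshold`; *low* otherwise. `high_threshold` has no default
and must be given explicitly: published analyses of this protein pair used
13-of-15 for one protein and 12-of-15 for the other, so any default would
bake in a judgment the caller should make.

## Inclusion quantification

The counting rules are the standard manual-scoring criteria, automated:

* a cell enters the denominator only if its nucleus is fully visible —
  operationalized as the connected component not touching any boundary
  pixel of the frame (strict reading of "clipped by the edge");
* a cell has inclusions when it shows at least one distinguishable focus.

Nuclei are segmented by a global Otsu threshold and 8-connected labeling;
components below `min_nucleus_area` (default 20 px) are treated as debris.
A constant nucleus channel yields zero cells with a warning rather than an
error. Touching nuclei merge into one label — a documented limitation of
connectivity-based segmentation; the synthetic generator avoids it by
construction and real data with dense monolayers would need a splitting
step out of scope here.

Manual scoring has no cell-boundary rule, so foci are attributed by the
simplest deterministic partition: every pixel belongs to the nearest
retained nucleus centroid (ties to the lower label). Foci are detected on
a difference-of-Gaussians band-pass (inner scale `spot_scale_px`, default
2 px ≈ the expected focus radius; outer scale 3×), which removes both the
diffuse cytoplasmic signal and per-cell expression differences. A peak
(local maximum with minimum separation `spot_scale_px`) counts as a focus
when it exceeds median + `k_mad`·MAD of the band-passed values within its
own cell region.

`k_mad` defaults to 8. The threshold is an extreme-value question, not a
per-pixel one: a cell region of ~10⁴ pixels contains hundreds of local
maxima of the smoothed noise field, whose maximum reaches ≈ 4.5 σ (≈ 6.7
MAD), while a genuine focus at the amplitudes of interest sits tens of MAD
above the median. k = 8 clears the noise extreme with margin and was
verified on synthetic truth to give zero false-positive and zero
false-negative cells at spot amplitudes of 5× and 10× the noise standard
deviation; k = 6 admits roughly three spurious cells per image under the
same conditions. Raising `k_mad` can only decrease per-cell counts
(monotonicity is property-tested).

Only presence/absence of foci per cell is scored; nuclear-vs-cytosolic
localization and 3-D stacks are out of scope.

## Synthetic generators

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; identical calls are bitwise identical.

* **Tracks** — scores drawn from a normal law centered at `mu_disordered`
  (default 0.8) inside the true segments and `mu_ordered` (default 0.2)
  outside, sd `sigma`, clipped to [0, 1]. Clipped-normal is the simplest
  bounded noise model; no predictor error model is published. At
  `sigma = 0` the consensus pipeline recovers the truth exactly, which
  anchors the recovery tests.
* **Orthologs** — the reference carries C exactly at the configured
  positions over a random non-C background; each other species retains
  each C independently with probability `p_conserve`, substituting a
  random non-C letter otherwise, and shares the background elsewhere.
  This deliberately ignores realistic evolution: conservation
  classification consumes only match/non-match structure. With
  `indel_rate > 0`, insertion columns (gap in the reference row, random
  letters elsewhere) are interleaved at Binomial(L+1, rate) slots and the
  true position→column map is emitted. The match count at a position is
  1 + Binomial(n−1, p), giving a closed-form oracle for recovery tests.
* **Images** — nuclei are non-overlapping disks (radius 8 px by default)
  with centers at least 4.5 radii apart, a configured fraction placed
  within one radius of an edge so the disk clips; the protein channel is a
  background level plus a smooth per-cell cytoplasmic halo plus, in a
  configured fraction of countable cells, `foci_per_cell` Gaussian spots
  (amplitude 60, σ 1.5 px over noise σ 6 by default — a 10× spot-to-noise
  ratio typical of a well-exposed punctum) placed 1.2–1.9 radii from the
  nucleus center; both channels get additive Gaussian noise and are
  clipped at zero. The 4.5-radius separation guarantees each cell's foci
  fall inside its own nearest-centroid region. Defaults give 45 nuclei on
  a 640×640 canvas, 20% border-clipped, hence 36 countable cells per
  field. The generator does not emulate texture, uneven illumination,
  point-spread blur of the nucleus channel, or touching nuclei, so passing
  recovery tests demonstrates the counting logic, not robustness to messy
  real micrographs.

## Canonical-protein stand-ins

`nrf2_standin()` and `keap1_standin()` are synthetic sequences carrying
the canonical human lengths (605 and 624 residues) and the literature-
documented cysteine positions (6 for Nrf2; 27 for Keap1, including the
sensor cysteines C151/C273/C288), with a deterministic non-cysteine filler
elsewhere. Cysteine counts and percentages depend only on length and
cysteine positions, so these statistics (0.99% and 4.33%) are exact; any
other statistic computed on the stand-ins is meaningless, and their ids
say "synthetic" to keep that visible.

## Problem sizes

The shipped tests and the acceptance script use 200 randomized track sets
(N ≤ 5, length ≤ 200), 200 simulated ortholog sets (15 species × 27
cysteines), and 20 micrographs per inclusion fraction at 640×640 px with
36 countable cells each — sizes at which the binomial and recovery checks
have comfortable power while a full run stays in the low minutes on one
CPU.

## Known limitations

* Touching nuclei merge; no watershed splitting.
* The focus detector's parameters are validated only against synthetic
  truth; real micrographs may need retuning of `spot_scale_px` and
  `k_mad`.
* Conservation uses strict identity; conservative substitutions score as
  non-matching.
* The pipeline consumes predictor tracks and alignments; it cannot audit
  how they were produced.
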