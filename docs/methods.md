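# Methods

This note documents the models, defaults and numerical choices behind
`zipswap`, and what the synthetic-data generators do and do not emulate.

## Differentially conserved residues (DCRs)

The sequence stage operates on a multiple sequence alignment whose rows are
partitioned into *specificity groups* — sets of orthologs or close paralogs
believed to share a substrate spectrum (e.g. the multi-metal ZIP8/ZIP14
branch versus the Zn-preferring ZIP4 branch of the LIV-1 subfamily).  A
column is flagged as a DCR when

1. every group's modal (consensus) residue reaches the within-group
   conservation threshold (`min_within_conservation`, default 1.0 — strict
   invariance; 0.9 is a reasonable relaxation for deep ortholog sets),
2. the target-group and reference-group consensuses differ, and
3. (optionally) the consensus pair is a *non-conservative* replacement,
   i.e. falls outside the classes {I/L/V/M, S/T, D/E, K/R, F/Y/W, N/Q}.
   The filter is off by default because "different at all" is the primitive
   definition; S/T is in the set because a Thr→Ser swap is conservative.

Each hit carries a swap mutation string (`Q180H`: target consensus,
1-based reference residue number, reference consensus), the elementary move
of specificity engineering.  Conventions and edge rules:

* Gaps never count toward a consensus; a column with more than 50% gaps in
  any group (`max_group_gap_fraction`) is excluded, as is any column where
  the reference sequence itself is gapped (no residue number to report).
* Modal ties break lexicographically and are recorded, so output is
  deterministic; columns whose consensus is the ambiguity code X are
  skipped.
* Alignment columns are 0-based internally; all reported positions use
  1-based reference numbering.
* Group labels are ordered alphabetically when the caller does not name the
  target/reference groups explicitly, which makes the scan invariant to row
  order.

Pairwise identity (used for ortholog selection at the conventional 50%
cutoff) is matches / (columns where neither sequence is a gap).  For
unaligned inputs a global Needleman–Wunsch alignment (BLOSUM62, gap open
−11, extend −1 — the standard protein defaults) is computed internally;
multi-sequence alignment itself is always an input, produced by an external
aligner.  Identity is computed in a canonical argument order so it is
exactly symmetric even when the optimal alignment is degenerate.

Subfamily column composition reports, per queried reference position, the
frequency vector over the 20 standard amino acids among non-gap residues
(sums to 1), with the gap/unknown fraction reported separately.

## Structural mapping

Structure models of distinct conformations (inward-facing, IFC;
outward-facing, OFC) are distinct PDB inputs carrying labels; the package
never interpolates between conformations.  Only Cα atoms are consulted:
altlocs resolve to the highest-occupancy copy (tie → 'A'), residues without
a Cα are skipped with a warning, insertion codes are rejected, and residue
numbering is taken verbatim from the file.

Pair distances are Euclidean Cα–Cα distances; the interesting readout for
an elevator-type transporter is how a residue pair's distance changes
between conformations (a pair that approaches only in the OFC is a
candidate *conditional* selectivity filter).

Pore proximity uses a geometric stand-in for the visually assigned
"along / at the entrance of / away from the transport pathway" classes: the
pathway axis runs between two user-chosen anchor residues (no canonical
anchors exist, so they are configuration), and a residue within the radial
cutoff (default 8 Å) is "pore" inside the anchor span and "entrance" beyond
either anchor; radially distant residues are "lipid".  Treating both mouths
of the pathway as "entrance" makes the classification independent of anchor
order.

Contact checking consumes a covariance-analysis export (CSV with columns
i, j, score); matching is unordered, and ranks are computed among rows that
pass the score and sequence-separation filters.

## Dual-isotope internal-competition assay

Both ⁶⁵Zn and ¹⁰⁹Cd are added to the same well and counted simultaneously
in two gamma-energy windows.  The within-well Zn/Cd ratio is then invariant
to any common multiplicative nuisance (transporter expression, cell number,
wash losses) — the implementation preserves this exactly, and a property
test asserts it to machine precision.

Calibration: ⁶⁵Zn spills into the Cd window, so Zn-only standards fit a
linear crosstalk slope *s* (Cd-window counts per Zn-window count) by
zero-intercept least squares, `s = Σxy/Σx²`.  The intercept is fixed at
zero because well background is removed downstream by empty-vector
subtraction, not by the calibration line; the free-intercept fit is carried
as a diagnostic.  Corrected Cd counts are `cd − s·zn`; negative values are
clipped to zero with a flag for display, but aggregation uses the unclipped
values so averages stay unbiased.

Activity per experiment = mean(construct wells) − mean(empty-vector wells),
per window, with Cd corrected first.  Relative activity and relative Zn/Cd
selectivity are expressed as percent of wild type *within the same
experiment* (WT ≡ 100 by construction); the cross-experiment summary is the
mean of per-experiment values, mirroring the one-dot-per-experiment
presentation of replicate experiments.  Experiments where a construct's Cd
activity is ≤ 0 yield no defined ratio and are excluded with a flag.
Significance uses the classic equal-variance two-sided Student's t test
(Welch optional).

## Hill kinetics and derived quantities

Uptake curves are fitted with v = Vmax·Sⁿ/(Kⁿ+Sⁿ) by unweighted nonlinear
least squares over pooled replicate points (1/v² weighting is exposed).
Initialisation: Vmax₀ = max rate, K₀ interpolated at half-max, n₀ = 1 with
multi-start over n₀ ∈ {0.5, 1, 2}; bounds Vmax ∈ (0, 10·max rate],
K ∈ (0, 100·max S], n ∈ [0.3, 4].  Standard errors are asymptotic (from the
Jacobian at the optimum); a fit that does not converge raises rather than
reporting parameters.  K is labelled K_M in tabular output for continuity
with kinetic tables even though it is the Hill half-saturation constant.

The specificity constant Vmax/K carries a delta-method SE;
`specificity_fold(a, b) = (Vmax_a/K_a)/(Vmax_b/K_b)` is the fold by which
b's specificity constant is lower than a's, so a 7× Vmax drop combined
with a 2× K rise compounds to a 14-fold specificity loss.

Competition is summarised as percent change of paired tracer transport,
`100·(with − without)/without` (negative = inhibition); no IC₅₀/Ki model is
fitted because single-dose competition is the designed readout.  ICP-MS
Mn/P molar ratios come from per-element linear standard curves (default
series 100…3.125 ng/mL) and atomic weights (Mn 54.938, P 30.974 g/mol);
phosphorus at or below detection is an error since it is the denominator
normalising for cell material.

## Synthetic data: what it emulates, and what it does not

All generators take an explicit seed (numpy `default_rng`), write only
standard text formats, and serialise their ground truth in a JSON sidecar
that `zipswap verify` re-checks against the written files.  Defaults encode
the study conditions the pipeline targets:

* **Families** — two groups of 8 sequences × 200 columns sharing one
  ancestral sequence; planted columns are invariant within groups and
  differ across them; background columns drift i.i.d. with per-member
  mutation probability 0.3.  No tree-structured evolution, indels, or
  rate heterogeneity: real alignments have phylogenetic correlation that
  can make relaxed conservation thresholds necessary, so planted-column
  recovery here validates the scanner's logic, not its behaviour on
  divergent real families.
* **Assay** — 5 experiments × 3 replicates per construct; Zn-window signal
  20 000 cpm for wild type, Cd 15 000 cpm, detector background 150 cpm,
  crosstalk slope 0.235; per-transfection expression factor lognormal
  (CV 15%) times a per-well factor (CV 5%) — the nuisance the internal
  competition cancels; counts Poisson.  Construct multipliers (WT 1/1,
  double variant 1.2/0.30, quadruple variant 1.1/0.147) produce relative
  selectivities of 100%, 400% and ~750%, the phenotype scales the assay is
  designed to resolve.  Standards: 0–20 µM at 5 000 cpm/µM, so non-zero
  wells expect ≥ 1.25e4 counts.
* **Curves** — Hill parameters per construct/metal encoding the measured
  fold changes (Zn: Vmax ~4× up, K ~2× up; Cd: K 6× up, Vmax unchanged;
  Fe: Vmax 7× down, K 2× up), concentrations 1–40 µM, triplicates,
  multiplicative Gaussian noise with CV 10%.
* **Structures** — a 3.8 Å-step Cα random walk with the designated pair
  placed at exactly 14.9 Å (IFC) and 7.5 Å (OFC) along a fixed axis-aligned
  direction; coordinates are snapped to the 0.001 Å PDB grid so requested
  distances with ≤ 3 decimals round-trip exactly.  These are geometric
  toys, not protein-like folds.

Counting noise is Poisson throughout (a Gaussian approximation is implied
at the count scales used but never substituted).  The simulators share no
code with the estimators they exercise beyond the Hill model definition.

## Problem sizes and tolerances in the test suite

Crosstalk slope recovery averages 1 000 independent 5-point standard
series; at ≥ 1e4 expected counts per well the estimator's bias from Poisson
noise in the regressor is O(Σμ/Σμ²) ≈ 1e−5 and the replicate mean recovers
0.235 to three decimals.  Hill-recovery medians use 200–500 simulated
curves (6 levels × 3 replicates, CV 10%): median relative error ≤ 10% for
K and ≤ 5% for Vmax, median n̂ within [1, 2] for a truth of 1.5.  Type-I
error of the t test is checked on 10 000 vectorised null replicates at
α = 0.05 ± 0.01.  Rigid-motion invariance uses random orthogonal
transforms; distance identities are asserted at 1e−9 Å.

## Known limitations

* The accession-fixed checks (ZIP8/ZIP14 48%, ZIP8/ZIP4 31%, the 35-DCR
  LIV-1 scan) run only when the published NCBI sequences are placed under
  `data/ncbi/`; the package does not redistribute or fetch them.
* The geometric pore/entrance rule is a stand-in for a visual assignment;
  anchor choice matters and no side-chain atoms are considered.
* No homology modelling, structure prediction, coupling inference, MD or
  free-energy machinery: structural models and covariance tables are
  consumed, never produced.
* The exact criteria reproducing a particular published DCR count on real
  families (conservation threshold, gap policy, domain boundaries) are a
  declared choice; the defaults here are the strict-invariance reading.
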