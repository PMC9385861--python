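# Methods

This note documents the models, conventions and numerical choices behind
`deepdom`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Peak alignment

Peaks from all samples are pooled, sorted by m/z, and chained by single
linkage: consecutive peaks whose relative gap is ≤ `tol_ppm` (computed
relative to the smaller mass; default 0.5 ppm) join one cluster. Because
single linkage can chain drifting masses indefinitely, each cluster is
greedily split so that no piece spans more than 2 × `tol_ppm` from its
lowest member. If a cluster contains two peaks from the same sample, the
more intense one represents the sample and the other is demoted to its own
feature — per-sample uniqueness is required downstream. The consensus mass
is the intensity-weighted mean of member masses. Demoted and span-split
features may legitimately sit within tolerance of a sibling feature; the
minimum-separation invariant is enforced among all other features.
Features present in only one sample ("singlets") are removed before
assignment. For ≤ 500 peaks the fast path is tested for exact agreement
with single-linkage clustering on the full pairwise ppm graph.

## Formula assignment

Negative-mode electrospray peaks are treated as [M−H]⁻, so the neutral
mass is the measured m/z plus one proton (1.00727646 Da); a `ion_mode=
"neutral"` flag accepts pre-neutralized input. Candidates are enumerated
within C₁₋₁₀₀H₁₋₁₀₀O₀₋₇₀N₀₋₄S₀₋₂P₀₋₁ (masses ≤ 1000 Da), requiring an
integer, non-negative double-bond equivalent DBE = 1 + C − H/2 + (N+P)/2
and (by default, toggleable) O ≤ C + 2, a standard sanity cap for natural
organic matter. The filter chain is: (a) heteroelement rule — candidates
with N+S+P > 3 are rejected unless the excess is purely nitrogen up to N₄;
(b) isotopologue verification — when a companion feature exists at the
parent mass + 1.0033548 (¹³C), +0.9970349 (¹⁵N) or +1.9957959 Da (³⁴S)
within tolerance, its summed-intensity ratio to the parent must fall
within a relative tolerance (default 500 ‰) of 0.0107·C, 0.00364·N or
0.0442·S; a missing companion only disqualifies a candidate when the
expected companion would exceed the method detection limit (S/N 3; the
`sn` column when present, intensity over the sample's minimum positive
intensity otherwise); (c) the surviving candidate with the smallest
absolute ppm error wins, ties broken by fewer heteroatoms, then fewer
atoms (parsimony). Candidates failing isotopologue verification are
demoted (assigned unverified) by default rather than dropped; a flag
switches to removal. After assignment, features recognized as the heavy
isotopologue companion of an assigned parent, and features matching the
four-contaminant list, are removed from the annotated output; unassigned
features are retained but excluded from formula-level analyses.

## Preprocessing

The fixed order is: normalize each sample to its intensity sum → set a
common detection limit (the highest per-sample minimum nonzero normalized
intensity; entries strictly below are zeroed, entries at the threshold
kept) → keep features occurring in ≥ 3 samples. The matrix is *not*
renormalized after zeroing by default, so retained peaks keep a
cross-sample-comparable scale; a flag renormalizes. Replicate spectra are
averaged per group (arithmetic mean of columns, then renormalized). The
detection-limit harmonization runs after singleton removal; this order is
a package choice where both orders are defensible.

## Molecular descriptors

All per-sample descriptors weight by normalized intensity among annotated
features only (weights renormalized over that subset). MLB_w counts
intensity with H/C strictly above 1.5 — "above the boundary" read as
strict, so a formula at exactly H/C = 1.5 is not labile. AI_mod values
with negative numerator or non-positive denominator are clamped to 0.
The seven van Krevelen class regions are used exactly as printed,
including their deliberate overlaps (e.g. O/C ≤ 0.29 at H/C exactly 1.6,
or O/C exactly 0.6 at H/C ≥ 1.5); a formula matching zero or several
regions is "unclassified". The AbioS marker list is a configuration input
(an externally published 15-formula reference list); the default is empty
and `abios_pct` is then 0.

## Multivariate statistics

Bray–Curtis dissimilarities use d = 1 − 2Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ). NMDS is
stress majorization with monotone regression (Kruskal stress-1), run from
a classical-scaling start plus random restarts (default 20; convergence
at stress change < 1e-6); non-convergence flags the result. db-RDA
decomposes the dissimilarity matrix into principal coordinates — negative
eigenvalues are dropped and their summed magnitude recorded (no Lingoes
correction by default, matching common practice for Bray–Curtis) — then
regresses the coordinates on standardized predictors; explained fraction
is constrained over total inertia, pseudo-F uses the predictor matrix
rank (pseudo-inverse for collinear predictors, with a warning), and the
p-value permutes the sample rows of the predictor table. The Procrustes
test scales both configurations to unit total variance (symmetric
scaling, so m² is comparable regardless of argument order) and counts
permutations with m² at most the observed value.

## Interdomain network

Molecular-formula and ASV tables are filtered (present in ≥ 5 samples;
ASVs with maximum relative abundance < 0.1 % removed), zeros replaced by
the feature's minimum nonzero value / 10, and clr-transformed *per block*
before stacking — transforming jointly changes ρ and is regression-tested
as different. ρ is computed as 2·cov(gᵢ,gⱼ)/(var gᵢ + var gⱼ) on clr rows
(sample variance, n−1); zero-variance features get ρ = 0 with a warning.
The |ρ| cutoff is selected on a grid (0.30–0.99, step 0.01) by a
permutation FDR: permutations shuffle the sample labels of the ASV block
only, preserving each block's internal covariance; FDR(c) is the
permutation-mean count of cross-block |ρ| ≥ c over the observed count,
defined as 0 when nothing is observed at c, and the smallest cutoff with
FDR below the 5 % target wins (the grid maximum, with a warning,
otherwise). Edges with |ρ| ≥ cutoff — positive and negative — enter an
unweighted graph (ρ and sign kept as edge attributes); modules come from
deterministic fast-greedy (CNM) modularity maximization on topology, with
module ids ordered by size. Node roles use the within-module degree
z-score (population standard deviation; z = 0 for zero-spread or
singleton modules) and participation coefficient P = 1 − Σₛ(k_is/kᵢ)²
(P = 0 for isolated nodes). The canonical scheme is the default:
peripheral (z ≤ 2.5, P ≤ 0.62), connector (z ≤ 2.5, P > 0.62), module hub
(z > 2.5, P ≤ 0.62), network hub (z > 2.5, P > 0.62). A `"printed"`
variant reproduces an overlapping published threshold table in which
module hubs require P ≥ 0.62; under it the z > 2.5, P < 0.62 corner has
no published name and is labeled "unclassified".

## Isotope and bulk-chemistry arithmetic

Radiocarbon ages use the physical 5730-year half-life (mean life ≈ 8267
yr): age = τ·ln(100/pMC). This choice, rather than the Libby 5568-year
convention (available by flag), makes pMC 60 correspond to ≈ 4220 years.
pMC > 100 is modern carbon: age 0 with a warning. No calibration-curve
correction is applied — these are uncalibrated mean residence times.
DON = TDN − (nitrate + nitrite + ammonium), clamped at 0 with a warning.
Molar C/N uses DOC/DON when inorganic nitrogen is supplied and DOC/TDN
otherwise, with the basis reported alongside the value. The bundled
water-chemistry table carries per-sample DOC, TDN and extracted-DOC
concentrations for two surface-seawater and eighteen groundwater samples;
extraction efficiency is recomputed as 100·extracted/DOC.

## Synthetic data generator

The generator emulates the study conditions the package targets: a
two-endmember mixing transect (a Baltic-like surface pool and an old
saline pool) whose formula pools share a dominant lignin-like terrigenous
core (~165 formulas) — so shared-core formulas appear in every sample —
with the surface pool enriched in tannin-like and condensed-aromatic
formulas and the saline pool in aliphatic and S-containing ones.
Intensities mix the endmember profiles at a per-sample fraction with
multiplicative lognormal noise (relative intensities are positive and
heteroscedastic); m/z values get Gaussian ppm error truncated at 3 sd
(default sd 0.15 ppm, keeping deviations within the 0.5-ppm join
tolerance); ¹³C isotopologues are simulated by default (¹⁵N/³⁴S are the
dominant verification channel's optional complements and off by default);
the four contaminant formulas are spiked into every sample; and the eight
hydrochemistry variables plus DOC are affine in the mixing fraction with
small relative noise (default 2 %). Default transect size is 15 samples,
matching the borehole-level dataset size the statistics are designed for.

The ASV generator plants association modules: all members of a module
(ASVs and MFs) share one standard-normal latent factor across samples,
scaled by `latent_strength`, plus independent log-scale measurement noise;
background features carry their own independent lognormal variation
(log-sd 0.8). That independent background variation is part of the model:
without it, the clr centering term would make *all* background profiles
mutually proportional in the noise-free limit, an artifact rather than a
null. At zero measurement noise, module members are exactly proportional
(ρ = 1) and module recovery should be perfect; at `latent_strength` 0 the
planted links are indistinguishable from background.

What passing synthetic tests shows — and does not. They demonstrate that
the implementation applies the stated rules exactly (oracle equivalence),
that the statistics are calibrated (uniform null p-values, controlled
null FDR), and that planted structure of realistic size is recovered.
They do not demonstrate robustness to instrument drift, batch effects
between acquisition runs, chimeric ASVs, non-lognormal intensity error,
or chemistry that is not a two-endmember mixture — real spectra violate
all of these to some degree.

## Problem sizes and determinism

Simulated problem sizes are chosen to resolve each question at desk
scale: ~230-formula endmember pools (≈ 590 peaks/sample with
isotopologues), 15-sample transects for ordination (8 predictors, the
regime where a mixing gradient is identifiable), 10 planted modules with
3 ASVs + 8 MFs each over 10 samples for network recovery, and 100
replicates for calibration checks. All randomness flows through explicit
integer seeds into `numpy.random.default_rng`; no global state. Pipeline
reruns with the same config are byte-identical, which is tested.

## Known limitations

- Only [M−H]⁻ singly-charged ions; no adducts, multiply-charged species
  or isotopic fine structure.
- The isotopologue detectability bound uses the sample's minimum positive
  intensity as a noise-floor proxy when no S/N column is available; with
  very sparse spectra this proxy is coarse.
- The FDR grid search returns the grid maximum when no cutoff meets the
  target, which on strong-signal data can admit more edges than a finer
  grid would.
- `fdr_cutoff` supports exactly two blocks (MF and ASV); multi-omics
  stacking beyond two compositional blocks is out of scope.
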