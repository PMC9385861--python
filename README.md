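# deepdom

Analysis toolkit for dissolved organic matter (DOM) in deep continental
groundwaters: ultrahigh-resolution mass-spectrometry formula assignment, DOM
molecular descriptors, multivariate hydrochemistry statistics, and
microbe–metabolite proportionality networks — plus a synthetic-data
generator with known ground truth so every stage is testable without
instrument data.

## Who it is for

Geochemists and microbial ecologists working with FT-ICR-MS spectra of
solid-phase-extracted DOM alongside 16S rRNA amplicon (ASV) tables and
water chemistry, who want a reproducible, scriptable version of the
standard desk analysis:

1. **Peak alignment** — per-sample (m/z, intensity, S/N) lists are joined
   across samples by a "fast join" at 0.5 ppm (single-linkage chaining with
   a 2×-tolerance span cap); singlet peaks are removed.
2. **Formula assignment** — each consensus neutral mass (measured [M−H]⁻
   m/z + 1.00727646 Da) is matched against all CHNOSP compositions within
   C₁₋₁₀₀H₁₋₁₀₀O₀₋₇₀N₀₋₄S₀₋₂P₀₋₁ at 0.5 ppm, requiring integer DBE ≥ 0,
   rejecting > 3 heteroatoms (except pure N up to N₄), verifying ¹³C/¹⁵N/³⁴S
   isotopologue companions, and removing four ubiquitous contaminants
   (C₁₆H₃₂O₂, C₁₂H₂₆O₄S, C₁₇H₂₈O₃S, C₁₀H₁₅NO₂S).
3. **Descriptors** — intensity-weighted elemental ratios (H/C_MF, O/C_MF,
   S/C_MF, …), weighted mass, the modified aromaticity index
   AI_mod = (1 + C − ½O − S − ½(H+N+P)) / (C − ½O − N − S − P), the
   lability fraction MLB_w (intensity with H/C > 1.5), van Krevelen
   compound classes, and the contribution of a user-supplied AbioS
   (abiotic sulfurization marker) list.
4. **Multivariate statistics** — Bray–Curtis dissimilarities, NMDS,
   distance-based redundancy analysis (db-RDA) with permutation inference,
   and Procrustes congruence tests.
5. **Interdomain network** — molecular formulas and ASVs are filtered by
   prevalence, zero-replaced (min/10), clr-transformed *separately*, and
   linked by the proportionality measure
   ρ(i,j) = 1 − var(gᵢ−gⱼ)/(var gᵢ + var gⱼ); the |ρ| cutoff is chosen by a
   permutation false-discovery-rate estimate, modules by fast-greedy
   modularity, and node roles by within-module degree z-score and
   participation coefficient P (peripheral / connector / module hub /
   network hub at z = 2.5, P = 0.62).
6. **Isotope arithmetic** — radiocarbon pMC → residence time
   (age = τ·ln(100/pMC), τ = 5730 yr / ln 2), δ¹³C DIC−DOC offsets, DON =
   TDN − inorganic N, and solid-phase extraction efficiency.

## Worked example

```python
import numpy as np
import deepdom as dd

peaklists, chemistry, truth = dd.generate_sample_peaklists(
    dd.default_endmembers(seed=1), np.linspace(1.0, 0.0, 15),
    noise_cv=0.05, seed=4)
aligned = dd.remove_singletons(dd.join_mass_lists(peaklists, tol_ppm=0.5))
d = dd.bray_curtis(dd.normalize_to_sum(aligned.intensities))
rda = dd.dbrda(d, chemistry[list(dd.synthetic.HYDROCHEM_VARS)],
               n_perm=999, seed=0)
print(f"hydrochemistry explains {100 * rda.explained_fraction:.1f} % "
      f"(pseudo-F = {rda.pseudo_F:.2f}, p = {rda.p_value:.4f})")
```

prints

```
hydrochemistry explains 99.7 % (pseudo-F = 255.19, p = 0.0010)
```

meaning that on a two-endmember mixing transect whose chemistry is affine
in the mixing fraction, the constrained ordination attributes nearly all
Bray–Curtis variability in DOM composition to the eight hydrochemistry
variables — the mixing-dominated regime this package is designed to probe.
The `examples/` directory has one short script per capability
(simulation, alignment/assignment, descriptors, ordination, network,
isotopes), each printing the numbers it computes and what they mean.

A `deepdom` command-line entry point runs the file-based pipeline stage by
stage (`deepdom run-all --seed 1 --out-dir run/`), writing every stage
output plus a JSON run report with feature counts at each filter step.

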