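"""Ordination of DOM composition and its link to hydrochemistry.

Bray-Curtis dissimilarities -> NMDS for visual gradients, db-RDA to ask
how much compositional variability the eight hydrochemistry variables
explain, and a Procrustes test between two configurations.
"""

import numpy as np

import deepdom as dd
from deepdom.synthetic import HYDROCHEM_VARS

peaklists, chemistry, _ = dd.generate_sample_peaklists(
    dd.default_endmembers(seed=1), np.linspace(1.0, 0.0, 15),
    noise_cv=0.05, seed=4)
aligned = dd.remove_singletons(dd.join_mass_lists(peaklists, 0.5))
profiles = dd.normalize_to_sum(aligned.intensities)

d = dd.bray_curtis(profiles)
ordination = dd.nmds(d, k=2, n_starts=10, seed=0)
print(f"NMDS stress-1 = {ordination.stress:.4f} (converged: {ordination.converged})")

rda = dd.dbrda(d, chemistry[list(HYDROCHEM_VARS)], n_perm=999, seed=0)
print(f"db-RDA: hydrochemistry explains {100 * rda.explained_fraction:.1f} % "
      f"of DOM variability (pseudo-F = {rda.pseudo_F:.2f}, p = {rda.p_value:.4f})")
# Chemistry is affine in the mixing fraction here, so the constrained
# ordination recovers the dominant mixing signal.

second = dd.nmds(d, k=2, n_starts=10, seed=99)
pro = dd.procrustes_test(ordination, second, n_perm=999, seed=0)
print(f"Procrustes m2 between two NMDS runs = {pro.m2:.4f} (p = {pro.p_value:.4f})")
# m2 near 0: the two configurations agree up to rotation/scaling.
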