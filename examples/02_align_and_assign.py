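"""Align multi-sample peak lists and assign CHNOSP molecular formulas.

Peaks are joined across samples at 0.5 ppm, singletons dropped, then each
consensus mass is annotated with the best valid elemental formula after
heteroelement, isotopologue and contaminant screening.
"""

import numpy as np

import deepdom as dd

peaklists, _, truth = dd.generate_sample_peaklists(
    dd.default_endmembers(seed=1), np.linspace(1.0, 0.0, 8), seed=2)

aligned = dd.join_mass_lists(peaklists, tol_ppm=0.5)
aligned = dd.remove_singletons(aligned)
annotated = dd.assign_formulas(aligned)

print("filter chain:", annotated.filter_log)
n_ann = int(annotated.annotated.sum())
print(f"{n_ann} of {len(annotated.features)} features carry a formula")
print(annotated.features.loc[annotated.annotated,
                             ["mz", "formula", "error_ppm", "dbe", "compound_class"]]
      .head(8).round(4).to_string(index=False))
# error_ppm is the recomputed deviation of the formula's exact mass from
# the measured neutral mass; every assignment stays within +/-0.5 ppm.
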