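"""Per-sample molecular descriptors of DOM composition.

Intensity-weighted elemental ratios (H/C_MF, O/C_MF, ...), mean mass,
weighted aromaticity (AI_mod), the molecular lability boundary fraction
MLB_w (share of intensity above H/C = 1.5), the contribution of a
user-supplied AbioS reference list (sulfurized-DOM markers), and compound
class fractions. Weights are normalized intensities among annotated
(formula-carrying) features of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .assignment import AnnotatedMatrix
from .formulas import COMPOUND_CLASSES, MolecularFormula

__all__ = [
    "SampleDomSummary",
    "MLB_BOUNDARY",
    "weighted_sample_summary",
    "sample_summary_table",
    "group_contrast",
]

#: Molecular lability boundary on H/C; "above" is read strictly.
MLB_BOUNDARY = 1.5

_CLASS_COLUMNS = COMPOUND_CLASSES + ("unclassified",)


@dataclass
class SampleDomSummary:
    """Intensity-weighted molecular descriptors of one sample."""

    sample_id: str
    hc_mf: float
    oc_mf: float
    nc_mf: float
    sc_mf: float
    pc_mf: float
    mz_mf: float
    ai_mod_w: float
    mlb_w: float
    abios_pct: float
    class_fractions: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        base = {k: getattr(self, k) for k in
                ("hc_mf", "oc_mf", "nc_mf", "sc_mf", "pc_mf", "mz_mf",
                 "ai_mod_w", "mlb_w", "abios_pct")}
        base.update({f"class_{c}": self.class_fractions.get(c, 0.0) for c in _CLASS_COLUMNS})
        return pd.Series(base, name=self.sample_id)


def weighted_sample_summary(matrix: AnnotatedMatrix, sample: str,
                            abios_list: Iterable[MolecularFormula] = ()) -> SampleDomSummary:
    """Descriptors of one sample, weighted by normalized intensity among
    annotated features present in that sample."""
    if sample not in matrix.intensities.columns:
        raise KeyError(f"unknown sample {sample!r}")
    ann = matrix.annotated.to_numpy()
    inten = matrix.intensities[sample].to_numpy(float)
    w = np.where(ann, inten, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"sample {sample!r} has no annotated intensity")
    w = w / total
    feats = matrix.features
    abios = {str(f) for f in abios_list}

    hc = feats["hc"].to_numpy(float)
    mlb = float(w[(hc > MLB_BOUNDARY) & (w > 0)].sum())
    class_lbl = feats["compound_class"].to_numpy(object)
    class_fr = {c: float(w[class_lbl == c].sum()) for c in _CLASS_COLUMNS}

    def wmean(col: str) -> float:
        return float(np.nansum(w * feats[col].to_numpy(float)))

    return SampleDomSummary(
        sample_id=sample,
        hc_mf=wmean("hc"), oc_mf=wmean("oc"), nc_mf=wmean("nc"),
        sc_mf=wmean("sc"), pc_mf=wmean("pc"),
        mz_mf=wmean("neutral_mass"),
        ai_mod_w=wmean("ai_mod"),
        mlb_w=mlb,
        abios_pct=100.0 * float(w[np.isin(feats["formula"].to_numpy(object), list(abios))].sum()),
        class_fractions=class_fr,
    )


def sample_summary_table(matrix: AnnotatedMatrix,
                         abios_list: Iterable[MolecularFormula] = ()) -> pd.DataFrame:
    """One row of descriptors per sample."""
    abios = tuple(abios_list)
    rows = [weighted_sample_summary(matrix, s, abios).as_series()
            for s in matrix.sample_ids]
    out = pd.DataFrame(rows)
    out.index.name = "sample"
    return out


def group_contrast(matrix: AnnotatedMatrix, groups: Mapping[str, str], metric: str,
                   abios_list: Iterable[MolecularFormula] = ()) -> pd.DataFrame:
    """Mean +/- sd of a descriptor per sample group (e.g. water type).

    ``metric`` names a column of :func:`sample_summary_table`
    (``sc_mf``, ``mlb_w``, ``ai_mod_w``, ``class_lignin_like``, ...).
    """
    table = sample_summary_table(matrix, abios_list)
    if metric not in table.columns:
        raise KeyError(f"unknown metric {metric!r}; available: {list(table.columns)}")
    unmapped = [s for s in table.index if s not in groups]
    if unmapped:
        raise ValueError(f"samples without a group: {unmapped}")
    table = table.assign(group=[groups[s] for s in table.index])
    out = (table.groupby("group")[metric]
           .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                n="count"))
    return out
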