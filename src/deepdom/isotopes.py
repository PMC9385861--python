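"""Bulk-chemistry and carbon-isotope arithmetic.

Radiocarbon percent-modern-carbon (pMC) to mean residence time, stable
carbon isotope offsets between dissolved inorganic and organic carbon,
dissolved organic nitrogen from total minus inorganic nitrogen, and
solid-phase extraction (SPE) efficiency on a carbon basis. A bundled
water-chemistry fixture table (DOC/TDN/extracted DOC per borehole sample)
supports the group summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CarbonIsotopeRecord",
    "BulkChemRecord",
    "HALF_LIFE_CARBON14",
    "HALF_LIFE_LIBBY",
    "pmc_to_age",
    "age_to_pmc",
    "delta_dic_doc",
    "don",
    "extraction_efficiency",
    "load_water_chemistry",
    "spe_efficiency_by_group",
]

#: Physical 14C half-life (years); the Libby convention is exposed as a flag.
HALF_LIFE_CARBON14 = 5730.0
HALF_LIFE_LIBBY = 5568.0

_MOLAR_MASS_C = 12.011
_MOLAR_MASS_N = 14.007


def pmc_to_age(pmc: float, half_life: float = HALF_LIFE_CARBON14) -> float:
    """Mean residence time (years) from percent modern carbon.

    age = tau * ln(100 / pMC) with tau = half_life / ln 2. Values above
    100 pMC are modern (post-bomb or recent) carbon and return 0 with a
    warning.
    """
    if not np.isfinite(pmc) or pmc <= 0:
        raise ValueError(f"pMC must be positive, got {pmc}")
    if pmc > 100:
        warnings.warn(f"pMC {pmc} > 100: modern carbon, age set to 0", stacklevel=2)
        return 0.0
    tau = half_life / math.log(2)
    return tau * math.log(100.0 / pmc)


def age_to_pmc(age: float, half_life: float = HALF_LIFE_CARBON14) -> float:
    """Inverse of :func:`pmc_to_age` on ages >= 0."""
    if age < 0:
        raise ValueError("age must be non-negative")
    tau = half_life / math.log(2)
    return 100.0 * math.exp(-age / tau)


@dataclass
class CarbonIsotopeRecord:
    """pMC and delta-13C of the inorganic (DIC) and organic (DOC) carbon
    pools of one sample; all deltas in permil vs PDB."""

    sample_id: str = ""
    pmc_doc: float | None = None
    pmc_dic: float | None = None
    d13c_doc: float | None = None
    d13c_dic: float | None = None
    d13c_spe_doc: float | None = None

    @property
    def age_doc(self) -> float | None:
        return pmc_to_age(self.pmc_doc) if self.pmc_doc is not None else None

    @property
    def age_dic(self) -> float | None:
        return pmc_to_age(self.pmc_dic) if self.pmc_dic is not None else None

    @property
    def delta13c_dic_doc(self) -> float | None:
        return delta_dic_doc(self)


def delta_dic_doc(record: CarbonIsotopeRecord) -> float | None:
    """Delta13C(DIC) - delta13C(DOC); negative when DIC is isotopically
    lighter than DOC. None (flagged) when either value is missing."""
    if record.d13c_dic is None or record.d13c_doc is None:
        warnings.warn(f"sample {record.sample_id!r}: missing delta13C value", stacklevel=2)
        return None
    return record.d13c_dic - record.d13c_doc


@dataclass
class BulkChemRecord:
    """Bulk DOC/nitrogen chemistry of one sample (mg L^-1)."""

    sample_id: str = ""
    doc: float | None = None
    tdn: float | None = None
    nitrate: float | None = None
    nitrite: float | None = None
    ammonium: float | None = None
    extracted_doc: float | None = None

    @property
    def don(self) -> float | None:
        return don(self)

    @property
    def extraction_efficiency(self) -> float:
        return extraction_efficiency(self)

    @property
    def cn_molar(self) -> tuple[float, str] | None:
        """Molar C/N ratio: (value, basis) where basis is "DON" when
        inorganic nitrogen is available, else "TDN"."""
        if self.doc is None:
            return None
        d = self.don
        if d is not None and d > 0:
            return ((self.doc / _MOLAR_MASS_C) / (d / _MOLAR_MASS_N), "DON")
        if self.tdn is not None and self.tdn > 0:
            return ((self.doc / _MOLAR_MASS_C) / (self.tdn / _MOLAR_MASS_N), "TDN")
        return None


def don(record: BulkChemRecord) -> float | None:
    """Dissolved organic nitrogen: TDN - (nitrate + nitrite + ammonium),
    clamped at 0. None (flagged) when a term is missing."""
    terms = (record.tdn, record.nitrate, record.nitrite, record.ammonium)
    if any(t is None for t in terms):
        warnings.warn(f"sample {record.sample_id!r}: missing nitrogen term for DON",
                      stacklevel=2)
        return None
    value = record.tdn - (record.nitrate + record.nitrite + record.ammonium)
    if value < 0:
        warnings.warn(f"sample {record.sample_id!r}: inorganic N exceeds TDN; DON set to 0",
                      stacklevel=2)
        return 0.0
    return value


def extraction_efficiency(record: BulkChemRecord) -> float:
    """Solid-phase extraction efficiency on a carbon basis:
    100 x extracted DOC / DOC."""
    if record.doc is None or record.doc <= 0:
        raise ValueError(f"sample {record.sample_id!r}: DOC must be positive")
    if record.extracted_doc is None:
        raise ValueError(f"sample {record.sample_id!r}: extracted DOC missing")
    return 100.0 * record.extracted_doc / record.doc


def load_water_chemistry(path: str | Path | None = None) -> pd.DataFrame:
    """Load the bundled per-sample water-chemistry table (or a user CSV of
    the same schema): borehole, water type, sampling date, DOC and TDN
    (mg L^-1, with sds) and the solid-phase-extracted DOC."""
    if path is None:
        ref = resources.files("deepdom.data") / "table1_water_chemistry.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"borehole", "water_type", "group", "doc_mgL", "extracted_doc_mgL"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"water chemistry table missing columns {sorted(missing)}")
    return df


def spe_efficiency_by_group(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute per-row SPE efficiency and summarize mean/sd/n per group
    (surface seawater vs deep groundwater)."""
    df = load_water_chemistry() if table is None else table
    eff = df.apply(lambda r: extraction_efficiency(
        BulkChemRecord(sample_id=str(r["borehole"]), doc=r["doc_mgL"],
                       extracted_doc=r["extracted_doc_mgL"])), axis=1)
    out = df.assign(efficiency_pct=eff).groupby("group")["efficiency_pct"].agg(
        mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0, n="count")
    return out
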