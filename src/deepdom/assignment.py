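"""Molecular-formula assignment to aligned FT-ICR-MS masses.

Candidate CHNOSP formulas are enumerated within element windows
(C1-100 H1-100 O0-70 N0-4 S0-2 P0-1) at a relative mass tolerance, screened
for chemical validity (integer DBE >= 0, optional O <= C + 2), the
heteroelement rule (> 3 heteroatoms rejected unless the excess is purely N
up to N4), isotopologue evidence (13C, 15N, 34S companions), and a
contaminant list. Negative-mode electrospray peaks are treated as [M-H]-
ions; the neutral mass is the measured m/z plus one proton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignedMatrix
from .formulas import (ELEMENT_BOUNDS, ELEMENT_MASS, MolecularFormula, ai_mod,
                       compound_class, exact_mass, parse_formula)

__all__ = [
    "AssignmentParams",
    "AnnotatedMatrix",
    "PROTON_MASS",
    "ISOTOPE_MASS_SHIFT",
    "ISOTOPE_ABUNDANCE_RATIO",
    "DEFAULT_CONTAMINANTS",
    "mass_error_ppm",
    "enumerate_candidates",
    "verify_isotopologue",
    "assign_formulas",
]

PROTON_MASS = 1.00727646

#: Mass shift (Da) of a single heavy-isotope substitution.
ISOTOPE_MASS_SHIFT = {"13C": 1.0033548378, "15N": 0.9970348941, "34S": 1.9957959}

#: Expected isotopologue/parent intensity ratio per substitutable atom.
ISOTOPE_ABUNDANCE_RATIO = {"13C": 0.0107, "15N": 0.00364, "34S": 0.0442}

_ISOTOPE_ELEMENT = {"13C": "c", "15N": "n", "34S": "s"}

#: Ubiquitous surfactant/plasticizer contaminants removed at feature level.
DEFAULT_CONTAMINANTS = frozenset({
    parse_formula("C16H32O2"),
    parse_formula("C12H26O4S"),
    parse_formula("C17H28O3S"),
    parse_formula("C10H15NO2S"),
})


@dataclass
class AssignmentParams:
    """Tunable knobs of the assignment/filter chain."""

    tol_ppm: float = 0.5
    mdl: float = 3.0  # method detection limit on S/N
    isotope_intensity_tol: float = 0.5  # relative tolerance on isotopologue ratio
    contaminants: frozenset = DEFAULT_CONTAMINANTS
    max_heteroelements: int = 3
    n4_exception: bool = True
    o_le_c_plus_2: bool = True
    max_mass: float = 1000.0
    ion_mode: str = "negative"  # "negative" ([M-H]-) or "neutral" (pre-neutralized)
    drop_on_isotope_fail: bool = False  # default: demote the candidate, keep the feature

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if self.mdl < 0:
            raise ValueError("mdl must be non-negative")
        if self.ion_mode not in ("negative", "neutral"):
            raise ValueError(f"unknown ion_mode {self.ion_mode!r}")


def mass_error_ppm(formula: MolecularFormula, neutral_mass: float) -> float:
    """Signed relative deviation of the formula's exact mass from
    ``neutral_mass`` in ppm."""
    return (exact_mass(formula) - neutral_mass) / neutral_mass * 1e6


def _candidate_sort_key(neutral_mass: float):
    def key(f: MolecularFormula):
        return (abs(mass_error_ppm(f, neutral_mass)), f.heteroelements, f.n_atoms, str(f))
    return key


def enumerate_candidates(neutral_mass: float, params: AssignmentParams | None = None) -> list[MolecularFormula]:
    """All chemically valid CHNOSP formulas within ``params.tol_ppm`` of a
    neutral mass, sorted by |mass error| (ties: fewer heteroatoms, fewer
    atoms).

    The heteroelement (> 3 except N4) rule is *not* applied here; it is part
    of :func:`assign_formulas`, matching the staged filter chain.
    """
    params = params or AssignmentParams()
    if not np.isfinite(neutral_mass) or neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if neutral_mass > params.max_mass:
        raise ValueError(f"neutral mass {neutral_mass:.4f} above assignment range "
                         f"(<= {params.max_mass} Da)")
    tol_da = neutral_mass * params.tol_ppm * 1e-6
    mC, mH, mN, mO, mS, mP = (ELEMENT_MASS[e] for e in "CHNOSP")
    out: list[MolecularFormula] = []
    c_lo, c_hi = ELEMENT_BOUNDS["c"]
    h_lo, h_hi = ELEMENT_BOUNDS["h"]
    o_hi_global = ELEMENT_BOUNDS["o"][1]
    for n in range(ELEMENT_BOUNDS["n"][1] + 1):
        for s in range(ELEMENT_BOUNDS["s"][1] + 1):
            for p in range(ELEMENT_BOUNDS["p"][1] + 1):
                base = n * mN + s * mS + p * mP
                if base - tol_da > neutral_mass - mC - mH:
                    continue
                c_max = min(c_hi, int((neutral_mass + tol_da - base - mH) / mC))
                for c in range(c_lo, c_max + 1):
                    o_cap = min(o_hi_global, c + 2) if params.o_le_c_plus_2 else o_hi_global
                    rem_for_o = neutral_mass + tol_da - base - c * mC - mH
                    o_max = min(o_cap, int(rem_for_o / mO)) if rem_for_o > 0 else -1
                    for o in range(o_max + 1):
                        rem = neutral_mass - base - c * mC - o * mO
                        h_mid = rem / mH
                        for h in {int(np.floor(h_mid)), int(np.ceil(h_mid))}:
                            if not h_lo <= h <= h_hi:
                                continue
                            f = MolecularFormula(c=c, h=h, n=n, o=o, s=s, p=p)
                            if abs(exact_mass(f) - neutral_mass) > tol_da:
                                continue
                            if not f.is_valid(o_le_c_plus_2=params.o_le_c_plus_2):
                                continue
                            out.append(f)
    out.sort(key=_candidate_sort_key(neutral_mass))
    return out


def _passes_heteroelement_rule(f: MolecularFormula, params: AssignmentParams) -> bool:
    if f.heteroelements <= params.max_heteroelements:
        return True
    # the exception admits purely-N excess up to N4
    return params.n4_exception and f.s == 0 and f.p == 0 and f.n <= ELEMENT_BOUNDS["n"][1]


def _sn_proxy(matrix: AlignedMatrix) -> np.ndarray:
    """Per-entry S/N: the measured sn column when present, else intensity
    over the sample's minimum positive intensity."""
    sn = matrix.sn.to_numpy(float)
    inten = matrix.intensities.to_numpy(float)
    proxy = sn.copy()
    for j in range(inten.shape[1]):
        col = inten[:, j]
        pos = col[col > 0]
        floor = pos.min() if len(pos) else 1.0
        missing = ~np.isfinite(proxy[:, j])
        proxy[missing, j] = np.where(col[missing] > 0, col[missing] / floor, 0.0)
    proxy[inten == 0] = 0.0
    return proxy


def verify_isotopologue(matrix: AlignedMatrix, feature_idx: int,
                        candidate: MolecularFormula,
                        params: AssignmentParams | None = None,
                        _sn: np.ndarray | None = None) -> tuple[bool, dict]:
    """Check isotopologue support for assigning ``candidate`` to a feature.

    For each heavy isotope (13C, 15N, 34S) with a substitutable atom, looks
    for a companion feature at the parent mass plus the isotope shift
    (within ``tol_ppm``) whose summed-intensity ratio to the parent is
    within ``isotope_intensity_tol`` (relative) of abundance x atom count.
    A missing companion is non-disqualifying when the expected companion
    would fall below the method detection limit. Returns (passed, evidence).
    """
    params = params or AssignmentParams()
    mz = np.asarray(matrix.feature_mz, float)
    inten = matrix.intensities.to_numpy(float)
    parent_int = inten[feature_idx]
    parent_total = parent_int.sum()
    sn_proxy = _sn_proxy(matrix) if _sn is None else _sn
    evidence: dict = {}
    passed = True
    for iso, shift in ISOTOPE_MASS_SHIFT.items():
        count = getattr(candidate, _ISOTOPE_ELEMENT[iso])
        if count == 0:
            continue
        expected_ratio = ISOTOPE_ABUNDANCE_RATIO[iso] * count
        target = mz[feature_idx] + shift
        tol_da = target * params.tol_ppm * 1e-6
        lo = np.searchsorted(mz, target - tol_da, side="left")
        hi = np.searchsorted(mz, target + tol_da, side="right")
        if hi > lo:
            # closest candidate companion
            j = lo + int(np.argmin(np.abs(mz[lo:hi] - target)))
            present = parent_int > 0
            comp_total = inten[j][present].sum()
            par_total = parent_int[present].sum()
            ratio = comp_total / par_total if par_total > 0 else np.nan
            ok = np.isfinite(ratio) and abs(ratio - expected_ratio) <= params.isotope_intensity_tol * expected_ratio
            evidence[iso] = {"companion_feature": int(j), "companion_mz": float(mz[j]),
                             "ratio": float(ratio), "expected_ratio": float(expected_ratio),
                             "found": True, "ok": bool(ok)}
            passed = passed and ok
        else:
            # no companion: disqualifying only if one should be detectable
            expected_sn = sn_proxy[feature_idx] * expected_ratio
            detectable = bool(np.any(expected_sn >= params.mdl))
            evidence[iso] = {"found": False, "expected_ratio": float(expected_ratio),
                             "detectable": detectable, "ok": not detectable}
            passed = passed and not detectable
    evidence["parent_total_intensity"] = float(parent_total)
    return passed, evidence


@dataclass
class AnnotatedMatrix:
    """Formula-annotated feature x sample matrix.

    ``features`` is indexed like ``intensities`` and carries per-feature
    metadata: consensus ``mz``, ``neutral_mass``, ``formula`` (Hill string,
    empty when unassigned), ``error_ppm``, element counts, ``dbe``, ``hc``,
    ``oc``, ``nc``, ``sc``, ``pc``, ``ai_mod``, ``compound_class`` and
    ``isotope_verified``. Unassigned features are retained but excluded
    from formula-level analyses via :attr:`annotated`.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    normalized: bool = False
    filter_log: dict = field(default_factory=dict)

    @property
    def annotated(self) -> pd.Series:
        """Boolean mask of features that carry a formula."""
        return self.features["formula"] != ""

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def formula_objects(self) -> dict[int, MolecularFormula]:
        return {i: parse_formula(f)
                for i, f in self.features.loc[self.annotated, "formula"].items()}

    def subset(self, mask) -> "AnnotatedMatrix":
        return AnnotatedMatrix(
            features=self.features.loc[mask].reset_index(drop=True),
            intensities=self.intensities.loc[mask].reset_index(drop=True),
            normalized=self.normalized,
            filter_log=dict(self.filter_log),
        )

    def with_intensities(self, intensities: pd.DataFrame, *, normalized: bool | None = None) -> "AnnotatedMatrix":
        return AnnotatedMatrix(features=self.features.copy(), intensities=intensities,
                               normalized=self.normalized if normalized is None else normalized,
                               filter_log=dict(self.filter_log))

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.features, self.intensities], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotatedMatrix":
        df = pd.read_csv(path, sep="\t", keep_default_na=False,
                         dtype={"formula": str, "compound_class": str})
        meta_cols = ["mz", "neutral_mass", "formula", "error_ppm", "c", "h", "n", "o", "s", "p",
                     "dbe", "hc", "oc", "nc", "sc", "pc", "ai_mod", "compound_class",
                     "isotope_verified"]
        meta = df[meta_cols].copy()
        for col in ("error_ppm", "dbe", "hc", "oc", "nc", "sc", "pc", "ai_mod"):
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
        inten = df.drop(columns=meta_cols).astype(float)
        return cls(features=meta, intensities=inten)


def _feature_row(mz: float, neutral: float, f: MolecularFormula | None,
                 err: float, verified: bool) -> dict:
    if f is None:
        return {"mz": mz, "neutral_mass": neutral, "formula": "", "error_ppm": np.nan,
                "c": 0, "h": 0, "n": 0, "o": 0, "s": 0, "p": 0, "dbe": np.nan,
                "hc": np.nan, "oc": np.nan, "nc": np.nan, "sc": np.nan, "pc": np.nan,
                "ai_mod": np.nan, "compound_class": "", "isotope_verified": False}
    return {"mz": mz, "neutral_mass": neutral, "formula": str(f), "error_ppm": err,
            "c": f.c, "h": f.h, "n": f.n, "o": f.o, "s": f.s, "p": f.p, "dbe": f.dbe,
            "hc": f.hc, "oc": f.oc, "nc": f.nc, "sc": f.sc, "pc": f.pc,
            "ai_mod": ai_mod(f), "compound_class": compound_class(f),
            "isotope_verified": verified}


def assign_formulas(matrix: AlignedMatrix, params: AssignmentParams | None = None) -> AnnotatedMatrix:
    """Run the full assignment chain on an aligned matrix.

    Per feature, candidates are enumerated at ``tol_ppm`` and screened by
    (a) the heteroelement rule, (b) isotopologue verification when evidence
    exists (failing candidates are demoted, or dropped when
    ``drop_on_isotope_fail``); the surviving candidate with the smallest
    |mass error| wins. Features matching the contaminant list, and features
    recognized as heavy-isotopologue companions of an assigned parent, are
    removed; other unassigned features are retained unannotated.
    """
    params = params or AssignmentParams()
    if matrix.n_features == 0:
        raise ValueError("cannot assign formulas to an empty matrix")

    # method detection limit on per-entry S/N
    sn_proxy = _sn_proxy(matrix)
    inten = matrix.intensities.to_numpy(float).copy()
    n_before = int((inten > 0).sum())
    inten[sn_proxy < params.mdl] = 0.0
    keep = inten.sum(axis=1) > 0
    work = AlignedMatrix(feature_mz=matrix.feature_mz[keep],
                         intensities=pd.DataFrame(inten[keep], columns=matrix.sample_ids),
                         sn=matrix.sn.loc[keep].reset_index(drop=True),
                         tol_ppm=matrix.tol_ppm,
                         demoted=matrix.demoted[keep],
                         split=matrix.split[keep])
    log = {"entries_before_mdl": n_before,
           "entries_after_mdl": int((inten > 0).sum()),
           "features_before_mdl": matrix.n_features,
           "features_after_mdl": work.n_features}

    shift = PROTON_MASS if params.ion_mode == "negative" else 0.0
    neutral = np.asarray(work.feature_mz, float) + shift

    rows: list[dict] = []
    assigned_formula: list[MolecularFormula | None] = []
    mzv = np.asarray(work.feature_mz, float)
    work_sn = _sn_proxy(work)
    for i in range(work.n_features):
        if neutral[i] > params.max_mass:
            rows.append(_feature_row(mzv[i], neutral[i], None, np.nan, False))
            assigned_formula.append(None)
            continue
        cands = [f for f in enumerate_candidates(neutral[i], params)
                 if _passes_heteroelement_rule(f, params)]
        chosen: MolecularFormula | None = None
        verified = False
        fallback: MolecularFormula | None = None
        for f in cands:
            ok, _evidence = verify_isotopologue(work, i, f, params, _sn=work_sn)
            if ok:
                chosen, verified = f, True
                break
            if fallback is None and not params.drop_on_isotope_fail:
                fallback = f
        if chosen is None:
            chosen = fallback  # demotion semantics: best candidate, unverified
        if chosen is None:
            rows.append(_feature_row(mzv[i], neutral[i], None, np.nan, False))
            assigned_formula.append(None)
        else:
            err = mass_error_ppm(chosen, neutral[i])
            assert abs(err) <= params.tol_ppm + 1e-9, "assignment outside tolerance"
            rows.append(_feature_row(mzv[i], neutral[i], chosen, err, verified))
            assigned_formula.append(chosen)

    features = pd.DataFrame(rows)
    log["features_assigned"] = int((features["formula"] != "").sum())

    # post-pass: features that sit at an isotope shift above an assigned
    # parent with a plausible intensity ratio are heavy-isotopologue
    # companions, not monoisotopic peaks; drop them from the annotated set
    isotopologue_member = np.zeros(work.n_features, dtype=bool)
    inten_work = work.intensities.to_numpy(float)
    for i, f in enumerate(assigned_formula):
        if f is None:
            continue
        for iso, delta in ISOTOPE_MASS_SHIFT.items():
            count = getattr(f, _ISOTOPE_ELEMENT[iso])
            if count == 0:
                continue
            target = mzv[i] + delta
            tol_da = target * params.tol_ppm * 1e-6
            lo = np.searchsorted(mzv, target - tol_da, side="left")
            hi = np.searchsorted(mzv, target + tol_da, side="right")
            if hi <= lo:
                continue
            j = lo + int(np.argmin(np.abs(mzv[lo:hi] - target)))
            present = inten_work[i] > 0
            par = inten_work[i][present].sum()
            comp = inten_work[j][present].sum()
            expected = ISOTOPE_ABUNDANCE_RATIO[iso] * count
            if par > 0 and abs(comp / par - expected) <= params.isotope_intensity_tol * expected:
                isotopologue_member[j] = True

    contaminant = np.array([f is not None and f in params.contaminants
                            for f in assigned_formula])
    log["contaminant_features_removed"] = int(contaminant.sum())
    # isotopologue companions of a *removed* contaminant stay flagged too
    drop = contaminant | isotopologue_member
    log["isotopologue_features_removed"] = int(isotopologue_member.sum())

    keep_mask = ~drop
    out = AnnotatedMatrix(
        features=features.loc[keep_mask].reset_index(drop=True),
        intensities=work.intensities.loc[keep_mask].reset_index(drop=True),
        normalized=False,
        filter_log=log,
    )
    if out.features.empty:
        warnings.warn("assignment produced an empty annotated matrix", stacklevel=2)
    return out
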