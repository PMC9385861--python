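"""Multi-sample peak alignment ("fast join") for FT-ICR-MS peak lists.

Each sample contributes a list of (m/z, intensity, S/N) peaks; alignment
joins peaks across samples into features at a fixed relative (ppm)
tolerance. Clusters are formed by single-linkage chaining of sorted masses,
with a span cap of twice the tolerance to bound chaining drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "AlignedMatrix",
    "read_peaklist",
    "join_mass_lists",
    "remove_singletons",
    "ACQUISITION_WINDOW",
]

#: Acquisition m/z window (Da); peaks outside it are rejected on read.
ACQUISITION_WINDOW = (92.0, 2000.0)


@dataclass
class PeakList:
    """Validated, mass-sorted peak list of one sample.

    ``peaks`` has columns ``mz`` (Da, strictly increasing), ``intensity``
    (> 0, arbitrary units) and ``sn`` (signal-to-noise; NaN when absent).
    """

    sample_id: str
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mz", "intensity"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peak list {self.sample_id!r} missing columns {sorted(missing)}")
        df = self.peaks.copy()
        if "sn" not in df.columns:
            df["sn"] = np.nan
        df = df[["mz", "intensity", "sn"]].sort_values("mz", kind="mergesort").reset_index(drop=True)
        problems = []
        lo, hi = ACQUISITION_WINDOW
        for i, row in df.iterrows():
            if not np.isfinite(row["mz"]) or not (lo < row["mz"] < hi):
                problems.append(f"row {i}: mz={row['mz']} outside acquisition window {ACQUISITION_WINDOW}")
            if not np.isfinite(row["intensity"]) or row["intensity"] <= 0:
                problems.append(f"row {i}: non-positive intensity {row['intensity']}")
        if problems:
            raise ValueError(f"invalid peak list {self.sample_id!r}: " + "; ".join(problems))
        dup = df["mz"].duplicated()
        if dup.any():
            # merge exact-mass duplicates (sum intensity, max sn)
            df = (df.groupby("mz", as_index=False)
                    .agg(intensity=("intensity", "sum"), sn=("sn", "max")))
        object.__setattr__(self, "peaks", df)

    def __len__(self) -> int:
        return len(self.peaks)

    def to_csv(self, path: str | Path) -> None:
        self.peaks.to_csv(path, index=False)


def read_peaklist(path: str | Path, sample_id: str | None = None) -> PeakList:
    """Read a per-sample peak-list CSV (columns ``mz``, ``intensity``,
    optional ``sn``) into a validated :class:`PeakList`.

    Parse and validation failures report the offending lines.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - reported with context
        raise ValueError(f"cannot parse {path} as CSV: {exc}") from exc
    required = {"mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    problems = []
    for col in ("mz", "intensity") + (("sn",) if "sn" in df.columns else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            # +2: header line plus 1-based numbering
            problems.append(f"line {i + 2}: non-numeric {col}={df.loc[i, col]!r}")
        df[col] = coerced
    nonpos = df.index[df["intensity"] <= 0]
    for i in nonpos:
        problems.append(f"line {i + 2}: non-positive intensity {df.loc[i, 'intensity']!r}")
    lo, hi = ACQUISITION_WINDOW
    outside = df.index[~df["mz"].between(lo, hi, inclusive="neither")]
    for i in outside:
        problems.append(f"line {i + 2}: mz {df.loc[i, 'mz']!r} outside acquisition window")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return PeakList(sample_id=sample_id, peaks=df)


@dataclass
class AlignedMatrix:
    """Feature x sample intensity matrix from multi-sample alignment.

    ``feature_mz`` holds intensity-weighted consensus masses (strictly
    increasing); ``intensities`` (and ``sn``) are DataFrames indexed by
    feature position with one column per sample, 0 marking absence.
    ``demoted`` flags features created by demoting a same-sample duplicate
    out of a cluster, and ``split`` flags trailing pieces of a span-capped
    cluster; either kind may legitimately lie within tolerance of its
    sibling feature.
    """

    feature_mz: np.ndarray
    intensities: pd.DataFrame
    sn: pd.DataFrame
    tol_ppm: float
    demoted: np.ndarray = field(default=None)  # type: ignore[assignment]
    split: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.demoted is None:
            self.demoted = np.zeros(len(self.feature_mz), dtype=bool)
        if self.split is None:
            self.split = np.zeros(len(self.feature_mz), dtype=bool)
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.feature_mz)

    def validate(self) -> None:
        mz = np.asarray(self.feature_mz, dtype=float)
        if len(mz) != len(self.intensities):
            raise ValueError("feature_mz and intensities disagree on feature count")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("consensus masses must be strictly increasing")
        if len(mz) and not (self.intensities.to_numpy() > 0).any(axis=1).all():
            raise ValueError("every feature must be present in at least one sample")
        kept = mz[~(self.demoted | self.split)]
        if len(kept) > 1:
            rel = np.diff(kept) / kept[:-1] * 1e6
            if np.any(rel <= self.tol_ppm):
                raise ValueError("non-demoted consensus masses closer than the join tolerance")

    def presence_counts(self) -> np.ndarray:
        """Number of samples each feature is detected in."""
        return (self.intensities.to_numpy() > 0).sum(axis=1)

    def subset(self, keep: np.ndarray) -> "AlignedMatrix":
        return AlignedMatrix(
            feature_mz=self.feature_mz[keep],
            intensities=self.intensities.loc[keep].reset_index(drop=True),
            sn=self.sn.loc[keep].reset_index(drop=True),
            tol_ppm=self.tol_ppm,
            demoted=self.demoted[keep],
            split=self.split[keep],
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.intensities.copy()
        out.insert(0, "mz", self.feature_mz)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, tol_ppm: float = 0.5) -> "AlignedMatrix":
        df = pd.read_csv(path)
        mz = df.pop("mz").to_numpy(float)
        sn = pd.DataFrame(np.nan, index=df.index, columns=df.columns)
        return cls(feature_mz=mz, intensities=df, sn=sn, tol_ppm=tol_ppm)


def _split_cluster_by_span(mz: np.ndarray, order: np.ndarray, max_span_ppm: float) -> list[np.ndarray]:
    """Split a sorted cluster so each piece spans <= max_span_ppm (relative
    to the piece's lowest mass). Deterministic greedy left-to-right walk."""
    pieces: list[list[int]] = []
    start_mz = None
    for idx in order:
        if start_mz is None or (mz[idx] - start_mz) / start_mz * 1e6 > max_span_ppm:
            pieces.append([idx])
            start_mz = mz[idx]
        else:
            pieces[-1].append(idx)
    return [np.asarray(piece) for piece in pieces]


def join_mass_lists(peaklists: list[PeakList], tol_ppm: float = 0.5) -> AlignedMatrix:
    """Join per-sample peak lists into one feature x sample matrix.

    Peaks whose relative mass difference is <= ``tol_ppm`` (computed
    relative to the smaller mass) are chained into a cluster by single
    linkage; clusters spanning more than 2 x ``tol_ppm`` are split. Within
    a cluster, each sample keeps its most intense member peak; losing
    duplicates are demoted to their own features. The consensus mass is
    the intensity-weighted mean of member masses.
    """
    if not peaklists:
        raise ValueError("need at least one peak list")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    ids = [pl.sample_id for pl in peaklists]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in peak lists")

    mz = np.concatenate([pl.peaks["mz"].to_numpy(float) for pl in peaklists]) if peaklists else np.array([])
    inten = np.concatenate([pl.peaks["intensity"].to_numpy(float) for pl in peaklists])
    sn = np.concatenate([pl.peaks["sn"].to_numpy(float) for pl in peaklists])
    sample = np.concatenate([np.full(len(pl), i) for i, pl in enumerate(peaklists)])

    order = np.argsort(mz, kind="mergesort")
    # (consensus, members, demoted, split)
    features: list[tuple[float, dict, bool, bool]] = []

    if len(order):
        # single-linkage on sorted masses: break where the consecutive gap
        # exceeds tol (relative to the smaller mass)
        gaps = np.diff(mz[order]) / mz[order[:-1]] * 1e6
        breakpoints = np.flatnonzero(gaps > tol_ppm) + 1
        clusters = np.split(order, breakpoints)
        for cluster in clusters:
            for piece_no, piece in enumerate(_split_cluster_by_span(mz, cluster, 2.0 * tol_ppm)):
                members: dict[int, int] = {}
                demoted_members: list[int] = []
                for idx in piece:
                    s = int(sample[idx])
                    if s in members:
                        # keep the more intense peak; demote the other
                        if inten[idx] > inten[members[s]]:
                            demoted_members.append(members[s])
                            members[s] = idx
                        else:
                            demoted_members.append(idx)
                    else:
                        members[s] = idx
                kept = np.fromiter(members.values(), dtype=int)
                consensus = float(np.average(mz[kept], weights=inten[kept]))
                features.append((consensus,
                                 {int(sample[i]): (mz[i], inten[i], sn[i]) for i in kept},
                                 False, piece_no > 0))
                for i in demoted_members:
                    features.append((float(mz[i]),
                                     {int(sample[i]): (mz[i], inten[i], sn[i])},
                                     True, False))

    features.sort(key=lambda f: f[0])
    n_feat = len(features)
    imat = np.zeros((n_feat, len(peaklists)))
    smat = np.full((n_feat, len(peaklists)), np.nan)
    cons = np.empty(n_feat)
    demoted = np.zeros(n_feat, dtype=bool)
    split = np.zeros(n_feat, dtype=bool)
    for fi, (consensus, members, was_demoted, was_split) in enumerate(features):
        cons[fi] = consensus
        demoted[fi] = was_demoted
        split[fi] = was_split
        for s, (_, it, snv) in members.items():
            imat[fi, s] = it
            smat[fi, s] = snv
    # exact-tie consensus masses can only arise from demotion collisions;
    # nudge is not attempted -- merge identical-mass features instead
    if n_feat > 1 and np.any(np.diff(cons) == 0):
        keep_rows = []
        i = 0
        while i < n_feat:
            j = i
            while j + 1 < n_feat and cons[j + 1] == cons[i]:
                j += 1
            if j > i:
                imat[i] = imat[i:j + 1].sum(axis=0)
                smat[i] = np.nanmax(smat[i:j + 1], axis=0)
                demoted[i] = bool(demoted[i:j + 1].all())
                split[i] = bool(split[i:j + 1].any())
            keep_rows.append(i)
            i = j + 1
        cons, imat, smat = cons[keep_rows], imat[keep_rows], smat[keep_rows]
        demoted, split = demoted[keep_rows], split[keep_rows]

    return AlignedMatrix(
        feature_mz=cons,
        intensities=pd.DataFrame(imat, columns=ids),
        sn=pd.DataFrame(smat, columns=ids),
        tol_ppm=tol_ppm,
        demoted=demoted,
        split=split,
    )


def remove_singletons(matrix: AlignedMatrix) -> AlignedMatrix:
    """Drop features detected in fewer than two samples ("singlet peaks")."""
    keep = matrix.presence_counts() >= 2
    if not keep.any():
        warnings.warn("all features are singletons; returning an empty matrix", stacklevel=2)
    return matrix.subset(keep)
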