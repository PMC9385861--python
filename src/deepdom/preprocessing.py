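"""Intensity normalization, detection-limit harmonization, occurrence
filtering and replicate averaging.

The canonical order is: normalize to the per-sample intensity sum,
harmonize detection limits across samples (highest per-sample minimum wins),
then require each feature to occur in at least ``min_samples`` samples.
Replicate spectra are averaged per group (e.g. per borehole) before
cross-dataset statistics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .assignment import AnnotatedMatrix

__all__ = [
    "normalize_to_sum",
    "harmonize_detection_limit",
    "occurrence_filter",
    "average_replicates",
    "preprocess",
    "read_grouping",
]


def _as_frame(matrix):
    if isinstance(matrix, AnnotatedMatrix):
        return matrix.intensities, matrix
    return matrix, None


def normalize_to_sum(matrix):
    """Scale every sample column to sum to 1 over its nonzero entries."""
    df, am = _as_frame(matrix)
    sums = df.sum(axis=0)
    dead = sums.index[sums <= 0].tolist()
    if dead:
        raise ValueError(f"samples with zero total intensity: {dead}")
    out = df / sums
    if am is not None:
        return am.with_intensities(out, normalized=True)
    return out


def harmonize_detection_limit(matrix):
    """Apply a common detection limit across samples.

    The threshold is the highest of the per-sample minimum nonzero
    (normalized) intensities; entries strictly below it are set to 0.
    Entries exactly at the threshold are kept.
    """
    df, am = _as_frame(matrix)
    mins = df[df > 0].min(axis=0)
    threshold = mins.max()
    out = df.where((df >= threshold) | (df == 0), 0.0)
    if am is not None:
        res = am.with_intensities(out)
        res.filter_log["detection_limit"] = float(threshold)
        return res
    return out


def occurrence_filter(matrix, min_samples: int = 3):
    """Retain features that are nonzero in at least ``min_samples`` samples."""
    df, am = _as_frame(matrix)
    keep = (df > 0).sum(axis=1) >= min_samples
    if am is not None:
        res = am.subset(keep.to_numpy())
        res.filter_log["features_before_occurrence"] = int(len(df))
        res.filter_log["features_after_occurrence"] = int(keep.sum())
        return res
    return df.loc[keep]


def average_replicates(matrix, grouping: Mapping[str, str]):
    """Average replicate sample columns per group and renormalize to sum 1.

    ``grouping`` maps every sample id to its group (e.g. borehole) label.
    """
    df, am = _as_frame(matrix)
    unmapped = [s for s in df.columns if s not in grouping]
    if unmapped:
        raise ValueError(f"samples without a group: {unmapped}")
    groups: dict[str, list[str]] = {}
    for s in df.columns:
        groups.setdefault(grouping[s], []).append(s)
    out = pd.DataFrame({g: df[cols].mean(axis=1) for g, cols in groups.items()})
    sums = out.sum(axis=0)
    out = out / sums.where(sums > 0, 1.0)
    if am is not None:
        return am.with_intensities(out, normalized=True)
    return out


def preprocess(matrix, min_occurrence: int = 3, *, renormalize: bool = False,
               grouping: Mapping[str, str] | None = None):
    """Canonical chain: normalize -> harmonize detection limit -> occurrence
    filter (optionally renormalize afterwards, off by default so retained
    peaks keep their cross-sample comparable scale), then optional replicate
    averaging."""
    out = normalize_to_sum(matrix)
    out = harmonize_detection_limit(out)
    out = occurrence_filter(out, min_samples=min_occurrence)
    if renormalize:
        out = normalize_to_sum(out)
    if grouping is not None:
        out = average_replicates(out, grouping)
    return out


def read_grouping(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, group) CSV into a mapping."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: grouping file needs two columns (sample, group)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
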