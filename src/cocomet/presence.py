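"""Presence/absence calls for molecular features, anchored on a knockout baseline.

The detection threshold is derived from analytes that are *known* to be
absent in a set of samples — here the koreenceine congeners A/B/C in
koreenceine-knockout (Δkec) cultures, whose recorded signal is therefore pure
noise.  The baseline is the maximum observed peak area of those analytes in
those samples; a feature is called present in a condition when its replicate
peak areas exceed that threshold under a chosen rule (median by default).
Features present in sterile media blanks are classified as media-derived and
excluded before tallying condition-unique and shared features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import ValidationError
from .io import FeatureTable

PRESENCE_RULES = ("median", "any", "all")


def _present(areas: np.ndarray, threshold: float, rule: str) -> np.ndarray:
    """Row-wise presence over replicate columns (features x replicates)."""
    if rule == "median":
        return np.median(areas, axis=1) > threshold
    if rule == "any":
        return (areas > threshold).any(axis=1)
    if rule == "all":
        return (areas > threshold).all(axis=1)
    raise ValidationError(f"unknown presence rule {rule!r}")


def detection_baseline(
    features: FeatureTable,
    absent_ids: Iterable[str],
    sample_ids: Iterable[str],
) -> float:
    """Noise threshold: max peak area of known-absent analytes in the given samples."""
    absent_ids = list(absent_ids)
    sample_ids = list(sample_ids)
    if not absent_ids:
        raise ValidationError("need at least one known-absent analyte")
    if not sample_ids:
        raise ValidationError("need at least one sample")
    missing = [f for f in absent_ids if f not in set(features.features)]
    if missing:
        raise ValidationError(f"absent analytes not in feature table: {missing}")
    missing_s = [s for s in sample_ids if s not in set(features.samples)]
    if missing_s:
        raise ValidationError(f"samples not in feature table: {missing_s}")
    return float(features.areas.loc[absent_ids, sample_ids].to_numpy().max())


def media_features(
    features: FeatureTable,
    design: StudyDesign,
    threshold: float,
    rule: str = "median",
) -> List[str]:
    """Features called present in the sterile media blanks (medium-derived)."""
    blanks = [s.sample_id for s in design.media_samples()]
    if not blanks:
        raise ValidationError("design has no media samples")
    areas = features.areas[blanks].to_numpy()
    mask = _present(areas, threshold, rule)
    return list(features.areas.index[mask])


@dataclass
class PresenceCalls:
    """Boolean feature x condition presence matrix for one genotype series."""

    calls: pd.DataFrame  # bool, index features, columns condition names
    threshold: float
    rule: str
    series: Optional[str]

    @property
    def features(self) -> List[str]:
        return list(self.calls.index)

    def detected(self) -> FrozenSet[str]:
        """Features present in at least one condition."""
        return frozenset(self.calls.index[self.calls.any(axis=1)])


def presence_matrix(
    features: FeatureTable,
    design: StudyDesign,
    threshold: float,
    rule: str = "median",
    series: Optional[str] = "wt",
    exclude: Optional[Iterable[str]] = None,
) -> PresenceCalls:
    """Call every feature present/absent in each non-media condition of a series.

    ``exclude`` drops features (typically the media-derived set) before
    calling.  Presence is antitone in ``threshold``: raising it can only
    remove calls.
    """
    areas = features.areas
    if exclude is not None:
        areas = areas.drop(index=[f for f in exclude if f in areas.index])
    cols = {}
    for cond in design.condition_names(series):
        reps = [s.sample_id for s in design.replicates_of(cond, series)]
        if not reps:
            raise ValidationError(f"condition {cond!r} has no replicates")
        cols[cond] = _present(areas[reps].to_numpy(), threshold, rule)
    calls = pd.DataFrame(cols, index=areas.index)
    return PresenceCalls(calls, threshold, rule, series)


@dataclass
class TallyResult:
    """Condition-unique / shared feature tallies, per series and across series."""

    per_series: pd.DataFrame  # n_detected, n_coculture_only, n_triple_only
    coculture_only: Dict[str, FrozenSet[str]]
    triple_only: Dict[str, FrozenSet[str]]
    matched: Optional[pd.DataFrame] = None  # per condition + overall comparison
    shared_ids: Optional[FrozenSet[str]] = None
    unique_first_ids: Optional[FrozenSet[str]] = None
    unique_second_ids: Optional[FrozenSet[str]] = None


def _series_sets(calls: PresenceCalls):
    df = calls.calls
    mono_cols = [c for c in df.columns if len(c) == 1]
    multi_cols = [c for c in df.columns if len(c) >= 2]
    in_mono = df[mono_cols].any(axis=1) if mono_cols else pd.Series(False, index=df.index)
    in_multi = df[multi_cols].any(axis=1) if multi_cols else pd.Series(False, index=df.index)
    coculture_only = frozenset(df.index[in_multi & ~in_mono])
    if "BFK" in df.columns:
        others = [c for c in df.columns if c != "BFK"]
        in_others = df[others].any(axis=1) if others else pd.Series(False, index=df.index)
        triple_only = frozenset(df.index[df["BFK"] & ~in_others])
    else:
        triple_only = frozenset()
    return coculture_only, triple_only


def condition_tallies(
    calls: PresenceCalls,
    calls_other: Optional[PresenceCalls] = None,
) -> TallyResult:
    """Tally coculture-only / triple-only features, and compare two series.

    Inputs must already exclude media-derived features.  The cross-series
    comparison reports, per matched condition and overall, the features shared
    and unique to each series, with percentages of the non-media union; these
    three counts partition the union exactly.
    """
    series_rows = {}
    cocult: Dict[str, FrozenSet[str]] = {}
    triple: Dict[str, FrozenSet[str]] = {}
    for c in [calls, calls_other] if calls_other is not None else [calls]:
        label = c.series or "all"
        co, tr = _series_sets(c)
        cocult[label], triple[label] = co, tr
        series_rows[label] = {
            "n_detected": len(c.detected()),
            "n_coculture_only": len(co),
            "n_triple_only": len(tr),
        }
    per_series = pd.DataFrame(series_rows).T
    per_series.index.name = "series"

    if calls_other is None:
        return TallyResult(per_series, cocult, triple)

    if list(calls.calls.index) != list(calls_other.calls.index):
        raise ValidationError("feature universes differ between the two series")

    rows = []

    def compare(det_a: FrozenSet[str], det_b: FrozenSet[str], label: str):
        union = det_a | det_b
        shared = det_a & det_b
        ua, ub = det_a - det_b, det_b - det_a
        n = len(union)
        rows.append(
            {
                "condition": label,
                "n_union": n,
                "n_shared": len(shared),
                "n_unique_first": len(ua),
                "n_unique_second": len(ub),
                "pct_shared": 100.0 * len(shared) / n if n else np.nan,
                "pct_unique_first": 100.0 * len(ua) / n if n else np.nan,
                "pct_unique_second": 100.0 * len(ub) / n if n else np.nan,
            }
        )
        return shared, ua, ub

    common_conditions = [
        c for c in calls.calls.columns if c in set(calls_other.calls.columns)
    ]
    for cond in common_conditions:
        det_a = frozenset(calls.calls.index[calls.calls[cond]])
        det_b = frozenset(calls_other.calls.index[calls_other.calls[cond]])
        compare(det_a, det_b, cond)
    shared, ua, ub = compare(calls.detected(), calls_other.detected(), "any")
    matched = pd.DataFrame(rows).set_index("condition")
    return TallyResult(
        per_series,
        cocult,
        triple,
        matched,
        frozenset(shared),
        frozenset(ua),
        frozenset(ub),
    )
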