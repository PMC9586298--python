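"""Per-feature 2^3 factorial model of species presence with all interactions.

For each molecular feature *m* the model regresses log peak area on ±1-coded
indicators of community membership:

    log(y_im) = b0_m + sum_j b_jm x_ij + sum_jk b_jkm x_ijk + b_BFKm x_iBFK + e_im

with j over the three members B, F, K, jk over the three pairs and a single
three-way term.  Two codings of the interaction columns are supported:

* ``containment`` — an interaction entry is +1 iff *all* species of the term
  are present in the sample, −1 otherwise (subset-indicator coding);
* ``product`` — the entry is the product of the member main-effect entries
  (classical full-factorial effect coding).

The two codings agree on main effects and on samples where all or none of a
term's species are present; they differ exactly where some but not all are.
On the seven non-media conditions either coding is rank 7 — the all-absent
(sterile media) design point is what identifies the three-way term — so fits
may include the media blanks as that eighth point, or run "strict" without
them and report the aliased trailing term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import Condition, StudyDesign
from .errors import ValidationError
from .io import FeatureTable

#: model terms in entry (and aliasing) order
TERMS = ("intercept", "B", "F", "K", "BF", "BK", "FK", "BFK")
INTERACTIONS = ("BF", "BK", "FK", "BFK")

CODINGS = ("containment", "product")


def encode_condition(condition: Condition, coding: str = "containment") -> np.ndarray:
    """±1 design row (8 terms) for one condition under the given coding."""
    if coding not in CODINGS:
        raise ValidationError(f"unknown coding {coding!r}")
    present = condition.species
    main = {s: (1.0 if s in present else -1.0) for s in "BFK"}
    row = [1.0, main["B"], main["F"], main["K"]]
    for term in INTERACTIONS:
        if coding == "containment":
            row.append(1.0 if all(s in present for s in term) else -1.0)
        else:
            row.append(float(np.prod([main[s] for s in term])))
    return np.asarray(row)


@dataclass
class DesignMatrix:
    """Assembled model matrix with rank diagnostics."""

    X: pd.DataFrame  # rows sample ids, columns TERMS
    coding: str
    rank: int
    null_space: np.ndarray  # shape (8, n_null); empty when full rank
    conditions: pd.Series  # condition name per sample row

    @property
    def sample_ids(self) -> List[str]:
        return list(self.X.index)

    @property
    def is_full_rank(self) -> bool:
        return self.rank == len(TERMS)


def build_design(
    design: StudyDesign,
    coding: str = "containment",
    include_baseline: bool = True,
    series: Optional[str] = "wt",
) -> DesignMatrix:
    """Assemble the factorial design matrix for one genotype series.

    ``include_baseline`` adds the media blanks as the all-absent design point
    (making all eight terms identifiable); without it the matrix over the
    seven culture conditions is rank deficient and the fit will alias the
    trailing dependent term.
    """
    samples = design.non_media_samples(series)
    if include_baseline:
        samples = samples + design.media_samples()
    conditions = {s.condition.name for s in samples}
    if len(conditions) < 2:
        raise ValidationError(
            f"need >=2 distinct conditions to fit a model, got {sorted(conditions)}"
        )
    rows = np.vstack([encode_condition(s.condition, coding) for s in samples])
    X = pd.DataFrame(rows, index=[s.sample_id for s in samples], columns=list(TERMS))
    u, sv, vt = np.linalg.svd(rows, full_matrices=True)
    tol = sv.max() * max(rows.shape) * np.finfo(float).eps
    rank = int((sv > tol).sum())
    null_space = vt[rank:].T  # (8, n_null)
    cond_series = pd.Series(
        [s.condition.name for s in samples], index=X.index, name="condition"
    )
    return DesignMatrix(X, coding, rank, null_space, cond_series)


def _independent_columns(X: np.ndarray) -> List[int]:
    """Greedy maximal independent column subset in term entry order."""
    kept: List[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append(j)
            rank = r
    return kept


@dataclass
class FeatureFit:
    """Least-squares fit of one feature: coefficients, SEs and t statistics."""

    coef: pd.Series
    se: pd.Series
    t: pd.Series
    rss: float
    df_resid: int
    aliased: List[str] = field(default_factory=list)


def _fit_matrix(Y: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, List[int]]:
    """Vectorised OLS of every column of ``Y`` (n x p) on ``X`` (n x k).

    Returns (coef, se, t, rss, df_resid, kept_columns); aliased columns are
    excluded from the returned arrays and reported via ``kept_columns``.
    """
    n = X.shape[0]
    kept = _independent_columns(X)
    Xr = X[:, kept]
    r = len(kept)
    df = n - r
    if df < 1:
        raise ValidationError("saturated model: zero residual degrees of freedom")
    gram_inv = np.linalg.inv(Xr.T @ Xr)
    coef = gram_inv @ (Xr.T @ Y)
    resid = Y - Xr @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    # exact interpolation leaves tiny negative round-off
    rss = np.maximum(rss, 0.0)
    s2 = rss / df
    se = np.sqrt(np.outer(np.diag(gram_inv), s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    # RSS == 0: slope estimates are exact, flag t as infinite (0/0 -> 0)
    zero = se == 0
    with np.errstate(invalid="ignore"):
        t[zero] = np.where(coef[zero] == 0, 0.0, np.sign(coef[zero]) * np.inf)
    return coef, se, t, rss, df, kept


def fit_feature(y: Sequence[float], dm: DesignMatrix) -> FeatureFit:
    """OLS fit of one feature's log abundances against the design matrix.

    Rank-deficient designs are fit on the maximal independent column subset in
    term order (intercept, mains, pairs, triple); trailing dependent terms are
    flagged aliased and carry no coefficient or t value.
    """
    y = np.asarray(y, dtype=float)
    X = dm.X.to_numpy()
    if y.shape[0] != X.shape[0]:
        raise ValidationError(
            f"response length {y.shape[0]} != design rows {X.shape[0]}"
        )
    if not np.isfinite(y).all():
        raise ValidationError("non-finite response values")
    coef, se, t, rss, df, kept = _fit_matrix(y[:, None], X)
    full = pd.Series(np.nan, index=list(TERMS))
    coef_s, se_s, t_s = full.copy(), full.copy(), full.copy()
    kept_names = [TERMS[j] for j in kept]
    coef_s[kept_names] = coef[:, 0]
    se_s[kept_names] = se[:, 0]
    t_s[kept_names] = t[:, 0]
    aliased = [name for name in TERMS if name not in kept_names]
    return FeatureFit(coef_s, se_s, t_s, float(rss[0]), df, aliased)


@dataclass
class EnsembleResult:
    """Per-term t-statistic ensemble over all molecular features."""

    t: pd.DataFrame  # features x terms (NaN for aliased terms)
    coef: pd.DataFrame
    se: pd.DataFrame
    df_resid: int
    aliased: List[str]
    summaries: pd.DataFrame  # per term: median, q25, q75, iqr
    failures: List[str] = field(default_factory=list)


def fit_ensemble(
    features: FeatureTable,
    dm: DesignMatrix,
    offset: float = 1.0,
) -> EnsembleResult:
    """Fit every molecular feature and assemble the t-statistic ensemble.

    The response is ``ln(area + offset)``; the offset (default 1) keeps zero
    areas finite and is irrelevant to t statistics for areas well above it.
    Features that fail to fit (non-finite response) are recorded in
    ``failures``, not silently dropped.
    """
    missing = [s for s in dm.sample_ids if s not in set(features.samples)]
    if missing:
        raise ValidationError(f"design samples missing from feature table: {missing}")
    areas = features.areas[dm.sample_ids].to_numpy(dtype=float)
    shifted = areas + offset
    if (shifted <= 0).any():
        raise ValidationError("area + offset must be positive for the log transform")
    Y = np.log(shifted).T  # samples x features
    X = dm.X.to_numpy()
    finite = np.isfinite(Y).all(axis=0)
    failures = [f for f, ok in zip(features.features, finite) if not ok]
    coef, se, t, rss, df, kept = _fit_matrix(Y[:, finite], X)
    kept_names = [TERMS[j] for j in kept]
    aliased = [name for name in TERMS if name not in kept_names]
    idx = [f for f, ok in zip(features.features, finite) if ok]

    def expand(mat: np.ndarray) -> pd.DataFrame:
        out = pd.DataFrame(np.nan, index=idx, columns=list(TERMS))
        out[kept_names] = mat.T
        return out

    t_df = expand(t)
    summaries = pd.DataFrame(
        {
            "median": t_df.median(),
            "q25": t_df.quantile(0.25),
            "q75": t_df.quantile(0.75),
        }
    )
    summaries["iqr"] = summaries["q75"] - summaries["q25"]
    return EnsembleResult(
        t=t_df,
        coef=expand(coef),
        se=expand(se),
        df_resid=df,
        aliased=aliased,
        summaries=summaries,
        failures=failures,
    )


def tail_select(
    ens: EnsembleResult, term: str, percentile: float = 2.5
) -> Tuple[List[str], List[str]]:
    """Features in the upper / lower tails of one term's t ensemble.

    Upper tail: t >= the (100 − percentile)th empirical quantile (linear
    interpolation); lower tail: t <= the percentile-th quantile.  Ties at a
    threshold are included, so degenerate all-equal ensembles select
    everything.
    """
    if term not in TERMS:
        raise ValidationError(f"unknown term {term!r}")
    if term in ens.aliased:
        raise ValidationError(f"term {term!r} is aliased; no t statistics")
    if not 0 < percentile < 50:
        raise ValidationError("percentile must be in (0, 50)")
    t = ens.t[term].dropna()
    vals = t.to_numpy()
    hi = np.percentile(vals, 100 - percentile)
    lo = np.percentile(vals, percentile)
    upper = list(t.index[vals >= hi])
    lower = list(t.index[vals <= lo])
    return upper, lower
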