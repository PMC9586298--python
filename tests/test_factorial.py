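import numpy as np
import pandas as pd
import pytest

from cocomet.design import Condition, Sample, StudyDesign
from cocomet.errors import ValidationError
from cocomet.factorial import (
    TERMS,
    build_design,
    encode_condition,
    fit_ensemble,
    fit_feature,
    tail_select,
)
from cocomet.io import FeatureTable
from cocomet.simulate import SimulationConfig, default_design

EXPECTED_NULL = np.array([1, -1, -1, -1, 1, 1, 1, -1], dtype=float)


def _design(reps=1, media=True):
    cfg = SimulationConfig(
        n_replicates=reps,
        n_media_replicates=max(reps, 1),
        n_genes_per_genome=8,
        n_bgc_per_genome=1,
        bgc_size=2,
        n_features=10,
        n_kec_features=0,
        n_threeway_only=0,
        n_pairwise_only=0,
    )
    d = default_design(cfg, series=("wt",))
    if not media:
        from cocomet.design import StudyDesign

        d = StudyDesign([s for s in d if not s.condition.is_media])
    return d


# --- coding ---------------------------------------------------------------


def test_containment_row_for_monoculture():
    row = encode_condition(Condition(frozenset("B")), "containment")
    assert list(row) == [1, 1, -1, -1, -1, -1, -1, -1]


def test_full_community_row_is_all_plus_one():
    for coding in ("containment", "product"):
        assert (encode_condition(Condition(frozenset("BFK")), coding) == 1).all()


def test_codings_differ_exactly_on_partial_interactions():
    # {B}: FK has no member present -> product (-1)(-1)=+1, containment -1
    c = Condition(frozenset("B"))
    cont = encode_condition(c, "containment")
    prod = encode_condition(c, "product")
    fk = TERMS.index("FK")
    assert cont[fk] == -1 and prod[fk] == 1
    # they agree on intercept and main effects everywhere
    assert (cont[:4] == prod[:4]).all()


# --- design assembly ------------------------------------------------------


@pytest.mark.parametrize("coding", ["containment", "product"])
def test_seven_conditions_are_rank_seven_with_known_null_vector(coding):
    dm = build_design(_design(media=False), coding, include_baseline=False)
    assert dm.rank == 7
    assert dm.null_space.shape == (8, 1)
    v = dm.null_space[:, 0]
    v = v / v[0]  # normalise sign and scale
    assert np.allclose(v, EXPECTED_NULL / EXPECTED_NULL[0], atol=1e-10)
    # and it annihilates every design row
    assert np.abs(dm.X.to_numpy() @ dm.null_space).max() < 1e-10


@pytest.mark.parametrize("coding", ["containment", "product"])
def test_media_baseline_restores_full_rank(coding):
    dm = build_design(_design(media=True), coding, include_baseline=True)
    assert dm.rank == 8 and dm.null_space.shape[1] == 0


def test_fewer_than_two_conditions_is_error():
    samples = [Sample(f"s{r}", Condition(frozenset("B")), r, "wt") for r in (1, 2)]
    with pytest.raises(ValidationError):
        build_design(StudyDesign(samples), include_baseline=False)


# --- single-feature fits --------------------------------------------------


def test_exact_interpolation_recovers_coefficients():
    dm = build_design(_design(reps=2, media=True))
    beta = np.array([5.0, 1.0, -0.5, 0.25, 0.0, 0.75, 0.0, 2.0])
    y = dm.X.to_numpy() @ beta
    fit = fit_feature(y, dm)
    assert np.allclose(fit.coef.to_numpy(), beta, atol=1e-10)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)
    nonzero = beta != 0
    assert np.isinf(fit.t.to_numpy()[nonzero]).all()


def test_fit_matches_statsmodels_on_random_instances():
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    dm = build_design(_design(reps=3, media=True))
    X = dm.X.to_numpy()
    for _ in range(20):
        y = rng.normal(size=X.shape[0])
        fit = fit_feature(y, dm)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(fit.coef.to_numpy(), ref.params, atol=1e-8)
        assert np.allclose(fit.se.to_numpy(), ref.bse, atol=1e-8)
        assert np.allclose(fit.t.to_numpy(), ref.tvalues, atol=1e-8)


def test_balanced_full_factorial_matches_closed_form():
    """Product coding over all 8 conditions is orthogonal: beta_j = x_j.y/n."""
    conditions = [Condition(frozenset(s)) for s in ("", "B", "F", "K", "BF", "BK", "FK", "BFK")]
    samples = []
    for c in conditions:
        for r in (1, 2, 3):
            series = None if c.is_media else "wt"
            samples.append(Sample(f"{c.name}_{r}", c, r, series))
    dm = build_design(StudyDesign(samples), coding="product", include_baseline=True)
    X = dm.X.to_numpy()
    n = X.shape[0]
    assert np.allclose(X.T @ X, n * np.eye(8))
    rng = np.random.default_rng(3)
    y = rng.normal(size=n)
    fit = fit_feature(y, dm)
    beta_closed = X.T @ y / n
    resid = y - X @ beta_closed
    s2 = resid @ resid / (n - 8)
    t_closed = beta_closed / np.sqrt(s2 / n)
    assert np.allclose(fit.coef.to_numpy(), beta_closed, atol=1e-8)
    assert np.allclose(fit.t.to_numpy(), t_closed, atol=1e-8)


def test_rank_deficient_fit_aliases_trailing_term():
    import statsmodels.api as sm

    dm = build_design(_design(reps=2, media=False), include_baseline=False)
    rng = np.random.default_rng(11)
    y = rng.normal(size=dm.X.shape[0])
    fit = fit_feature(y, dm)
    assert fit.aliased == ["BFK"]
    assert np.isnan(fit.coef["BFK"]) and np.isnan(fit.t["BFK"])
    ref = sm.OLS(y, dm.X.to_numpy()[:, :7]).fit()
    assert np.allclose(fit.coef.to_numpy()[:7], ref.params, atol=1e-8)
    assert np.allclose(fit.t.to_numpy()[:7], ref.tvalues, atol=1e-8)


def test_saturated_model_is_error():
    dm = build_design(_design(reps=1, media=True))
    # 7 + 1 media samples, 8 columns -> zero residual df
    with pytest.raises(ValidationError, match="saturated"):
        fit_feature(np.zeros(dm.X.shape[0]), dm)


def test_non_finite_response_is_error():
    dm = build_design(_design(reps=2, media=True))
    y = np.zeros(dm.X.shape[0])
    y[0] = np.nan
    with pytest.raises(ValidationError):
        fit_feature(y, dm)


# --- ensembles and tails --------------------------------------------------


def _feature_table(values: np.ndarray, sample_ids, prefix="f"):
    idx = pd.Index([f"{prefix}{i}" for i in range(values.shape[0])], name="feature_id")
    return FeatureTable(pd.DataFrame(values, index=idx, columns=sample_ids))


def test_null_ensemble_t_medians_near_zero():
    rng = np.random.default_rng(5)
    design = _design(reps=5, media=True)
    dm = build_design(design)
    areas = np.exp(rng.normal(10, 0.5, (100, dm.X.shape[0])))
    ens = fit_ensemble(_feature_table(areas, dm.sample_ids), dm)
    assert ens.t.drop(columns="intercept").median().abs().max() < 0.5
    assert len(ens.t) == 100
    # summaries are recomputable from the matrix
    assert np.allclose(ens.summaries["iqr"], ens.t.quantile(0.75) - ens.t.quantile(0.25))


def test_single_feature_ensemble():
    design = _design(reps=2, media=True)
    dm = build_design(design)
    rng = np.random.default_rng(0)
    areas = np.exp(rng.normal(10, 0.3, (1, dm.X.shape[0])))
    ens = fit_ensemble(_feature_table(areas, dm.sample_ids), dm)
    assert ens.t.shape[0] == 1 and not ens.failures


def test_planted_threeway_feature_tops_the_ensemble():
    rng = np.random.default_rng(9)
    design = _design(reps=5, media=True)
    dm = build_design(design)
    n = dm.X.shape[0]
    log_areas = rng.normal(10, 0.5, (50, n))
    # feature 0: strong three-way effect via the containment code
    bfk_code = dm.X["BFK"].to_numpy()
    log_areas[0] = 10 + 4.0 * bfk_code + rng.normal(0, 0.5, n)
    ens = fit_ensemble(_feature_table(np.exp(log_areas), dm.sample_ids), dm)
    assert ens.t["BFK"].idxmax() == "f0"
    upper, _ = tail_select(ens, "BFK", 2.5)
    assert "f0" in upper


def test_tail_counts_at_two_and_a_half_percent():
    design = _design(reps=2, media=True)
    dm = build_design(design)

    class FakeEns:
        aliased = []
        t = pd.DataFrame({"BFK": np.arange(1000.0)},
                         index=[f"f{i}" for i in range(1000)])

    upper, lower = tail_select(FakeEns(), "BFK", 2.5)
    assert len(upper) == 25 and len(lower) == 25

    class Small:
        aliased = []
        t = pd.DataFrame({"BFK": np.arange(40.0)}, index=[f"f{i}" for i in range(40)])

    upper, lower = tail_select(Small(), "BFK", 2.5)
    assert len(upper) == 1


def test_tail_select_includes_threshold_ties():
    class Tied:
        aliased = []
        t = pd.DataFrame({"BFK": np.ones(10)}, index=[f"f{i}" for i in range(10)])

    upper, lower = tail_select(Tied(), "BFK", 2.5)
    assert len(upper) == 10 and len(lower) == 10


def test_tail_select_rejects_aliased_term():
    class Aliased:
        aliased = ["BFK"]
        t = pd.DataFrame({"BFK": [np.nan]}, index=["f0"])

    with pytest.raises(ValidationError):
        tail_select(Aliased(), "BFK", 2.5)


def test_permuted_labels_destroy_planted_tail_enrichment():
    """Shuffling sample labels leaves planted features no better than chance."""
    rng = np.random.default_rng(21)
    design = _design(reps=5, media=True)
    dm = build_design(design)
    n = dm.X.shape[0]
    log_areas = rng.normal(10, 0.5, (200, n))
    bfk_code = dm.X["BFK"].to_numpy()
    planted = [f"f{i}" for i in range(5)]
    log_areas[:5] += 3.0 * bfk_code
    ft = _feature_table(np.exp(log_areas), dm.sample_ids)
    hits = 0
    for _ in range(20):
        perm = rng.permutation(n)
        shuffled = FeatureTable(
            pd.DataFrame(ft.areas.to_numpy()[:, perm], index=ft.areas.index,
                         columns=ft.areas.columns)
        )
        ens = fit_ensemble(shuffled, dm)
        upper, _ = tail_select(ens, "BFK", 2.5)
        hits += len(set(planted) & set(upper))
    # 5 planted out of 200 features, 2.5% tail -> expected hits/round ~ 0.125
    assert hits <= 10


def test_zero_noise_fit_recovers_every_planted_effect(zero_noise_study):
    """With sigma=0 the baseline-augmented containment fit interpolates the
    generator's model exactly for every non-media feature."""
    st = zero_noise_study
    dm = build_design(st.design, series="wt", include_baseline=True)
    ens = fit_ensemble(st.features, dm, offset=0.0)
    non_media = [
        f for f in st.truth.feature_terms.index if f not in st.truth.media_features
    ]
    got = ens.coef.loc[non_media, list(TERMS)].to_numpy()
    want = st.truth.feature_terms.loc[non_media].to_numpy()
    assert np.allclose(got, want, atol=1e-8)
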