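import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cocomet.design import Condition, Sample, StudyDesign
from cocomet.errors import ValidationError
from cocomet.io import BgcCatalog, BgcRegion, CountMatrix
from cocomet.transcript import (
    ExpressionMatrix,
    bgc_expression,
    cpm,
    lfc_table,
    low_expression_filter,
    percent_change,
    psi_effect_lfc,
    series_percent_change,
)


def _cm(data, genes):
    df = pd.DataFrame(data)
    df.index = pd.Index(genes, name="gene_id")
    return CountMatrix(df.astype(np.int64))


# --- CPM ------------------------------------------------------------------


def test_cpm_definition():
    cm = _cm({"s1": [10, 30, 60]}, ["B:g1", "B:g2", "B:g3"])
    expr = cpm(cm)
    assert np.allclose(expr.cpm["s1"], [100000, 300000, 600000])


def test_cpm_columns_sum_to_one_million(small_study):
    expr = cpm(small_study.counts)
    sums = expr.cpm.sum(axis=0)
    assert np.allclose(sums, 1e6, rtol=1e-6)


def test_cpm_zero_total_sample_is_error():
    cm = _cm({"s1": [1, 2], "s2": [0, 0]}, ["B:g1", "B:g2"])
    with pytest.raises(ValidationError) as e:
        cpm(cm)
    assert "s2" in str(e.value)


# --- low-expression filter ------------------------------------------------


def test_filter_threshold_interpolates_between_order_statistics():
    # maxima 1..100, 2.5th percentile -> threshold 3.475, genes {1,2,3} removed
    genes = [f"B:g{i}" for i in range(1, 101)]
    mat = pd.DataFrame({"s1": np.arange(1.0, 101.0)}, index=genes)
    expr = ExpressionMatrix(mat)
    kept, removed = low_expression_filter(expr, percentile=2.5)
    assert sorted(removed) == ["B:g1", "B:g2", "B:g3"]
    assert len(kept.cpm) == 97
    assert np.percentile(mat["s1"], 2.5) == pytest.approx(3.475)


def test_filter_percentile_zero_removes_nothing():
    mat = pd.DataFrame({"s1": [5.0, 1.0, 9.0]}, index=["B:a", "B:b", "B:c"])
    kept, removed = low_expression_filter(ExpressionMatrix(mat), percentile=0)
    assert removed == [] and len(kept.cpm) == 3


def test_filter_keeps_ties_at_threshold():
    mat = pd.DataFrame({"s1": [4.0] * 10}, index=[f"B:g{i}" for i in range(10)])
    kept, removed = low_expression_filter(ExpressionMatrix(mat), percentile=2.5)
    assert removed == []


def test_filter_is_per_genome_and_matches_brute_force():
    rng = np.random.default_rng(42)
    genes = [f"B:g{i}" for i in range(40)] + [f"K:g{i}" for i in range(60)]
    mat = pd.DataFrame(
        rng.lognormal(3, 1, (100, 6)), index=genes, columns=[f"s{j}" for j in range(6)]
    )
    _, removed = low_expression_filter(ExpressionMatrix(mat), percentile=7.5)
    maxima = mat.max(axis=1)
    expected = []
    for genome in ("B", "K"):
        vals = maxima[[g for g in genes if g.startswith(genome)]]
        thr = np.percentile(vals, 7.5)
        expected.extend(vals.index[vals < thr])
    assert sorted(removed) == sorted(expected)


# --- psi estimator --------------------------------------------------------


def test_psi_is_zero_for_identical_conditions():
    assert psi_effect_lfc(7, 7, 1e6, 1e6) == pytest.approx(0.0)


def test_psi_large_count_convergence_to_log2_ratio():
    assert psi_effect_lfc(1000, 100, 1e6, 1e6) == pytest.approx(np.log2(10), abs=0.01)


def test_psi_finite_at_zero_counts():
    assert np.isfinite(psi_effect_lfc(0, 0, 1e6, 1e6))
    assert np.isfinite(psi_effect_lfc(0, 50, 1e6, 1e6))


def test_psi_adjusts_for_library_size():
    # doubling library A halves relative abundance: shift of exactly -1 log2
    base = psi_effect_lfc(100, 100, 1e6, 1e6)
    assert psi_effect_lfc(100, 100, 2e6, 1e6) == pytest.approx(base - 1.0)


@given(
    a=st.integers(min_value=0, max_value=10_000),
    b=st.integers(min_value=0, max_value=10_000),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_psi_antisymmetry(a, b):
    assert psi_effect_lfc(a, b, 1e6, 1e6) == pytest.approx(
        -psi_effect_lfc(b, a, 1e6, 1e6), abs=1e-12
    )


@given(k=st.integers(min_value=0, max_value=5_000))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_psi_strictly_increasing_in_first_count(k):
    assert psi_effect_lfc(k + 1, 37, 1e6, 1e6) > psi_effect_lfc(k, 37, 1e6, 1e6)


def test_psi_rejects_bad_domains():
    with pytest.raises(ValidationError):
        psi_effect_lfc(-1, 2, 1e6, 1e6)
    with pytest.raises(ValidationError):
        psi_effect_lfc(1, 2, 0, 1e6)


# --- lfc table ------------------------------------------------------------


def _toy_design(reps=2):
    samples = []
    for cond in ("B", "BF"):
        species = frozenset(cond)
        for r in range(1, reps + 1):
            samples.append(Sample(f"{cond}_r{r}", Condition(species), r, "wt"))
    return StudyDesign(samples)


def test_lfc_zero_for_identical_replicate_counts():
    design = _toy_design()
    cm = _cm(
        {"B_r1": [50, 100], "B_r2": [50, 100], "BF_r1": [50, 100], "BF_r2": [50, 100]},
        ["B:g1", "B:g2"],
    )
    table = lfc_table(cm, design)
    assert np.allclose(table["psi_lfc"], 0.0)


def test_lfc_recovers_tenfold_change_with_equal_libraries():
    design = _toy_design()
    # unit sums 1000 vs 100; a balancing gene keeps genome library sizes equal
    cm = _cm(
        {"B_r1": [50, 1000], "B_r2": [50, 1000], "BF_r1": [500, 550], "BF_r2": [500, 550]},
        ["B:g1", "B:g2"],
    )
    table = lfc_table(cm, design).set_index("unit_id")
    assert table.loc["B:g1", "psi_lfc"] == pytest.approx(np.log2(10), abs=0.01)


def test_lfc_median_centering_zeroes_the_genome_median():
    design = _toy_design()
    rng = np.random.default_rng(1)
    counts = {
        s.sample_id: rng.integers(1, 500, size=21) for s in design
    }
    cm = _cm(counts, [f"B:g{i}" for i in range(21)])
    table = lfc_table(cm, design, center=True)
    assert table.groupby("contrast")["psi_lfc"].median().abs().max() < 1e-12


def test_lfc_missing_monoculture_is_error():
    samples = [
        Sample("BF_r1", Condition(frozenset("BF")), 1, "wt"),
        Sample("BF_r2", Condition(frozenset("BF")), 2, "wt"),
    ]
    cm = _cm({"BF_r1": [5], "BF_r2": [6]}, ["B:g1"])
    with pytest.raises(ValidationError):
        lfc_table(cm, StudyDesign(samples))


# --- BGC aggregation ------------------------------------------------------


def test_bgc_expression_sums_member_cpm():
    mat = pd.DataFrame({"s1": [100.0, 200.0, 50.0, 7.0]},
                       index=["B:g1", "B:g2", "B:g3", "B:g4"])
    cat = BgcCatalog([BgcRegion("r1", "B", "x", ("B:g1", "B:g2", "B:g3"))])
    totals, report = bgc_expression(ExpressionMatrix(mat), cat)
    assert totals.loc["r1", "s1"] == pytest.approx(350.0)
    assert report.loc["r1", "n_filtered"] == 0


def test_bgc_expression_reports_filtered_members():
    mat = pd.DataFrame({"s1": [50.0]}, index=["B:g2"])
    cat = BgcCatalog([BgcRegion("r1", "B", "x", ("B:g1", "B:g2"))])
    totals, report = bgc_expression(ExpressionMatrix(mat), cat)
    assert totals.loc["r1", "s1"] == pytest.approx(50.0)
    assert report.loc["r1", "n_filtered"] == 1


def test_bgc_expression_empty_catalog():
    mat = pd.DataFrame({"s1": [50.0]}, index=["B:g1"])
    totals, report = bgc_expression(ExpressionMatrix(mat), BgcCatalog([]))
    assert totals.empty and report.empty


# --- percent change -------------------------------------------------------


@pytest.mark.parametrize(
    "mut,wt,expected", [(11.41, 1.0, 1041.0), (2.0, 1.0, 100.0), (0.5, 1.0, -50.0)]
)
def test_percent_change_convention(mut, wt, expected):
    assert percent_change(mut, wt) == pytest.approx(expected)


def test_percent_change_zero_wildtype_is_domain_error():
    with pytest.raises(ValidationError):
        percent_change(1.0, 0.0)


def test_mutant_boost_shows_up_as_percent_increase(small_study):
    """Knockout-coculture boosts planted on B. cereus siderophore BGCs are measured."""
    st = small_study
    expr = cpm(st.counts)
    totals, _ = bgc_expression(expr, st.truth.bgc_catalog)
    pc = series_percent_change(totals, st.design).set_index(["region_id", "condition"])
    # CPM ratios are compressed by library-composition shifts (the boosted
    # regions inflate the knockout libraries), so assert direction and order
    measured = {
        rid: pc.loc[(rid, "BK"), "percent_change"]
        for rid in st.truth.mutant_boost
    }
    assert all(v > 200.0 for v in measured.values())
    boosts = st.truth.mutant_boost
    hi = max(boosts, key=boosts.get)
    lo = min(boosts, key=boosts.get)
    assert measured[hi] > measured[lo]
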