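"""Planted-signal recovery experiments over repeated simulations.

These drive the end-to-end checks that the pipeline recovers what the
generator planted: three-way-only features must land in the upper tail of the
three-way t ensemble, planted BGC log2 fold changes must be recovered by the
Ψ estimator, and knockout-dependent features must be tallied unique to the
wild-type series.  Each experiment re-simulates under ``n_seeds`` independent
seeds derived from one base seed and reports per-seed success.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .design import SERIES_WT, StudyDesign
from .factorial import build_design, fit_ensemble, tail_select
from .presence import condition_tallies, detection_baseline, media_features, presence_matrix
from .simulate import (
    PlantedEffects,
    SimulationConfig,
    default_design,
    generate_counts,
    generate_feature_table,
    planted_truth,
)
from .transcript import lfc_table


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


@dataclass
class TailRecoveryResult:
    n_seeds: int
    all_in_tail: np.ndarray  # bool per seed: every planted feature in upper tail
    max_is_flagship: np.ndarray  # bool per seed: ensemble argmax t is the flagship
    flagship_t: np.ndarray  # the flagship feature's three-way t per seed

    @property
    def tail_rate(self) -> float:
        return float(self.all_in_tail.mean())

    @property
    def flagship_rate(self) -> float:
        return float(self.max_is_flagship.mean())


def threeway_tail_recovery(
    config: SimulationConfig,
    n_seeds: int = 100,
    seed: int = 0,
    tail_percentile: float = 2.5,
) -> TailRecoveryResult:
    """Do planted three-way-only features reach the upper BFK t tail?

    Simulates the wild-type series plus media blanks under ``n_seeds``
    independent seeds, fits the baseline-augmented containment model per
    feature, and checks (a) that every planted three-way feature falls in the
    upper ``tail_percentile`` tail of the three-way term's t ensemble and (b)
    that the feature with the largest planted effect carries the ensemble's
    maximum t.
    """
    design = default_design(config, series=(SERIES_WT,))
    seeds = _child_seeds(seed, 2 * n_seeds).reshape(2, n_seeds)
    all_in, max_is, flag_t = [], [], []
    for i in range(n_seeds):
        truth = planted_truth(config, int(seeds[0, i]), design)
        features = generate_feature_table(design, truth, int(seeds[1, i]))
        dm = build_design(design, "containment", include_baseline=True, series=SERIES_WT)
        ens = fit_ensemble(features, dm)
        upper, _ = tail_select(ens, "BFK", tail_percentile)
        planted = truth.threeway_only_features
        all_in.append(planted <= set(upper))
        t = ens.t["BFK"]
        max_is.append(t.idxmax() == truth.community_feature)
        flag_t.append(float(t[truth.community_feature]))
    return TailRecoveryResult(
        n_seeds, np.array(all_in), np.array(max_is), np.array(flag_t)
    )


@dataclass
class BgcRecoveryResult:
    n_seeds: int
    per_seed_ok: np.ndarray  # bool per seed: every planted region within tolerance
    errors: pd.DataFrame  # region_id, condition, lfc, per-seed absolute error stats

    @property
    def rate(self) -> float:
        return float(self.per_seed_ok.mean())


def bgc_lfc_recovery(
    config: SimulationConfig,
    n_seeds: int = 100,
    seed: int = 0,
    rel_tol: float = 0.15,
    abs_tol: float = 0.1,
) -> BgcRecoveryResult:
    """Is each planted BGC log2 fold change recovered by the Ψ pipeline?

    A planted value delta passes when the estimated region-level Ψ LFC in the
    planted contrast is within ``|delta| * rel_tol + abs_tol`` of delta.  Only
    regions with a nonzero planted delta are scored.
    """
    design = default_design(config, series=(SERIES_WT,))
    seeds = _child_seeds(seed, 2 * n_seeds).reshape(2, n_seeds)
    per_seed, err_rows = [], []
    for i in range(n_seeds):
        truth = planted_truth(config, int(seeds[0, i]), design)
        counts = generate_counts(design, truth, int(seeds[1, i]))
        table = lfc_table(counts, design, truth.bgc_catalog, series=SERIES_WT)
        est = table.set_index(["unit_id", "condition"])["psi_lfc"]
        ok = True
        for row in truth.bgc_planted.itertuples(index=False):
            if row.lfc == 0:
                continue
            got = est[(row.region_id, row.condition)]
            err = abs(got - row.lfc)
            err_rows.append(
                {
                    "seed_index": i,
                    "region_id": row.region_id,
                    "condition": row.condition,
                    "lfc": row.lfc,
                    "abs_error": err,
                }
            )
            ok &= err <= abs(row.lfc) * rel_tol + abs_tol
        per_seed.append(ok)
    return BgcRecoveryResult(n_seeds, np.array(per_seed), pd.DataFrame(err_rows))


@dataclass
class KnockoutBookkeeping:
    threshold: float
    unique_to_wt: frozenset
    unique_to_kec: frozenset
    shared: frozenset
    kec_features_recovered: bool  # planted kec set == unique-to-wt set
    tallies: object


def knockout_bookkeeping(
    config: SimulationConfig, seed: int = 0, rule: str = "median"
) -> KnockoutBookkeeping:
    """Run the presence pipeline on one full synthetic study and compare series.

    The detection baseline is anchored on the synthetic koreenceine A/B/C
    stand-ins in knockout cultures; media-derived features are subtracted;
    tallies compare wild-type and knockout series over the common feature
    universe.
    """
    from .simulate import generate_study

    study = generate_study(config, seed)
    truth = study.truth
    kec_samples = [
        s.sample_id
        for s in study.design.non_media_samples("kec")
        if "K" in s.condition.species
    ]
    threshold = detection_baseline(
        study.features, truth.kec_anchor_features, kec_samples
    )
    med = media_features(study.features, study.design, threshold, rule)
    calls_wt = presence_matrix(
        study.features, study.design, threshold, rule, series="wt", exclude=med
    )
    calls_kec = presence_matrix(
        study.features, study.design, threshold, rule, series="kec", exclude=med
    )
    tallies = condition_tallies(calls_wt, calls_kec)
    return KnockoutBookkeeping(
        threshold=threshold,
        unique_to_wt=tallies.unique_first_ids,
        unique_to_kec=tallies.unique_second_ids,
        shared=tallies.shared_ids,
        kec_features_recovered=(
            tallies.unique_first_ids == truth.kec_dependent_features
        ),
        tallies=tallies,
    )
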