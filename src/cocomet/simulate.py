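"""Synthetic multi-omics community study generator with planted ground truth.

Emulates the statistical structure of a three-member coculture experiment:

* a molecular-feature table over 7 culture conditions (B, F, K, BF, BK, FK,
  BFK) x 2 genotype series (wild-type and koreenceine-null K) x 5 replicates,
  plus 5 shared sterile-media blanks;
* a gene count matrix for the same culture samples, negative-binomially
  distributed with planted BGC-level condition fold changes.

Feature abundances are log-normal: log peak area follows the containment-coded
factorial model exactly (additive effects on the log scale), so the
downstream per-feature linear model is correctly specified under the null.
"Absence" is encoded as a detection floor/10 level rather than zero so log
transforms stay finite, mirroring LC-MS noise floors.  Every non-media
feature is tied to a producer (a species, a pair, or the full triple) whose
containment effect places the absent side exactly at that noise level;
media-derived features sit at a constant media level in every sample.
Koreenceine-dependent features are additionally forced to the noise level in
every koreenceine-null sample, standing in for the knockout's missing product
and its regulatory cascade.

All randomness flows from one integer seed through child seeds drawn in a
fixed order (truth, counts, features); identical (config, seed) pairs yield
identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import (
    CONDITION_ORDER,
    Condition,
    KEC_NULL,
    NOT_APPLICABLE,
    Sample,
    SERIES_KEC,
    SERIES_WT,
    SPECIES,
    StudyDesign,
    WILD_TYPE,
)
from .errors import ConfigurationError, DimensionError
from .factorial import TERMS, encode_condition
from .io import (
    BgcCatalog,
    BgcRegion,
    CountMatrix,
    FeatureTable,
    write_bgc_catalog,
    write_count_matrix,
    write_feature_table,
    write_sample_sheet,
    write_table,
)

#: BGC product labels per genome, cycled over regions
PRODUCT_LABELS = {
    "B": ("bacillibactin", "petrobactin", "kanosamine", "zwittermicin A"),
    "F": ("flexirubin", "lanthipeptide", "terpene", "siderophore"),
    "K": ("koreenceine", "lokisin", "pyoverdine", "hydrogen cyanide"),
}

FEATURE_CLASSES = ("regular", "media", "kec", "pairwise_only", "threeway_only")


@dataclass
class SimulationConfig:
    """Study-condition settings for the synthetic generator.

    Defaults are a desk-scale rendition of the study design: 1,000 molecular
    features of which 93 are coculture-only (75 pairwise-only + 18
    three-way-only), 5 replicates per condition, 500 genes per genome.
    ``n_features`` and friends scale up to experiment scale via overrides.
    """

    # molecular features
    n_features: int = 1000
    media_fraction: float = 0.10
    n_kec_features: int = 20
    n_threeway_only: int = 18
    n_pairwise_only: int = 75
    producer_effect_mean: float = 2.0
    producer_effect_sd: float = 0.4
    producer_effect_min: float = 1.2
    frac_modulated: float = 0.3
    modulation_sd: float = 0.3
    threeway_effect: float = 3.0
    # flagship "community metabolite": separated from the three-way bulk by
    # >4 coefficient SEs (SE_BFK ~ sigma*0.63 at 5 reps) so it reliably
    # carries the ensemble's maximum three-way t
    community_effect: float = 6.0
    pairwise_only_effect: float = 3.0
    kec_effect: float = 3.0
    noise_sigma: float = 0.5
    detection_floor: float = 1e5  # peak-area units; absence encoded at floor/10
    media_log_area: float = math.log(1e6)
    # layout
    n_replicates: int = 5
    n_media_replicates: int = 5
    # transcriptome
    n_genes_per_genome: int = 500
    n_bgc_per_genome: int = 4
    bgc_size: int = 8
    gene_mean_log: float = math.log(200.0)
    gene_mean_sd: float = 1.0
    planted_bgc_lfc: Tuple[float, ...] = (-2.0, 1.0, 3.0, 0.0)
    mutant_boost: Dict[str, float] = field(
        default_factory=lambda: {"bacillibactin": 3.5, "petrobactin": 4.5}
    )
    nb_dispersion: float = 0.05
    library_size: int = 1_000_000
    library_jitter: Tuple[float, float] = (0.7, 1.3)

    def __post_init__(self):
        positive = {
            "n_features": self.n_features,
            "n_replicates": self.n_replicates,
            "n_media_replicates": self.n_media_replicates,
            "n_genes_per_genome": self.n_genes_per_genome,
            "library_size": self.library_size,
            "detection_floor": self.detection_floor,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ConfigurationError(f"{name} must be positive, got {val}")
        for name, val in (
            ("noise_sigma", self.noise_sigma),
            ("nb_dispersion", self.nb_dispersion),
            ("n_kec_features", self.n_kec_features),
            ("n_threeway_only", self.n_threeway_only),
            ("n_pairwise_only", self.n_pairwise_only),
            ("n_bgc_per_genome", self.n_bgc_per_genome),
        ):
            if val < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {val}")
        if not 0 <= self.media_fraction < 1:
            raise ConfigurationError("media_fraction must be in [0, 1)")
        if self.n_bgc_per_genome * self.bgc_size > self.n_genes_per_genome:
            raise ConfigurationError("BGC regions exceed genes per genome")
        planted = self.n_media + self.n_kec_features + self.n_threeway_only + self.n_pairwise_only
        if planted > self.n_features:
            raise ConfigurationError(
                f"feature classes ({planted}) exceed n_features ({self.n_features})"
            )

    @property
    def n_media(self) -> int:
        return int(round(self.n_features * self.media_fraction))

    @property
    def absence_log_area(self) -> float:
        return math.log(self.detection_floor / 10.0)


@dataclass
class PlantedEffects:
    """Ground truth of a synthetic study, for parameter-recovery tests."""

    feature_terms: pd.DataFrame  # features x 8 model terms (log-area units)
    feature_class: pd.Series
    media_features: FrozenSet[str]
    kec_dependent_features: FrozenSet[str]
    kec_anchor_features: Tuple[str, ...]  # synthetic koreenceine A/B/C stand-ins
    pairwise_only_features: FrozenSet[str]
    threeway_only_features: FrozenSet[str]
    community_feature: Optional[str]
    gene_base_mean: pd.Series  # namespaced gene -> baseline NB mean
    gene_condition_lfc: pd.DataFrame  # genes x condition names, log2 units
    bgc_catalog: BgcCatalog
    bgc_planted: pd.DataFrame  # region_id, condition, lfc
    mutant_boost: Dict[str, float]  # region_id -> extra log2 FC in kec series
    kec_region: Optional[str]
    library_sizes: Dict[str, int]
    noise_sigma: float
    nb_dispersion: float
    detection_floor: float
    media_log_area: float


@dataclass
class SyntheticStudy:
    design: StudyDesign
    counts: CountMatrix
    features: FeatureTable
    truth: PlantedEffects
    seed: int


def default_design(config: SimulationConfig, series: Sequence[str] = (SERIES_WT, SERIES_KEC)) -> StudyDesign:
    """The study layout: each series x 7 conditions x replicates, plus media blanks."""
    samples = []
    for ser in series:
        for cond_name in CONDITION_ORDER:
            species = frozenset(cond_name)
            if "K" in species:
                genotype = KEC_NULL if ser == SERIES_KEC else WILD_TYPE
            else:
                genotype = NOT_APPLICABLE
            condition = Condition(species, genotype)
            for rep in range(1, config.n_replicates + 1):
                samples.append(
                    Sample(f"{ser}_{cond_name}_r{rep}", condition, rep, ser)
                )
    for rep in range(1, config.n_media_replicates + 1):
        samples.append(Sample(f"media_r{rep}", Condition(frozenset()), rep, None))
    return StudyDesign(samples)


def _term_index(name: str) -> int:
    return TERMS.index(name)


def planted_truth(
    config: SimulationConfig, seed: int, design: Optional[StudyDesign] = None
) -> PlantedEffects:
    """Draw the ground truth (effect sizes, class memberships, gene means, libraries)."""
    rng = np.random.default_rng(seed)
    if design is None:
        design = default_design(config)
    n = config.n_features
    ids = np.array([f"ft{i:05d}" for i in range(n)])
    perm = rng.permutation(n)
    bounds = np.cumsum(
        [config.n_media, config.n_kec_features, config.n_threeway_only, config.n_pairwise_only]
    )
    media_idx = perm[: bounds[0]]
    kec_idx = perm[bounds[0] : bounds[1]]
    three_idx = perm[bounds[1] : bounds[2]]
    pair_idx = perm[bounds[2] : bounds[3]]
    reg_idx = perm[bounds[3] :]

    classes = np.full(n, "regular", dtype=object)
    classes[media_idx] = "media"
    classes[kec_idx] = "kec"
    classes[three_idx] = "threeway_only"
    classes[pair_idx] = "pairwise_only"

    floor_log = config.absence_log_area
    T = np.zeros((n, len(TERMS)))

    # regular features: producer species main effect; absent side sits at floor/10
    m = len(reg_idx)
    if m:
        producer_col = rng.integers(1, 4, size=m)  # columns 1..3 = B, F, K mains
        p = np.clip(
            rng.normal(config.producer_effect_mean, config.producer_effect_sd, m),
            config.producer_effect_min,
            None,
        )
        T[reg_idx, 0] = floor_log + p
        T[reg_idx, producer_col] = p
        # positive pairwise modulation on a pair containing the producer: the
        # absent/blank side stays exactly at the noise floor, so presence
        # patterns remain "producer present" and blanks stay feature-free
        modulated = rng.random(m) < config.frac_modulated
        if modulated.any():
            rows = reg_idx[modulated]
            pair_options = {
                1: (_term_index("BF"), _term_index("BK")),
                2: (_term_index("BF"), _term_index("FK")),
                3: (_term_index("BK"), _term_index("FK")),
            }
            pick = rng.integers(0, 2, size=modulated.sum())
            col = np.array(
                [pair_options[pc][k] for pc, k in zip(producer_col[modulated], pick)]
            )
            T[rows, col] += np.abs(rng.normal(0, config.modulation_sd, len(rows)))

    # koreenceine-dependent features: K-produced, plus knockout forcing downstream
    if len(kec_idx):
        T[kec_idx, 0] = floor_log + config.kec_effect
        T[kec_idx, _term_index("K")] = config.kec_effect

    # three-way-only features; the first is the flagship community metabolite
    community = None
    if len(three_idx):
        effects = np.full(len(three_idx), config.threeway_effect)
        effects[0] = config.community_effect
        T[three_idx, 0] = floor_log + effects
        T[three_idx, _term_index("BFK")] = effects
        community = ids[three_idx[0]]

    # pairwise-only features, cycled over the three pairs
    if len(pair_idx):
        pair_cols = np.array(
            [_term_index(p) for p in ("BF", "BK", "FK")]
        )[np.arange(len(pair_idx)) % 3]
        T[pair_idx, 0] = floor_log + config.pairwise_only_effect
        T[pair_idx, pair_cols] = config.pairwise_only_effect

    feature_terms = pd.DataFrame(T, index=ids, columns=list(TERMS))
    feature_terms.index.name = "feature_id"

    # transcriptome truth
    gene_ids, base_means = [], []
    regions: List[BgcRegion] = []
    cond_names = list(CONDITION_ORDER)
    lfc = {}
    bgc_rows = []
    mutant_boost: Dict[str, float] = {}
    kec_region = None
    for genome in SPECIES:
        genes = [f"{genome}:g{i:04d}" for i in range(config.n_genes_per_genome)]
        gene_ids.extend(genes)
        base_means.append(
            rng.lognormal(config.gene_mean_log, config.gene_mean_sd, len(genes))
        )
        cocultures = [c for c in cond_names if genome in c and len(c) > 1]
        labels = PRODUCT_LABELS[genome]
        for j in range(config.n_bgc_per_genome):
            rid = f"{genome}_bgc{j + 1}"
            members = tuple(genes[j * config.bgc_size : (j + 1) * config.bgc_size])
            product = labels[j % len(labels)]
            regions.append(BgcRegion(rid, genome, product, members))
            delta = config.planted_bgc_lfc[j % len(config.planted_bgc_lfc)]
            cond = cocultures[j % len(cocultures)]
            if delta != 0:
                for g in members:
                    lfc[(g, cond)] = delta
            bgc_rows.append({"region_id": rid, "condition": cond, "lfc": delta})
            if genome == "K" and product == "koreenceine":
                kec_region = rid
            if genome == "B" and product in config.mutant_boost:
                mutant_boost[rid] = config.mutant_boost[product]

    gene_base_mean = pd.Series(
        np.concatenate(base_means), index=gene_ids, name="base_mean"
    )
    gene_condition_lfc = pd.DataFrame(0.0, index=gene_ids, columns=cond_names)
    for (g, cond), val in lfc.items():
        gene_condition_lfc.loc[g, cond] = val

    library_sizes = {
        s.sample_id: int(
            round(config.library_size * rng.uniform(*config.library_jitter))
        )
        for s in design.non_media_samples()
    }
    if any(v <= 0 for v in library_sizes.values()):
        raise ConfigurationError("library sizes must be positive")

    kec_ids = tuple(ids[kec_idx])
    return PlantedEffects(
        feature_terms=feature_terms,
        feature_class=pd.Series(classes, index=ids, name="feature_class"),
        media_features=frozenset(ids[media_idx]),
        kec_dependent_features=frozenset(kec_ids),
        kec_anchor_features=kec_ids[:3],
        pairwise_only_features=frozenset(ids[pair_idx]),
        threeway_only_features=frozenset(ids[three_idx]),
        community_feature=community,
        gene_base_mean=gene_base_mean,
        gene_condition_lfc=gene_condition_lfc,
        bgc_catalog=BgcCatalog(regions),
        bgc_planted=pd.DataFrame(bgc_rows),
        mutant_boost=mutant_boost,
        kec_region=kec_region,
        library_sizes=library_sizes,
        noise_sigma=config.noise_sigma,
        nb_dispersion=config.nb_dispersion,
        detection_floor=config.detection_floor,
        media_log_area=config.media_log_area,
    )


def generate_feature_table(
    design: StudyDesign, truth: PlantedEffects, seed: int
) -> FeatureTable:
    """Draw log-normal peak areas from the planted factorial model.

    Log abundance of feature m in sample i is its intercept plus the planted
    effects times the containment codes of the sample's condition, plus
    N(0, noise_sigma); media-derived features sit at the media level in every
    sample, and koreenceine-dependent features are forced to the detection
    noise level (floor/10) in every koreenceine-null sample.  Peak areas are
    the exponentiated values.
    """
    if not len(design):
        raise DimensionError("empty design")
    if not len(truth.feature_terms):
        raise DimensionError("truth has no features")
    rng = np.random.default_rng(seed)
    ids = truth.feature_terms.index
    samples = list(design)
    codes = np.vstack(
        [encode_condition(s.condition, "containment") for s in samples]
    )  # n_samples x 8
    M = truth.feature_terms.to_numpy() @ codes.T  # features x samples

    is_media_feature = truth.feature_class.to_numpy() == "media"
    M[is_media_feature, :] = truth.media_log_area

    floor_log = math.log(truth.detection_floor / 10.0)
    kec_mask = truth.feature_class.to_numpy() == "kec"
    null_cols = np.array(
        [s.condition.genotype == KEC_NULL for s in samples], dtype=bool
    )
    if kec_mask.any() and null_cols.any():
        M[np.ix_(kec_mask, null_cols)] = floor_log

    if truth.noise_sigma > 0:
        M = M + rng.normal(0.0, truth.noise_sigma, M.shape)

    areas = pd.DataFrame(
        np.exp(M), index=ids, columns=[s.sample_id for s in samples]
    )
    mw = pd.Series(
        np.round(rng.uniform(150.0, 1500.0, len(ids)), 4), index=ids, name="mw"
    )
    if truth.community_feature is not None:
        mw[truth.community_feature] = 1127.7028  # flagship community metabolite
    rt = pd.Series(
        np.round(rng.uniform(0.5, 18.5, len(ids)), 2), index=ids, name="rt"
    )
    return FeatureTable(areas, mw, rt)


def generate_counts(
    design: StudyDesign, truth: PlantedEffects, seed: int
) -> CountMatrix:
    """Draw negative-binomial gene counts with planted condition fold changes.

    Per culture sample, relative expression of each present genome's genes is
    baseline * 2^(planted LFC for the condition); absent genomes contribute no
    reads.  The vector is scaled so the expected column total equals the
    sample's library size, then counts are drawn NB with the shared
    dispersion (Poisson in the dispersion -> 0 limit).  The koreenceine BGC is
    zeroed in knockout samples, and mutant-boost regions are up-shifted in
    knockout cocultures containing their genome.
    """
    rng = np.random.default_rng(seed)
    genes = truth.gene_base_mean.index
    gene_genome = np.array([g.split(":", 1)[0] for g in genes])
    base = truth.gene_base_mean.to_numpy()
    lfc = truth.gene_condition_lfc
    samples = design.non_media_samples()
    if not samples:
        raise DimensionError("design has no culture samples")

    region_genes = {
        r.region_id: np.isin(genes, r.genes) for r in truth.bgc_catalog
    }
    cols = {}
    for s in samples:
        lib = truth.library_sizes.get(s.sample_id)
        if lib is None:
            raise ConfigurationError(f"no library size for sample {s.sample_id!r}")
        if lib <= 0:
            raise ConfigurationError(f"zero library size for sample {s.sample_id!r}")
        present = np.isin(gene_genome, list(s.condition.species))
        rel = np.where(present, base * 2.0 ** lfc[s.condition.name].to_numpy(), 0.0)
        if s.condition.genotype == KEC_NULL:
            if truth.kec_region is not None:
                rel[region_genes[truth.kec_region]] = 0.0
            for rid, boost in truth.mutant_boost.items():
                region = truth.bgc_catalog.region(rid)
                if region.genome in s.condition.species:
                    mask = region_genes[rid] & present
                    rel[mask] *= 2.0**boost
        total = rel.sum()
        if total <= 0:
            raise ConfigurationError(
                f"sample {s.sample_id!r} has no expressed genes"
            )
        mu = rel / total * lib
        if truth.nb_dispersion > 0:
            size = 1.0 / truth.nb_dispersion
            draws = np.zeros(len(genes), dtype=np.int64)
            pos = mu > 0
            draws[pos] = rng.negative_binomial(size, size / (size + mu[pos]))
        else:
            draws = rng.poisson(mu).astype(np.int64)
        cols[s.sample_id] = draws
    counts = pd.DataFrame(cols, index=genes)
    counts.index.name = "gene_id"
    return CountMatrix(counts)


def generate_study(config: SimulationConfig, seed: int) -> SyntheticStudy:
    """Compose truth, counts and features under one seed on the default layout."""
    rng = np.random.default_rng(seed)
    truth_seed, counts_seed, features_seed = rng.integers(0, 2**31 - 1, size=3)
    design = default_design(config)
    truth = planted_truth(config, int(truth_seed), design)
    counts = generate_counts(design, truth, int(counts_seed))
    features = generate_feature_table(design, truth, int(features_seed))
    return SyntheticStudy(design, counts, features, truth, seed)


def write_study(study: SyntheticStudy, outdir) -> Dict[str, Path]:
    """Write the standard pipeline inputs plus the planted truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "sample_sheet.tsv",
        "features": outdir / "features.csv",
        "bgc": outdir / "bgc_catalog.tsv",
        "truth_features": outdir / "truth_feature_terms.tsv",
        "truth_meta": outdir / "truth_meta.json",
    }
    write_count_matrix(study.counts, paths["counts"])
    write_sample_sheet(study.design, paths["samples"])
    write_feature_table(study.features, paths["features"])
    write_bgc_catalog(study.truth.bgc_catalog, paths["bgc"])
    truth = study.truth
    terms = truth.feature_terms.copy()
    terms.insert(0, "feature_class", truth.feature_class)
    write_table(terms, paths["truth_features"])
    meta = {
        "seed": study.seed,
        "media_features": sorted(truth.media_features),
        "kec_dependent_features": sorted(truth.kec_dependent_features),
        "kec_anchor_features": list(truth.kec_anchor_features),
        "pairwise_only_features": sorted(truth.pairwise_only_features),
        "threeway_only_features": sorted(truth.threeway_only_features),
        "community_feature": truth.community_feature,
        "kec_region": truth.kec_region,
        "mutant_boost": truth.mutant_boost,
        "bgc_planted": truth.bgc_planted.to_dict(orient="records"),
        "library_sizes": truth.library_sizes,
        "noise_sigma": truth.noise_sigma,
        "nb_dispersion": truth.nb_dispersion,
        "detection_floor": truth.detection_floor,
    }
    with open(paths["truth_meta"], "w") as fh:
        json.dump(meta, fh, indent=1)
    return paths
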