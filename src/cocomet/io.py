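"""Readers and writers for the pipeline's tabular inputs and outputs.

Conventions (chosen to keep fixtures diffable and match the upstream
exporters): gene count matrices, sample sheets, BGC catalogs and all result
tables are TSV; the LC-MS molecular-feature table is CSV.  Sample ids are the
join key everywhere — no positional joining.  Floats are written with six
significant digits, so write/read round-trips reproduce values to that
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .design import (
    Condition,
    GENOTYPES,
    KEC_NULL,
    NOT_APPLICABLE,
    Sample,
    SERIES_KEC,
    SERIES_WT,
    StudyDesign,
    WILD_TYPE,
    parse_condition_string,
)
from .errors import ConfigurationError, ParseError, ValidationError

log = logging.getLogger("cocomet")

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Integer gene counts, genes (namespaced ``genome:gene``) x samples."""

    counts: pd.DataFrame  # int dtype, index gene ids, columns sample ids

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dupes[:5])}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")

    @property
    def genes(self) -> List[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def genome_of(self, gene_id: str) -> str:
        return gene_id.split(":", 1)[0]

    @property
    def genomes(self) -> List[str]:
        seen = {}
        for g in self.counts.index:
            seen.setdefault(self.genome_of(g), None)
        return list(seen)

    def genome_genes(self, genome: str) -> List[str]:
        return [g for g in self.counts.index if self.genome_of(g) == genome]


@dataclass
class FeatureTable:
    """LC-MS molecular features: peak areas per sample, optional MW (Da) and RT (min)."""

    areas: pd.DataFrame  # float, index feature ids, columns sample ids
    mw: Optional[pd.Series] = None
    rt: Optional[pd.Series] = None

    def __post_init__(self):
        if self.areas.index.has_duplicates:
            dupes = self.areas.index[self.areas.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dupes[:5])}")
        vals = self.areas.to_numpy()
        if np.isnan(vals).any():
            raise ValidationError("missing peak areas (upstream extractor gap-fills)")
        if (vals < 0).any():
            raise ValidationError("negative peak areas")
        if self.mw is None:
            self.mw = pd.Series(np.nan, index=self.areas.index, name="mw")
        if self.rt is None:
            self.rt = pd.Series(np.nan, index=self.areas.index, name="rt")

    @property
    def features(self) -> List[str]:
        return list(self.areas.index)

    @property
    def samples(self) -> List[str]:
        return list(self.areas.columns)


@dataclass(frozen=True)
class BgcRegion:
    region_id: str
    genome: str
    product_label: str
    genes: Tuple[str, ...]


@dataclass
class BgcCatalog:
    """Biosynthetic gene cluster regions and their member genes (one genome each)."""

    regions: List[BgcRegion] = field(default_factory=list)

    def __post_init__(self):
        owner: Dict[str, str] = {}
        ids = set()
        for r in self.regions:
            if r.region_id in ids:
                raise ValidationError(f"duplicate region id {r.region_id!r}")
            ids.add(r.region_id)
            for g in r.genes:
                if g in owner:
                    raise ValidationError(
                        f"gene {g!r} listed under regions {owner[g]!r} and {r.region_id!r}"
                    )
                owner[g] = r.region_id

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def region(self, region_id: str) -> BgcRegion:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise ValidationError(f"unknown region {region_id!r}")


# ---------------------------------------------------------------------------
# count matrix


def read_count_matrix(path) -> CountMatrix:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise ParseError("count matrix needs a gene id column and >=1 sample", path)
    gene_col = raw.columns[0]
    genes = raw[gene_col].astype(str)
    data = {}
    for col in raw.columns[1:]:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric % 1 != 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-integer or negative count {raw[col].iloc[i]!r} for gene "
                f"{genes.iloc[i]!r}, sample {col!r}",
                path,
                line=i + 2,
            )
        data[col] = numeric.astype(np.int64)
    df = pd.DataFrame(data)
    df.index = pd.Index(genes, name="gene_id")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValidationError(f"duplicate gene id(s) {list(dupes[:5])} in {path}")
    return CountMatrix(df)


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample sheet

_GENOTYPE_ALIASES = {
    "wild_type": WILD_TYPE,
    "wt": WILD_TYPE,
    "kec_null": KEC_NULL,
    "not_applicable": NOT_APPLICABLE,
    "na": NOT_APPLICABLE,
    "": NOT_APPLICABLE,
}


def read_sample_sheet(path) -> StudyDesign:
    """Parse a sample sheet TSV into a :class:`StudyDesign`.

    Required columns: ``sample_id``, ``condition`` (letters over B/F/K, or
    ``media``), ``genotype`` (wild_type / kec_null / not_applicable), and
    ``replicate``.  An optional ``series`` column ("wt"/"kec") separates the
    two genotype series; when absent it is derived from the genotype
    (kec_null -> "kec", otherwise "wt") for non-media samples.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["sample_id", "condition", "genotype", "replicate"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ParseError(f"sample sheet missing columns {missing}", path)
    has_series = "series" in raw.columns
    samples = []
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2
        species = parse_condition_string(row.condition, path, line)
        geno_raw = row.genotype.strip().lower()
        if geno_raw not in _GENOTYPE_ALIASES:
            raise ParseError(f"unknown genotype {row.genotype!r}", path, line)
        genotype = _GENOTYPE_ALIASES[geno_raw]
        if genotype == KEC_NULL and "K" not in species:
            raise ValidationError(
                f"kec_null genotype on K-free condition {row.condition!r} "
                f"(sample {row.sample_id!r}, {path}, line {line})"
            )
        try:
            condition = Condition(species, genotype)
        except ValidationError as e:
            raise ValidationError(f"{e} ({path}, line {line})") from None
        try:
            replicate = int(row.replicate)
        except ValueError:
            raise ParseError(f"bad replicate {row.replicate!r}", path, line) from None
        if condition.is_media:
            series = None
        elif has_series and row.series.strip():
            series = row.series.strip().lower()
            if series not in (SERIES_WT, SERIES_KEC):
                raise ParseError(f"unknown series {row.series!r}", path, line)
        else:
            series = SERIES_KEC if genotype == KEC_NULL else SERIES_WT
        samples.append(Sample(row.sample_id, condition, replicate, series))
    return StudyDesign(samples)


def write_sample_sheet(design: StudyDesign, path) -> None:
    rows = []
    for s in design:
        rows.append(
            {
                "sample_id": s.sample_id,
                "condition": s.condition.name,
                "genotype": s.condition.genotype,
                "replicate": s.replicate,
                "series": s.series or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature table


def read_feature_table(path, design: Optional[StudyDesign] = None) -> FeatureTable:
    """Read the molecular-feature CSV (feature_id, mw, rt, then one column per sample).

    Missing mw/rt are allowed; a missing area cell is a parse error (the
    upstream feature extractor gap-fills).  When ``design`` is given, sample
    columns not present in the design are an error.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    required = ["feature_id", "mw", "rt"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ParseError(f"feature table missing columns {missing}", path)
    sample_cols = [c for c in raw.columns if c not in required]
    if not sample_cols:
        raise ParseError("feature table has no sample columns", path)
    if design is not None:
        unknown = [c for c in sample_cols if c not in set(design.sample_ids)]
        if unknown:
            raise ValidationError(
                f"feature table has sample columns not in the design: {unknown} ({path})"
            )
    features = raw["feature_id"].astype(str)
    data = {}
    for col in sample_cols:
        empty = raw[col].isna() | (raw[col].astype(str).str.strip() == "")
        if empty.any():
            i = int(np.flatnonzero(empty.to_numpy())[0])
            raise ParseError(
                f"empty peak area for feature {features.iloc[i]!r}, sample {col!r}",
                path,
                line=i + 2,
            )
        numeric = pd.to_numeric(raw[col], errors="coerce")
        if numeric.isna().any():
            i = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(
                f"non-numeric peak area {raw[col].iloc[i]!r} for feature "
                f"{features.iloc[i]!r}, sample {col!r}",
                path,
                line=i + 2,
            )
        if (numeric < 0).any():
            i = int(np.flatnonzero((numeric < 0).to_numpy())[0])
            raise ValidationError(
                f"negative peak area {numeric.iloc[i]} for feature "
                f"{features.iloc[i]!r}, sample {col!r} ({path}, line {i + 2})"
            )
        data[col] = numeric.astype(float)
    areas = pd.DataFrame(data)
    areas.index = pd.Index(features, name="feature_id")
    mw = pd.to_numeric(raw["mw"], errors="coerce")
    rt = pd.to_numeric(raw["rt"], errors="coerce")
    mw.index = areas.index
    rt.index = areas.index
    return FeatureTable(areas, mw.rename("mw"), rt.rename("rt"))


def write_feature_table(ft: FeatureTable, path) -> None:
    out = pd.DataFrame(
        {"mw": ft.mw, "rt": ft.rt}, index=ft.areas.index
    ).join(ft.areas)
    out.to_csv(path, index_label="feature_id", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# BGC catalog


def read_bgc_catalog(path) -> BgcCatalog:
    """Read the BGC region catalog TSV (region_id, genome, product_label, gene_id).

    One row per member gene; rows are grouped by region preserving gene order.
    An empty file (header only) yields an empty, valid catalog.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = ["region_id", "genome", "product_label", "gene_id"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ParseError(f"BGC catalog missing columns {missing}", path)
    order: List[str] = []
    meta: Dict[str, Tuple[str, str]] = {}
    members: Dict[str, List[str]] = {}
    for i, row in enumerate(raw.itertuples(index=False)):
        rid = row.region_id
        if rid not in meta:
            order.append(rid)
            meta[rid] = (row.genome, row.product_label)
            members[rid] = []
        elif meta[rid][0] != row.genome:
            raise ValidationError(
                f"region {rid!r} spans genomes {meta[rid][0]!r} and {row.genome!r} "
                f"({path}, line {i + 2})"
            )
        members[rid].append(row.gene_id)
    regions = [
        BgcRegion(rid, meta[rid][0], meta[rid][1], tuple(members[rid]))
        for rid in order
    ]
    return BgcCatalog(regions)


def write_bgc_catalog(catalog: BgcCatalog, path) -> None:
    rows = []
    for r in catalog:
        for g in r.genes:
            rows.append(
                {
                    "region_id": r.region_id,
                    "genome": r.genome,
                    "product_label": r.product_label,
                    "gene_id": g,
                }
            )
    pd.DataFrame(
        rows, columns=["region_id", "genome", "product_label", "gene_id"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result tables and config


def write_table(table: pd.DataFrame, path, index: bool = True) -> None:
    """Write a result table as TSV with 6-significant-digit floats."""
    try:
        table.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    except OSError as e:
        raise OSError(f"cannot write table to {path}: {e}") from e


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


#: every tunable named by the pipeline modules; unknown config keys are an error
KNOWN_CONFIG_KEYS = frozenset(
    {
        # synthetic generator (SimulationConfig fields are validated there too)
        "n_features", "media_fraction", "n_kec_features", "n_threeway_only",
        "n_pairwise_only", "producer_effect_mean", "producer_effect_sd",
        "producer_effect_min", "modulation_sd", "frac_modulated",
        "threeway_effect", "community_effect", "pairwise_only_effect",
        "kec_effect", "noise_sigma", "detection_floor", "media_log_area",
        "n_replicates", "n_media_replicates", "n_genes_per_genome",
        "n_bgc_per_genome", "bgc_size", "gene_mean_log", "gene_mean_sd",
        "planted_bgc_lfc", "mutant_boost", "nb_dispersion", "library_size",
        "library_jitter",
        # transcript_bgc
        "cpm_method", "filter_percentile", "lfc_input", "lfc_prior", "center",
        # factorial_metabolome
        "coding", "baseline", "log_offset", "tail_percentile",
        # feature_presence
        "presence_rule", "baseline_rule",
        # profile_report
        "pca_scaling", "linkage_method",
    }
)


def read_config(path) -> dict:
    """Read the flat key-value YAML run configuration; unknown keys are an error."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} is not a flat key-value mapping")
    unknown = sorted(set(cfg) - KNOWN_CONFIG_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config keys {unknown} in {path}")
    return cfg
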