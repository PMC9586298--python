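"""Gene- and BGC-level expression quantification and Ψ effect-size fold changes.

Workflow: raw counts -> counts per million (CPM, plain library-size scaling)
-> per-genome low-expression filter (genes whose maximum CPM falls below the
2.5th percentile of their genome's maxima are dropped) -> BGC-wide expression
as the sum of member-gene CPMs -> Ψ log2 fold changes of each coculture
condition against the monoculture of the unit's genome.

The Ψ estimator is the posterior-mean ("optimal") effect-size log fold change
built from digamma functions with a pseudo-count prior; it is finite for any
non-negative counts, including zeros on either side:

    psi(kA, kB) = [ψ0(kA + a) − ψ0(kB + a)] / ln 2 − log2(LA / LB)

with ψ0 the digamma function, a the prior pseudo-count (default 0.5,
Jeffreys-type) and LA/LB the library sizes.  For large counts it converges to
the naive log2 ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import digamma

from .design import SPECIES, StudyDesign, condition_name
from .errors import ValidationError
from .io import BgcCatalog, CountMatrix

log = logging.getLogger("cocomet")

LN2 = np.log(2.0)


@dataclass
class ExpressionMatrix:
    """Counts-per-million expression, genes x samples."""

    cpm: pd.DataFrame

    @property
    def genes(self) -> List[str]:
        return list(self.cpm.index)

    @property
    def samples(self) -> List[str]:
        return list(self.cpm.columns)


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: each column scaled to sum to 1e6."""
    mat = counts.counts
    totals = mat.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"zero total counts for sample(s) {list(zero.index[:5])}"
        )
    return ExpressionMatrix(mat.div(totals, axis=1) * 1e6)


def low_expression_filter(
    expr: ExpressionMatrix,
    percentile: float = 2.5,
    groups: Optional[Dict[str, str]] = None,
) -> Tuple[ExpressionMatrix, List[str]]:
    """Drop, per genome, genes whose maximum CPM sits below that genome's percentile.

    For each genome the threshold is the empirical ``percentile`` (linear
    interpolation between order statistics) of the per-gene maxima across all
    samples; genes strictly below it are removed.  ``groups`` maps gene id to
    genome; by default the ``genome:`` prefix of the gene id is used.
    """
    if not 0 <= percentile < 100:
        raise ValidationError("percentile must be in [0, 100)")
    mat = expr.cpm
    if groups is None:
        groups = {g: g.split(":", 1)[0] for g in mat.index}
    genomes: Dict[str, List[str]] = {}
    for g in mat.index:
        try:
            genomes.setdefault(groups[g], []).append(g)
        except KeyError:
            raise ValidationError(f"gene {g!r} has no genome group") from None
    removed: List[str] = []
    maxima = mat.max(axis=1)
    for genome, genes in genomes.items():
        if not genes:
            raise ValidationError(f"empty genome group {genome!r}")
        vals = maxima[genes]
        threshold = np.percentile(vals.to_numpy(), percentile)
        removed.extend(vals.index[vals.to_numpy() < threshold])
    kept = mat.drop(index=removed)
    return ExpressionMatrix(kept), removed


def psi_effect_lfc(kA, kB, libA, libB, prior: float = 0.5):
    """Ψ posterior-mean log2 fold change of condition A over condition B.

    Accepts scalars or arrays; finite for all non-negative counts.
    """
    kA = np.asarray(kA, dtype=float)
    kB = np.asarray(kB, dtype=float)
    libA = np.asarray(libA, dtype=float)
    libB = np.asarray(libB, dtype=float)
    if (kA < 0).any() or (kB < 0).any():
        raise ValidationError("counts must be non-negative")
    if (libA <= 0).any() or (libB <= 0).any():
        raise ValidationError("library sizes must be positive")
    if prior <= 0:
        raise ValidationError("prior pseudo-count must be positive")
    out = (digamma(kA + prior) - digamma(kB + prior)) / LN2 - np.log2(libA / libB)
    return out if out.ndim else float(out)


def bgc_expression(
    expr: ExpressionMatrix, catalog: BgcCatalog
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """BGC-wide expression: the sum of member-gene CPMs per region and sample.

    Member genes absent from the (possibly filtered) expression matrix
    contribute zero; the second return value reports, per region, how many
    member genes were filtered out.  Regions with no surviving members are
    flagged with a warning and carry zeros.
    """
    present = set(expr.genes)
    totals = {}
    report_rows = []
    for r in catalog:
        members = [g for g in r.genes if g in present]
        missing = len(r.genes) - len(members)
        if members:
            totals[r.region_id] = expr.cpm.loc[members].sum(axis=0)
        else:
            log.warning("BGC region %s has no surviving member genes", r.region_id)
            totals[r.region_id] = pd.Series(0.0, index=expr.cpm.columns)
        report_rows.append(
            {
                "region_id": r.region_id,
                "genome": r.genome,
                "product_label": r.product_label,
                "n_members": len(r.genes),
                "n_filtered": missing,
            }
        )
    cols = ["region_id", "genome", "product_label", "n_members", "n_filtered"]
    table = pd.DataFrame(totals).T if totals else pd.DataFrame(columns=expr.cpm.columns)
    table.index.name = "region_id"
    report = pd.DataFrame(report_rows, columns=cols).set_index("region_id")
    return table, report


def _genome_species_map(genomes: Sequence[str], genome_species) -> Dict[str, str]:
    if genome_species is not None:
        return dict(genome_species)
    bad = [g for g in genomes if g not in SPECIES]
    if bad:
        raise ValidationError(
            f"cannot infer species for genomes {bad}; pass genome_species mapping"
        )
    return {g: g for g in genomes}


def lfc_table(
    counts: CountMatrix,
    design: StudyDesign,
    catalog: Optional[BgcCatalog] = None,
    series: Optional[str] = "wt",
    center: bool = False,
    prior: float = 0.5,
    genome_species: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Ψ log2 fold changes of each coculture condition vs the unit's monoculture.

    Units are genes (``catalog=None``) or BGC regions.  For each unit of
    genome g and each coculture condition containing g's species, counts are
    summed across replicates within each condition (and across member genes
    for regions); library sizes — the genome's total counts in those samples —
    are summed correspondingly, and the Ψ estimator applied.  ``center``
    subtracts the per-contrast median LFC across the genome's units.
    """
    genomes = counts.genomes
    species_of = _genome_species_map(genomes, genome_species)
    mat = counts.counts

    genome_lib = {}
    for genome in genomes:
        genome_lib[genome] = mat.loc[counts.genome_genes(genome)].sum(axis=0)

    def condition_samples(name: str) -> List[str]:
        reps = design.replicates_of(name, series)
        return [s.sample_id for s in reps if s.sample_id in set(counts.samples)]

    rows = []
    for genome in genomes:
        sp = species_of[genome]
        mono = condition_name([sp])
        mono_samples = condition_samples(mono)
        if not mono_samples:
            raise ValidationError(
                f"monoculture condition {mono!r} missing for genome {genome!r}"
            )
        if catalog is None:
            units = [(g, [g]) for g in counts.genome_genes(genome)]
        else:
            units = [
                (r.region_id, list(r.genes))
                for r in catalog
                if r.genome == genome
            ]
        cocultures = [
            c for c in design.condition_names(series) if sp in c and len(c) > 1
        ]
        for cond in cocultures:
            cond_samples = condition_samples(cond)
            if not cond_samples:
                continue
            libA = genome_lib[genome][cond_samples].sum()
            libB = genome_lib[genome][mono_samples].sum()
            for unit_id, genes in units:
                present = [g for g in genes if g in mat.index]
                kA = mat.loc[present, cond_samples].to_numpy().sum()
                kB = mat.loc[present, mono_samples].to_numpy().sum()
                rows.append(
                    {
                        "unit_id": unit_id,
                        "genome": genome,
                        "condition": cond,
                        "contrast": f"{cond}_vs_{mono}",
                        "psi_lfc": psi_effect_lfc(kA, kB, libA, libB, prior),
                    }
                )
    table = pd.DataFrame(
        rows, columns=["unit_id", "genome", "condition", "contrast", "psi_lfc"]
    )
    if center and len(table):
        med = table.groupby(["genome", "contrast"])["psi_lfc"].transform("median")
        table["psi_lfc"] = table["psi_lfc"] - med
    return table


def percent_change(value_mut: float, value_wt: float) -> float:
    """Percent change of the mutant value over wild type ("X% higher" convention)."""
    if value_wt <= 0:
        raise ValidationError("wild-type value must be positive")
    if value_mut < 0:
        raise ValidationError("values must be non-negative")
    return (value_mut - value_wt) / value_wt * 100.0


def series_percent_change(
    bgc_totals: pd.DataFrame,
    design: StudyDesign,
    series_a: str = "kec",
    series_b: str = "wt",
) -> pd.DataFrame:
    """Per-region percent change of mean BGC expression, series_a vs series_b.

    Conditions present in both series are compared on replicate-mean total
    CPM; regions with zero wild-type mean in a condition are skipped with a
    warning (percent change undefined).
    """
    common = [
        c
        for c in design.condition_names(series_b)
        if c in set(design.condition_names(series_a))
    ]
    rows = []
    sample_set = set(bgc_totals.columns)
    for cond in common:
        ids_a = [s.sample_id for s in design.replicates_of(cond, series_a) if s.sample_id in sample_set]
        ids_b = [s.sample_id for s in design.replicates_of(cond, series_b) if s.sample_id in sample_set]
        if not ids_a or not ids_b:
            continue
        mean_a = bgc_totals[ids_a].mean(axis=1)
        mean_b = bgc_totals[ids_b].mean(axis=1)
        for region in bgc_totals.index:
            if mean_b[region] <= 0:
                # silent when the region is dark in both series (its genome is
                # absent from the condition); warn only on a one-sided zero
                if mean_a[region] > 0:
                    log.warning(
                        "region %s has non-positive %s mean in %s; percent change skipped",
                        region, series_b, cond,
                    )
                continue
            rows.append(
                {
                    "region_id": region,
                    "condition": cond,
                    f"mean_{series_a}": mean_a[region],
                    f"mean_{series_b}": mean_b[region],
                    "percent_change": percent_change(mean_a[region], mean_b[region]),
                }
            )
    return pd.DataFrame(rows)
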