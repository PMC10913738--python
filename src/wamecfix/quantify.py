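"""Core quantification: TPM, expression filters, within-taxon re-normalization,
lineage-resolved Calvin (CCF) and non-Calvin (NCF) carbon-fixation activity,
pathway-completeness filtering and relative-contribution partitioning.

Conventions
-----------
* CCF activity of a lineage = summed TPM of its RuBisCO-annotated unigenes;
  the higher the transcript pool, the higher the inferred fixation potential.
* NCF activity of a lineage = summed TPM of its unigenes annotated to any KO
  of the five NCF pathways, divided by the number of distinct KOs in the
  pathway definition (the "mean TPM per pathway gene").  Dividing by the
  *defined* rather than the *detected* gene count makes the statistic
  monotone in expression and comparable across lineages; the detected-gene
  variant is available via ``denominator="detected"``.
* A unigene annotated to several KOs of one set is counted once toward the
  TPM sum (no double counting).
* Unigenes that are ``unclassified`` at the chosen rank form their own
  explicit category, preserving the partition property: per-lineage
  activities always sum to the whole-community activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    RANKS,
    PathwaySet,
    SampleTable,
    UnigeneCatalog,
    ValidationError,
)

__all__ = [
    "ActivityTable",
    "ContributionTable",
    "compute_tpm",
    "filter_low_expression",
    "taxon_normalize",
    "ccf_activity",
    "ncf_activity",
    "pathway_gene_support",
    "completeness_filter",
    "relative_contribution",
    "aggregate_replicates",
]


@dataclass
class ActivityTable:
    """Nonnegative pathway activity per (lineage, column).

    ``values`` rows are lineage labels at ``rank``; columns are raw library
    IDs (``by_condition=False``) or replicate-averaged condition labels
    (``by_condition=True``).  ``statistic`` records how the activity was
    computed: ``rubisco_tpm_sum`` or ``ncf_mean_gene_tpm``.
    """

    values: pd.DataFrame
    pathway: str
    statistic: str
    rank: str
    by_condition: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("activity values must be nonnegative")


@dataclass
class ContributionTable:
    """Relative share (%) of each lineage in a pathway's transcript pool.

    Per column the entries sum to 100 when the pooled activity is positive;
    columns with zero pooled activity are all-NaN (not available, never 0).
    """

    values: pd.DataFrame
    pathway: str
    rank: str

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if (vals[np.isfinite(vals)] < 0).any():
            raise ValidationError("contributions must be nonnegative")


def compute_tpm(counts: pd.DataFrame, catalog: UnigeneCatalog) -> pd.DataFrame:
    """Transcripts per million: per library, length-normalized read rates
    rescaled to sum to 1e6.

    rate_i = count_i / (length_i/1000);  TPM_i = 1e6 * rate_i / sum(rates).
    """
    lengths_kb = catalog.frame.loc[counts.index, "length_bp"].to_numpy(dtype=float) / 1000.0
    rates = counts.to_numpy(dtype=float) / lengths_kb[:, None]
    totals = rates.sum(axis=0)
    empty = np.flatnonzero(totals <= 0)
    if empty.size:
        raise ValidationError(f"empty library '{counts.columns[empty[0]]}'")
    tpm = rates / totals[None, :] * 1e6
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def filter_low_expression(
    tpm: pd.DataFrame, threshold: float = 0.1
) -> tuple[pd.DataFrame, int]:
    """Drop unigenes whose TPM is below ``threshold`` in *every* library.

    A single library at or above the threshold retains the unigene.  The
    survivors are deliberately not re-normalized, so column sums after
    filtering fall short of 1e6 by exactly the removed TPM mass.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    keep = (tpm >= threshold).any(axis=1)
    return tpm[keep], int((~keep).sum())


def taxon_normalize(
    tpm: pd.DataFrame, catalog: UnigeneCatalog, taxon: tuple[str, str]
) -> pd.DataFrame:
    """Re-normalize expression within one taxonomic group.

    ``taxon`` is a ``(rank, label)`` selector.  Within each library the
    group's unigene values are rescaled to sum to 1e6 ("transcripts per
    million mapped reads of the taxonomic group"), which removes the
    group's abundance from between-sample comparisons of its gene
    expression.  Libraries where the group is entirely absent are returned
    as NaN, never zero.
    """
    rank, label = taxon
    lineage = catalog.lineage_at(rank)
    members = tpm.index.intersection(lineage.index[lineage == label])
    if len(members) == 0:
        raise ValidationError(f"taxon selector ({rank!r}, {label!r}) matches no unigene")
    sub = tpm.loc[members]
    totals = sub.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sub / totals.replace(0.0, np.nan) * 1e6
    return out


def _marker_activity(
    tpm: pd.DataFrame,
    catalog: UnigeneCatalog,
    gene_ids: tuple,
    rank: str,
) -> pd.DataFrame:
    """Summed TPM of unigenes carrying any of ``gene_ids``, by lineage at
    ``rank``.  Each unigene counts once even if annotated to several of the
    requested genes, and maps to exactly one lineage."""
    if rank not in RANKS:
        raise ValidationError(f"unknown taxonomy rank '{rank}'; expected one of {RANKS}")
    members = tpm.index.intersection(catalog.genes_with(gene_ids))
    lineage = catalog.lineage_at(rank).loc[members]
    if len(members) == 0:
        return pd.DataFrame(columns=tpm.columns, dtype=float)
    return tpm.loc[members].groupby(lineage).sum()


def ccf_activity(
    tpm: pd.DataFrame,
    catalog: UnigeneCatalog,
    pathways: PathwaySet,
    rank: str = "supergroup",
    samples: SampleTable | None = None,
) -> ActivityTable:
    """Calvin carbon-fixation activity per lineage: summed TPM of
    RuBisCO-marker-annotated unigenes.

    When ``samples`` is given, replicate libraries are averaged into
    per-condition (station x layer x fraction) values.
    """
    markers = pathways.role_genes("ccf_marker")
    if not markers:
        raise ValidationError("pathway set defines no ccf_marker genes")
    values = _marker_activity(tpm, catalog, markers, rank)
    table = ActivityTable(values, pathway="ccf", statistic="rubisco_tpm_sum", rank=rank)
    if samples is not None:
        table = aggregate_replicates(table, samples)
    return table


def rhodopsin_activity(
    tpm: pd.DataFrame,
    catalog: UnigeneCatalog,
    pathways: PathwaySet,
    rank: str = "order",
    samples: SampleTable | None = None,
) -> ActivityTable:
    """Rhodopsin expression per lineage: summed TPM of unigenes carrying the
    microbial-rhodopsin domain (PF01036 in the default configuration)."""
    genes = pathways["rhodopsin"].gene_ids if "rhodopsin" in pathways else ()
    if not genes:
        raise ValidationError("pathway set defines no rhodopsin entry")
    values = _marker_activity(tpm, catalog, tuple(genes), rank)
    table = ActivityTable(values, pathway="rhodopsin", statistic="tpm_sum", rank=rank)
    if samples is not None:
        table = aggregate_replicates(table, samples)
    return table


def _detected_denominator(
    tpm: pd.DataFrame, catalog: UnigeneCatalog, gene_ids: tuple, rank: str
) -> pd.DataFrame:
    support = pathway_gene_support(tpm, catalog, gene_ids, rank)
    return support.astype(float)


def ncf_activity(
    tpm: pd.DataFrame,
    catalog: UnigeneCatalog,
    pathways: PathwaySet,
    rank: str = "order",
    samples: SampleTable | None = None,
    denominator: str = "defined",
    per_pathway: bool = False,
) -> ActivityTable | tuple[ActivityTable, dict]:
    """Non-Calvin carbon-fixation activity per lineage: mean TPM per pathway
    gene, i.e. summed TPM over unigenes annotated to any KO of the five NCF
    pathways divided by the number of distinct KOs.

    ``denominator="defined"`` (default) divides by the size of the pathway
    definition; ``"detected"`` divides by the per-(lineage, library) count
    of expressed KOs.  With ``per_pathway=True`` a dict of per-pathway
    breakdown tables is returned alongside the union statistic.
    """
    ncf_pathways = pathways.by_role("ncf_pathway")
    if not ncf_pathways:
        raise ValidationError("pathway set defines no ncf_pathway entries")
    if denominator not in ("defined", "detected"):
        raise ValidationError(f"unknown denominator mode '{denominator}'")

    def one(gene_ids: tuple, name: str) -> ActivityTable:
        sums = _marker_activity(tpm, catalog, gene_ids, rank)
        if denominator == "defined":
            values = sums / len(gene_ids)
        else:
            det = _detected_denominator(tpm, catalog, gene_ids, rank).reindex_like(sums)
            with np.errstate(divide="ignore", invalid="ignore"):
                values = (sums / det.replace(0.0, np.nan)).fillna(0.0)
        table = ActivityTable(values, pathway=name, statistic="ncf_mean_gene_tpm", rank=rank)
        if samples is not None:
            table = aggregate_replicates(table, samples)
        return table

    union = one(pathways.ncf_union, "ncf")
    if not per_pathway:
        return union
    breakdown = {pw.name: one(pw.gene_ids, pw.name) for pw in ncf_pathways}
    return union, breakdown


def pathway_gene_support(
    tpm: pd.DataFrame,
    catalog: UnigeneCatalog,
    gene_ids: tuple,
    rank: str,
) -> pd.DataFrame:
    """Number of distinct pathway KOs with non-zero expression, per
    (lineage, library)."""
    if rank not in RANKS:
        raise ValidationError(f"unknown taxonomy rank '{rank}'; expected one of {RANKS}")
    wanted = frozenset(gene_ids)
    members = tpm.index.intersection(catalog.genes_with(gene_ids))
    lineage = catalog.lineage_at(rank)
    pieces: dict[tuple[str, str], np.ndarray] = {}
    for uid in members:
        row = catalog.frame.loc[uid]
        annots = (row["ko_ids"] | row["pfam_ids"]) & wanted
        expressed = tpm.loc[uid].to_numpy() > 0
        for g in annots:
            key = (lineage[uid], g)
            if key in pieces:
                pieces[key] = pieces[key] | expressed
            else:
                pieces[key] = expressed.copy()
    lineages = sorted({k[0] for k in pieces})
    out = pd.DataFrame(0, index=lineages, columns=tpm.columns, dtype=int)
    for (lin, _g), expressed in pieces.items():
        out.loc[lin] += expressed.astype(int)
    return out


def completeness_filter(
    support: pd.DataFrame, min_genes: int = 15
) -> tuple[list, pd.DataFrame]:
    """Retain lineages expressing at least ``min_genes`` distinct NCF KOs in
    at least one library (boundary inclusive).

    Returns the retained lineage list and a report with each lineage's best
    per-library gene count and its verdict.
    """
    if min_genes < 1:
        raise ValidationError("min_genes must be >= 1")
    best = support.max(axis=1)
    retained = best[best >= min_genes].index.tolist()
    report = pd.DataFrame(
        {"max_genes_expressed": best, "retained": best >= min_genes}
    )
    return retained, report


def relative_contribution(activity: ActivityTable) -> ContributionTable:
    """Partition a pathway's transcript pool: per column,
    100 * activity / pooled activity.  Columns with zero pooled activity are
    returned as NaN."""
    vals = activity.values
    if (vals.to_numpy() < 0).any():
        raise ValidationError("negative activity encountered")
    totals = vals.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = vals / totals.replace(0.0, np.nan) * 100.0
    return ContributionTable(contrib, pathway=activity.pathway, rank=activity.rank)


def aggregate_replicates(table: ActivityTable, samples: SampleTable) -> ActivityTable:
    """Average replicate libraries into per-condition values.

    Conditions are station x layer x size fraction when both fractions are
    present, station x layer otherwise (the arithmetic mean of replicate
    activities; the per-library table remains available upstream).
    """
    if table.by_condition:
        return table
    frame = samples.frame.loc[table.values.columns]
    include_fraction = frame["size_fraction"].nunique() > 1
    lab = frame["station"].astype(str) + "_" + frame["layer"].astype(str)
    if include_fraction:
        lab = lab + "_" + frame["size_fraction"].astype(str)
    grouped = table.values.T.groupby(lab.values).mean().T
    return ActivityTable(
        grouped,
        pathway=table.pathway,
        statistic=table.statistic,
        rank=table.rank,
        by_condition=True,
    )
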