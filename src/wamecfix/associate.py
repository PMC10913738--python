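"""Association statistics: gene-gene correlation matrices, the
rhodopsin-versus-NCF regression, and Mantel tests of community-environment
association.

* Gene occupancy filter: correlations are computed only for genes with
  non-zero expression in at least 6 of the 20 libraries (threshold
  configurable, boundary inclusive).
* Endocytosis-photosynthesis coupling: Pearson correlation between the
  taxon-normalized per-gene expression of two core gene sets within one
  lineage, reported as a full r/p matrix (no multiple-testing correction by
  default; Benjamini-Hochberg optional).
* Rhodopsin-NCF coupling: ordinary least squares of an order's NCF activity
  on its rhodopsin expression, by default on the log2(value+1) scale.
* Community-environment association: Mantel test between Bray-Curtis
  distances of lineage-contribution profiles and Euclidean distances of a
  z-scored environmental variable, with seeded one-sided permutation
  p-values (999 permutations by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import SampleTable, UnigeneCatalog, ValidationError
from .quantify import ContributionTable

__all__ = [
    "GeneCorrelationMatrix",
    "RegressionResult",
    "MantelResult",
    "occupancy_filter",
    "per_gene_expression",
    "core_gene_correlation",
    "ppr_ncf_regression",
    "mantel",
    "mantel_env",
]


class InsufficientDataError(ValueError):
    """Fewer paired observations than the statistic requires."""


@dataclass
class GeneCorrelationMatrix:
    """Pairwise Pearson correlations between two gene sets.

    ``r``/``p`` are (set1 gene x set2 gene) frames; pairs involving a
    zero-variance expression vector are NaN. ``occupancy`` counts, per gene,
    the libraries with non-zero expression; genes failing the occupancy
    filter are absent from the matrix."""

    r: pd.DataFrame
    p: pd.DataFrame
    occupancy: pd.Series
    n: int

    @property
    def mean_r(self) -> float:
        """Mean pairwise correlation — a one-number summary of the
        pathway-level coupling sign and strength."""
        return float(np.nanmean(self.r.to_numpy()))


@dataclass
class RegressionResult:
    """Ordinary-least-squares fit summary."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    log_scale: bool


@dataclass
class MantelResult:
    """Mantel test of two distance matrices over the same conditions."""

    statistic: float
    p_value: float
    n_permutations: int
    alternative: str
    metric_a: str
    metric_b: str
    n: int

    @property
    def significance(self) -> str:
        """Significance class: '**' for p < 0.01, '*' for 0.01 <= p < 0.05,
        'ns' otherwise."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


def occupancy_filter(tpm: pd.DataFrame, min_nonzero: int = 6) -> list:
    """Genes (rows) with non-zero expression in at least ``min_nonzero``
    libraries (boundary inclusive)."""
    if min_nonzero < 2:
        raise ValidationError("min_nonzero must be >= 2")
    nz = (tpm > 0).sum(axis=1)
    return tpm.index[nz >= min_nonzero].tolist()


def per_gene_expression(
    tpm_taxon: pd.DataFrame, catalog: UnigeneCatalog, gene_ids: tuple
) -> pd.DataFrame:
    """Aggregate unigene-level (taxon-normalized) TPM to per-gene expression:
    for each KO/Pfam ID, the summed TPM of the taxon's unigenes annotated to
    it. A unigene annotated to two requested genes contributes to both
    rows."""
    sub = catalog.frame.loc[catalog.frame.index.intersection(tpm_taxon.index)]
    rows = {}
    for g in gene_ids:
        attr = "ko_ids" if g.startswith("K") else "pfam_ids"
        members = [u for u in sub.index if g in sub.at[u, attr]]
        if members:
            rows[g] = tpm_taxon.loc[members].sum(axis=0)
    return pd.DataFrame(rows).T.reindex(columns=tpm_taxon.columns)


def core_gene_correlation(
    tpm_taxon: pd.DataFrame,
    catalog: UnigeneCatalog,
    set1: tuple,
    set2: tuple,
    min_nonzero: int = 6,
    fdr: bool = False,
) -> GeneCorrelationMatrix:
    """Pearson correlation between each gene of ``set1`` and each gene of
    ``set2``, on taxon-normalized expression.

    Genes must pass the occupancy filter; pairs with a zero-variance vector
    are reported NaN; fewer than 3 paired observations is an error.
    ``fdr=True`` applies Benjamini-Hochberg across the reported p-values
    (off by default)."""
    expr1 = per_gene_expression(tpm_taxon, catalog, tuple(set1))
    expr2 = per_gene_expression(tpm_taxon, catalog, tuple(set2))
    expr_all = pd.concat([expr1, expr2[~expr2.index.isin(expr1.index)]])
    occupancy = (expr_all > 0).sum(axis=1)
    keep1 = [g for g in expr1.index if occupancy[g] >= min_nonzero]
    keep2 = [g for g in expr2.index if occupancy[g] >= min_nonzero]
    if not keep1 or not keep2:
        raise InsufficientDataError(
            "no gene of one of the sets passes the occupancy filter"
        )
    valid = expr_all.notna().all(axis=0)
    n = int(valid.sum())
    if n < 3:
        raise InsufficientDataError(f"only {n} paired observations; need >= 3")
    cols = expr_all.columns[valid]
    r = pd.DataFrame(np.nan, index=keep1, columns=keep2)
    p = pd.DataFrame(np.nan, index=keep1, columns=keep2)
    for g1 in keep1:
        x = expr1.loc[g1, cols].to_numpy(dtype=float)
        for g2 in keep2:
            y = expr_all.loc[g2, cols].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r.at[g1, g2] = res.statistic
            p.at[g1, g2] = res.pvalue
    if fdr:
        flat = p.to_numpy().ravel()
        mask = np.isfinite(flat)
        if mask.any():
            flat[mask] = stats.false_discovery_control(flat[mask])
            p = pd.DataFrame(flat.reshape(p.shape), index=p.index, columns=p.columns)
    return GeneCorrelationMatrix(r=r, p=p, occupancy=occupancy, n=n)


def ppr_ncf_regression(
    ncf: pd.Series,
    rhodopsin: pd.Series,
    log_scale: bool = True,
) -> RegressionResult:
    """OLS of one order's NCF activity on its rhodopsin expression across
    conditions, by default after the log2(value+1) transform."""
    joined = pd.concat({"ncf": ncf, "rho": rhodopsin}, axis=1).dropna()
    if len(joined) < 3:
        raise InsufficientDataError(f"only {len(joined)} paired conditions; need >= 3")
    y = joined["ncf"].to_numpy(dtype=float)
    x = joined["rho"].to_numpy(dtype=float)
    if log_scale:
        if (x < 0).any() or (y < 0).any():
            raise ValidationError("log2(value+1) scale requires nonnegative values")
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    if np.std(x) == 0:
        raise ValidationError("zero-variance predictor: rhodopsin expression is constant")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(joined),
        log_scale=log_scale,
    )


def _condensed(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel(
    dist_a: np.ndarray | pd.DataFrame,
    dist_b: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    alternative: str = "greater",
    seed: int | np.random.Generator = 0,
    metric_a: str = "",
    metric_b: str = "",
) -> MantelResult:
    """Mantel test: Pearson correlation of the off-diagonal entries of two
    square distance matrices, with a permutation p-value obtained by jointly
    relabeling the rows and columns of the second matrix.

    p = (1 + #{permuted statistic at least as extreme}) / (1 + n_perm),
    one-sided per ``alternative`` ('greater', 'less' or 'two-sided')."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("distance matrices must be square and of equal shape")
    n = a.shape[0]
    if n < 4:
        raise ValidationError("Mantel test requires at least 4 conditions")
    va = _condensed(a)
    if np.std(va) == 0 or np.std(_condensed(b)) == 0:
        raise ValidationError("degenerate (constant) distance matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def corr_with(bmat: np.ndarray) -> float:
        vb = _condensed(bmat)
        sd = np.std(vb)
        if sd == 0:
            return 0.0
        return float(np.corrcoef(va, vb)[0, 1])

    observed = corr_with(b)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = corr_with(b[np.ix_(perm, perm)])
        if alternative == "greater":
            hits += r_perm >= observed
        elif alternative == "less":
            hits += r_perm <= observed
        elif alternative == "two-sided":
            hits += abs(r_perm) >= abs(observed)
        else:
            raise ValidationError(f"unknown alternative '{alternative}'")
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(
        statistic=observed,
        p_value=float(p),
        n_permutations=n_perm,
        alternative=alternative,
        metric_a=metric_a,
        metric_b=metric_b,
        n=n,
    )


def mantel_env(
    contrib: ContributionTable,
    samples: SampleTable,
    env_var: str = "all",
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    contrib_metric: str = "braycurtis",
    env_metric: str = "euclidean",
) -> dict:
    """Mantel tests between lineage-contribution profiles and environmental
    variables.

    Distance A: ``contrib_metric`` (default Bray-Curtis) on the per-condition
    lineage-contribution profiles. Distance B: ``env_metric`` (default
    Euclidean) on the z-scored environmental variable, one test per
    variable. Environmental values are averaged over the libraries of each
    condition."""
    profiles = contrib.values.dropna(axis=1, how="all")
    conditions = list(profiles.columns)
    if len(conditions) < 4:
        raise ValidationError("Mantel test requires at least 4 conditions")
    dist_a = squareform(pdist(profiles.T.to_numpy(dtype=float), metric=contrib_metric))

    f = samples.frame
    include_fraction = f["size_fraction"].nunique() > 1
    lab = f["station"].astype(str) + "_" + f["layer"].astype(str)
    if include_fraction:
        lab = lab + "_" + f["size_fraction"].astype(str)
    env_cols = [
        c
        for c in f.columns
        if c not in ("station", "layer", "size_fraction", "replicate", "rna_yield_per_L")
    ]
    if env_var != "all":
        if env_var not in env_cols:
            raise ValidationError(f"unknown environment variable '{env_var}'")
        env_cols = [env_var]

    rng = np.random.default_rng(seed)
    results: dict = {}
    for var in env_cols:
        per_cond = f.groupby(lab.values)[var].mean().reindex(conditions)
        if per_cond.isna().any():
            raise ValidationError(f"environment variable '{var}' missing for a condition")
        v = per_cond.to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValidationError(f"environment variable '{var}' is constant")
        z = (v - v.mean()) / sd
        dist_b = squareform(pdist(z[:, None], metric=env_metric))
        results[var] = mantel(
            dist_a,
            dist_b,
            n_perm=n_perm,
            alternative=alternative,
            seed=rng,
            metric_a=contrib_metric,
            metric_b=env_metric,
        )
    return results
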