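"""Synthetic whole-assemblage metatranscriptome datasets with known ground truth.

The generator emulates the field design this pipeline targets: two stations
(a shallow shelf station with SUR and DCM layers and a deeper slope station
with SUR, DCM and BOT layers — five water masses), two organismal size
fractions (0.2-3 um and 3-200 um) and two biological replicates, i.e. 20
sequencing libraries in the default configuration.

Generative model
----------------
* Each programmed lineage contributes background unigenes (no functional
  annotation; lognormal relative abundances fixed across conditions) and one
  unigene per gene of each pathway it participates in.  Unigene lengths are
  lognormal around the lineage's mean length with a 200 bp floor.
* Every pathway in ``pathway_truth`` receives an expected read budget
  ``library_depth * pool_fraction``, jittered lognormally per (pathway,
  condition, fraction) to create between-condition biological variability.
  Within the pathway, expected *length-normalized rates* (not reads) are
  allocated to lineages in the programmed shares, so the programmed share is
  exactly the lineage's expected share of the pathway's TPM pool.
* Counts are negative binomial around their expectations via library-level
  gamma-Poisson mixing: a shared Gamma(1/a, a) factor per library times
  per-gene Poisson sampling, so each gene is marginally NB with dispersion
  ``a`` (dispersion 0 degenerates to Poisson) while within-library relative
  composition — what TPM measures — keeps binomial-scale sampling error.
  A mild lognormal per-library replicate multiplier models extraction and
  sequencing-depth differences between replicates.
* Rhodopsin expression of each coupled order is drawn from a linear model on
  that order's realized NCF expression, log2(TPM+1) scale, with residual
  variance set from the realized predictor variance so that the population
  coefficient of determination equals ``rhodopsin_coupling_r2``.  Rhodopsin
  counts are the deterministic discretisation of that draw — the count-level
  sampling noise of coupled genes is subsumed in the model residual, so the
  programmed R^2 is the R^2 of what the pipeline can measure.
* Environmental covariates follow per-variable linear layer gradients,
  optionally coupled to a programmed lineage share, plus Gaussian noise.

Identical seed and configuration give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    PathwaySet,
    SampleTable,
    UnigeneCatalog,
    UNCLASSIFIED,
    ValidationError,
    load_default_pathways,
)

__all__ = [
    "LineageSpec",
    "EnvGradient",
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "truth_recovery_report",
]

_PROKARYOTE_SUPERGROUPS = {
    "Cyanobacteria",
    "Proteobacteria",
    "Bacteroidetes",
    "O_Bacteria",
    "Firmicutes",
    "Actinobacteria",
}

_LENGTH_SIGMA = 0.35  # lognormal sigma of unigene lengths (log scale)


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class LineageSpec:
    """One programmed lineage: a supergroup/order pair with its background
    catalog size and mean unigene length.  Orders must be unique; they are
    the keys used by ``pathway_truth``."""

    supergroup: str
    order: str
    n_unigenes: int = 50
    mean_length_bp: float = 1000.0
    domain: str | None = None

    def resolved_domain(self) -> str:
        if self.domain:
            return self.domain
        if self.supergroup == "Archaea":
            return "Archaea"
        if self.supergroup in _PROKARYOTE_SUPERGROUPS:
            return "Bacteria"
        return "Eukaryota"


@dataclass(frozen=True)
class EnvGradient:
    """Linear layer gradient for one environmental variable:
    value = base + layer_slope * layer_index
            + couple_strength * share(couple_to, couple_pathway, condition)
            + N(0, noise_sd)."""

    base: float
    layer_slope: float = 0.0
    couple_to: str | None = None
    couple_pathway: str = "ccf"
    couple_strength: float = 0.0
    noise_sd: float = 0.0


def _default_lineages() -> tuple:
    return (
        LineageSpec("Bacillariophyta", "Bacillariales"),
        LineageSpec("O_Stramenopiles", "Pelagomonadales"),
        LineageSpec("Haptophyta", "Prymnesiales"),
        LineageSpec("Cyanobacteria", "Synechococcales"),
        LineageSpec("Chlorophyta", "Mamiellales"),
        LineageSpec("Dinophyta", "Gymnodiniales"),
        LineageSpec("Bacteroidetes", "Flavobacteriales", mean_length_bp=900.0),
        LineageSpec("Proteobacteria", "Rhodobacterales", mean_length_bp=900.0),
    )


def _default_truth() -> dict:
    # A community loosely shaped like a subtropical coastal assemblage:
    # eukaryotic phytoplankton and cyanobacteria share the Calvin pool,
    # heterotrophic bacterial orders share the non-Calvin pool.
    return {
        "ccf": {
            "Bacillariales": 0.25,
            "Pelagomonadales": 0.20,
            "Prymnesiales": 0.15,
            "Synechococcales": 0.15,
            "Mamiellales": 0.10,
            "Gymnodiniales": 0.15,
        },
        "rtca": {
            "Flavobacteriales": 0.60,
            "Rhodobacterales": 0.40,
        },
        "photosynthesis_core": {
            "Bacillariales": 0.30,
            "Pelagomonadales": 0.20,
            "Prymnesiales": 0.15,
            "Synechococcales": 0.15,
            "Mamiellales": 0.10,
            "Gymnodiniales": 0.10,
        },
        "endocytosis_core": {
            "Bacillariales": 0.30,
            "Prymnesiales": 0.20,
            "Mamiellales": 0.20,
            "Gymnodiniales": 0.30,
        },
    }


def _default_env() -> dict:
    return {
        "temperature": EnvGradient(29.5, -4.0, noise_sd=0.3),
        "salinity": EnvGradient(33.4, 0.35, noise_sd=0.05),
        "depth": EnvGradient(5.0, 35.0, noise_sd=1.0),
        "no2_no3": EnvGradient(0.15, 2.0, noise_sd=0.05),
        "po4": EnvGradient(0.02, 0.18, noise_sd=0.005),
        "sio3": EnvGradient(2.0, 3.0, noise_sd=0.2),
        "par": EnvGradient(1250.0, -550.0, noise_sd=30.0),
    }


@dataclass
class SimulationConfig:
    """Full description of one synthetic study.

    ``pathway_truth`` maps pathway name -> order -> programmed share of that
    pathway's transcript pool; a share is either a single fraction (all
    conditions) or a {condition: fraction} mapping (a ``"*"`` key supplies
    the default).  Shares must sum to 1 per (pathway, condition).
    """

    seed: int = 0
    stations: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"shelf": ("SUR", "DCM"), "slope": ("SUR", "DCM", "BOT")}
    )
    fractions: Sequence[str] = ("small", "large")
    n_replicates: int = 2
    lineages: Sequence[LineageSpec] = field(default_factory=_default_lineages)
    pathway_truth: Mapping[str, Mapping] = field(default_factory=_default_truth)
    pathway_pool_fraction: float | Mapping[str, float] = 0.02
    pathway_cv: float = 0.5
    background_sigma: float = 1.0
    replicate_cv: float = 0.10
    library_depth: int = 1_000_000
    dispersion: float = 0.1
    rna_yield_small: float | Mapping[str, float] = 1.0
    rna_yield_large: float | Mapping[str, float] = 1.5
    rhodopsin_coupling_r2: float = 0.8
    rhodopsin_orders: Sequence[str] | None = None
    rhodopsin_slope: float = 1.0
    rhodopsin_intercept: float = 2.0
    rhodopsin_mean_length_bp: float = 750.0
    env_gradients: Mapping[str, EnvGradient] = field(default_factory=_default_env)
    pathways: PathwaySet | None = None

    # -- helpers -----------------------------------------------------------

    @property
    def conditions(self) -> list:
        return [f"{st}_{ly}" for st, layers in self.stations.items() for ly in layers]

    def layer_index(self, condition: str) -> int:
        st, ly = condition.rsplit("_", 1)
        return list(self.stations[st]).index(ly)

    def resolved_pathways(self) -> PathwaySet:
        return self.pathways if self.pathways is not None else load_default_pathways()

    def pool_fraction(self, pathway: str) -> float:
        if isinstance(self.pathway_pool_fraction, Mapping):
            return float(self.pathway_pool_fraction[pathway])
        return float(self.pathway_pool_fraction)

    def share(self, pathway: str, order: str, condition: str) -> float:
        spec = self.pathway_truth.get(pathway, {}).get(order, 0.0)
        if isinstance(spec, Mapping):
            return float(spec.get(condition, spec.get("*", 0.0)))
        return float(spec)

    def rna_yield(self, fraction: str, condition: str) -> float:
        spec = self.rna_yield_small if fraction == "small" else self.rna_yield_large
        if isinstance(spec, Mapping):
            return float(spec[condition])
        return float(spec)

    def validate(self) -> None:
        if self.library_depth <= 0:
            raise SimulationError("library_depth must be > 0")
        if not 0.0 <= self.rhodopsin_coupling_r2 <= 1.0:
            raise SimulationError("rhodopsin_coupling_r2 must lie in [0, 1]")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be nonnegative")
        orders = [l.order for l in self.lineages]
        if len(set(orders)) != len(orders):
            raise SimulationError("lineage orders must be unique")
        known = set(orders)
        pathway_names = set(self.resolved_pathways().pathways)
        for pw, shares in self.pathway_truth.items():
            if pw not in pathway_names:
                raise SimulationError(f"pathway_truth references unknown pathway '{pw}'")
            for order in shares:
                if order not in known:
                    raise SimulationError(
                        f"pathway_truth['{pw}'] references unknown lineage order '{order}'"
                    )
            for cond in self.conditions:
                total = sum(self.share(pw, o, cond) for o in shares)
                if abs(total - 1.0) > 1e-9:
                    raise SimulationError(
                        f"shares for pathway '{pw}' in condition '{cond}' sum to "
                        f"{total!r}, expected 1"
                    )
                for o in shares:
                    if self.share(pw, o, cond) < 0:
                        raise SimulationError("negative programmed share")

    def coupled_orders(self) -> list:
        if self.rhodopsin_orders is not None:
            return list(self.rhodopsin_orders)
        ncf_names = {pw.name for pw in self.resolved_pathways().by_role("ncf_pathway")}
        out: list = []
        for pw, shares in self.pathway_truth.items():
            if pw in ncf_names:
                for order in shares:
                    if order not in out:
                        out.append(order)
        return out


@dataclass
class GroundTruth:
    """Programmed quantities of one simulated dataset, for recovery checks."""

    shares: dict  # pathway -> order -> condition -> fraction of the TPM pool
    supergroup_of: dict
    rhodopsin_coupling_r2: float
    rhodopsin_params: dict  # order -> (intercept, slope, residual_sd)
    env_gradients: dict
    warnings: list = field(default_factory=list)

    def contribution_percent(self, pathway: str, rank: str = "order") -> pd.DataFrame:
        """Programmed lineage shares as a percent table (lineage x condition),
        aggregated to ``rank`` (order or supergroup)."""
        shares = self.shares[pathway]
        conditions = sorted({c for per in shares.values() for c in per})
        rows: dict = {}
        for order, per in shares.items():
            label = order if rank == "order" else self.supergroup_of[order]
            row = rows.setdefault(label, dict.fromkeys(conditions, 0.0))
            for cond in conditions:
                row[cond] += per.get(cond, 0.0) * 100.0
        return pd.DataFrame.from_dict(rows, orient="index")[conditions]


def _lognormal_lengths(rng: np.random.Generator, n: int, mean_bp: float) -> np.ndarray:
    mu = math.log(mean_bp) - _LENGTH_SIGMA**2 / 2.0
    lengths = rng.lognormal(mu, _LENGTH_SIGMA, size=n)
    return np.maximum(np.round(lengths), 200).astype(int)


def _cv_to_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv**2))


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size=None):
    """Lognormal multiplier with mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = _cv_to_sigma(cv)
    return rng.lognormal(-sigma**2 / 2.0, sigma, size=size)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[UnigeneCatalog, pd.DataFrame, SampleTable, GroundTruth]:
    """Generate (catalog, counts, samples, truth) for one synthetic study."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pathways = config.resolved_pathways()
    conditions = config.conditions
    warnings: list = []

    # ---- catalog ---------------------------------------------------------
    records: list = []  # (unigene_id, length, lineage_spec, annots, kind, pathway)
    by_lineage = {l.order: l for l in config.lineages}
    for lin in config.lineages:
        lengths = _lognormal_lengths(rng, lin.n_unigenes, lin.mean_length_bp)
        for i in range(lin.n_unigenes):
            records.append((f"{lin.order}_bg{i:04d}", lengths[i], lin, frozenset(), "bg", None))
    pathway_unigenes: dict = {}  # (pathway, order) -> list of row positions
    for pw_name in config.pathway_truth:
        pw = pathways[pw_name]
        participating = [o for o in config.pathway_truth[pw_name]]
        for order in participating:
            lin = by_lineage[order]
            lengths = _lognormal_lengths(rng, len(pw.gene_ids), lin.mean_length_bp)
            idxs = []
            for g, length in zip(pw.gene_ids, lengths):
                idxs.append(len(records))
                records.append((f"{order}_{pw_name}_{g}", length, lin, frozenset([g]), "pw", pw_name))
            pathway_unigenes[(pw_name, order)] = idxs
    coupled = config.coupled_orders()
    rhodopsin_rows: dict = {}
    rhodopsin_genes = pathways["rhodopsin"].gene_ids if "rhodopsin" in pathways else ("PF01036",)
    for order in coupled:
        lin = by_lineage[order]
        length = int(_lognormal_lengths(rng, 1, config.rhodopsin_mean_length_bp)[0])
        for g in rhodopsin_genes:
            rhodopsin_rows[order] = len(records)
            records.append((f"{order}_rhodopsin_{g}", length, lin, frozenset([g]), "rho", None))

    ids = [r[0] for r in records]
    lengths_bp = np.array([r[1] for r in records], dtype=int)
    frame = pd.DataFrame(index=pd.Index(ids, name="unigene_id"))
    frame["length_bp"] = lengths_bp
    frame["domain"] = [r[2].resolved_domain() for r in records]
    frame["supergroup"] = [r[2].supergroup for r in records]
    frame["phylum"] = [r[2].supergroup for r in records]
    frame["class"] = UNCLASSIFIED
    frame["order"] = [r[2].order for r in records]
    frame["genus"] = UNCLASSIFIED
    frame["species"] = UNCLASSIFIED
    frame["ko_ids"] = [frozenset(g for g in r[3] if g.startswith("K")) for r in records]
    frame["pfam_ids"] = [frozenset(g for g in r[3] if g.startswith("PF")) for r in records]
    catalog = UnigeneCatalog(frame)
    len_kb = lengths_bp / 1000.0

    # ---- expected counts -------------------------------------------------
    bg_rows = [i for i, r in enumerate(records) if r[4] == "bg"]
    bg_abundance = _lognormal_unit_mean(
        rng, math.sqrt(math.exp(config.background_sigma**2) - 1.0), size=len(bg_rows)
    )
    pool_total = sum(config.pool_fraction(pw) for pw in config.pathway_truth)
    if pool_total >= 1.0:
        raise SimulationError("pathway pool fractions must sum to < 1")
    bg_mass = config.library_depth * (1.0 - pool_total)

    libraries: list = []  # (library_id, condition, fraction, replicate)
    for st, layers in config.stations.items():
        for ly in layers:
            for fr in config.fractions:
                for rep in range(1, config.n_replicates + 1):
                    libraries.append((f"{st}_{ly}_{fr}_{rep}", f"{st}_{ly}", fr, rep))

    # per-(pathway, condition, fraction) biological pool multiplier
    pool_mult = {
        (pw, cond, fr): _lognormal_unit_mean(rng, config.pathway_cv)
        for pw in config.pathway_truth
        for cond in conditions
        for fr in config.fractions
    }

    n_genes, n_libs = len(records), len(libraries)
    expected = np.zeros((n_genes, n_libs))
    for j, (_lib, cond, fr, _rep) in enumerate(libraries):
        col = np.zeros(n_genes)
        # background: fixed relative rates, scaled to the background read mass
        e_bg = bg_abundance * len_kb[bg_rows]
        col[bg_rows] = e_bg / e_bg.sum() * bg_mass
        for pw_name, shares in config.pathway_truth.items():
            budget = config.library_depth * config.pool_fraction(pw_name) * pool_mult[
                (pw_name, cond, fr)
            ]
            rate = np.zeros(n_genes)
            for order in shares:
                s = config.share(pw_name, order, cond)
                rows = pathway_unigenes[(pw_name, order)]
                if s > 0:
                    rate[rows] = s / len(rows)
            e_pw = rate * len_kb
            total = e_pw.sum()
            if total > 0:
                col += e_pw / total * budget
        expected[:, j] = col

    # depth sufficiency warning for the rarest programmed share
    for pw_name, shares in config.pathway_truth.items():
        for order in shares:
            rows = pathway_unigenes[(pw_name, order)]
            for cond in conditions:
                s = config.share(pw_name, order, cond)
                if s <= 0:
                    continue
                j = next(
                    k for k, (_l, c, _f, _r) in enumerate(libraries) if c == cond
                )
                if expected[rows, j].min() < 1.0:
                    warnings.append(
                        f"pathway '{pw_name}' lineage '{order}' condition '{cond}': "
                        "expected count < 1 for at least one pathway unigene; "
                        "library_depth may be too small for this share"
                    )
                    break

    rep_mult = _lognormal_unit_mean(rng, config.replicate_cv, size=n_libs)
    mu = expected * rep_mult[None, :]

    if config.dispersion > 0:
        # library-level gamma mixing: counts_gj | G_j ~ Poisson(G_j mu_gj),
        # G_j ~ Gamma(1/a, a) with mean 1, so each gene is marginally
        # negative binomial with dispersion a (Var = mu + a mu^2) while
        # within-library relative composition keeps binomial-scale error
        gmix = rng.gamma(1.0 / config.dispersion, config.dispersion, size=n_libs)
        counts = rng.poisson(mu * gmix[None, :])
    else:
        counts = rng.poisson(mu)
    counts = counts.astype(np.int64)

    # ---- rhodopsin coupled to realized NCF expression --------------------
    ncf_union = frozenset(pathways.ncf_union)
    n_union = len(ncf_union)
    rates_all = counts / len_kb[:, None]
    totals = rates_all.sum(axis=0)  # pre-rhodopsin library rate totals
    rhodopsin_params: dict = {}
    r2 = config.rhodopsin_coupling_r2
    for order in coupled:
        rows = [
            i
            for (pw_name, o), idxs in pathway_unigenes.items()
            if o == order and set(pathways[pw_name].gene_ids) & ncf_union
            for i in idxs
        ]
        if not rows:
            continue
        ncf_tpm = rates_all[rows, :].sum(axis=0) / totals * 1e6 / n_union
        x = np.log2(ncf_tpm + 1.0)
        var_x = float(np.var(x, ddof=1)) if n_libs > 1 else 0.0
        if 0.0 < r2 < 1.0:
            if var_x <= 0:
                raise SimulationError(
                    f"order '{order}': NCF expression has zero variance across "
                    "libraries; cannot program a rhodopsin coupling R^2 in (0, 1)"
                )
            slope = config.rhodopsin_slope
            sd = math.sqrt(slope**2 * var_x * (1.0 - r2) / r2)
        elif r2 == 0.0:
            slope, sd = 0.0, 1.0
        else:  # r2 == 1: exact linear dependence
            slope, sd = config.rhodopsin_slope, 0.0
        y = config.rhodopsin_intercept + slope * x + rng.normal(0.0, sd, size=n_libs)
        tpm_y = np.maximum(np.exp2(y) - 1.0, 0.0)
        i_rho = rhodopsin_rows[order]
        counts[i_rho, :] = np.round(tpm_y * len_kb[i_rho] * totals / 1e6).astype(np.int64)
        rhodopsin_params[order] = (config.rhodopsin_intercept, slope, sd)

    count_frame = pd.DataFrame(counts, index=frame.index, columns=[l[0] for l in libraries])

    # ---- sample table ----------------------------------------------------
    resolved_shares = {
        pw: {
            order: {cond: config.share(pw, order, cond) for cond in conditions}
            for order in shares
        }
        for pw, shares in config.pathway_truth.items()
    }
    env_values: dict = {}
    for var, grad in config.env_gradients.items():
        vals = {}
        for cond in conditions:
            v = grad.base + grad.layer_slope * config.layer_index(cond)
            if grad.couple_to is not None:
                v += grad.couple_strength * config.share(
                    grad.couple_pathway, grad.couple_to, cond
                )
            v += rng.normal(0.0, grad.noise_sd)
            vals[cond] = v
        env_values[var] = vals

    rows = []
    for lib, cond, fr, rep in libraries:
        st, ly = cond.rsplit("_", 1)
        row = {
            "library_id": lib,
            "station": st,
            "layer": ly,
            "size_fraction": fr,
            "replicate": rep,
            "rna_yield_per_L": config.rna_yield(fr, cond),
        }
        for var in env_values:
            row[var] = env_values[var][cond]
        rows.append(row)
    samples = SampleTable(pd.DataFrame(rows).set_index("library_id"))

    truth = GroundTruth(
        shares=resolved_shares,
        supergroup_of={l.order: l.supergroup for l in config.lineages},
        rhodopsin_coupling_r2=r2,
        rhodopsin_params=rhodopsin_params,
        env_gradients={
            var: asdict(grad) for var, grad in config.env_gradients.items()
        },
        warnings=warnings,
    )
    return catalog, count_frame, samples, truth


def truth_recovery_report(
    truth: GroundTruth, estimate, pathway: str | None = None
) -> pd.DataFrame:
    """Pair programmed and estimated contribution percentages cell by cell.

    ``estimate`` is a :class:`~wamecfix.quantify.ContributionTable`.  Returns
    a long table (lineage, condition, true %, estimated %, absolute error)
    with a trailing max-absolute-error summary row.
    """
    pw = pathway or estimate.pathway
    true_tbl = truth.contribution_percent(pw, rank=estimate.rank)
    est = estimate.values
    # estimate columns may carry a size-fraction suffix (condition_small /
    # condition_large); the programmed shares apply to both fractions
    cond_of = {}
    for col in est.columns:
        base = col
        for suffix in ("_small", "_large"):
            if col.endswith(suffix):
                base = col[: -len(suffix)]
        cond_of[col] = base
    missing = sorted(set(true_tbl.columns) - set(cond_of.values()))
    if missing:
        raise ValidationError(
            f"estimate lacks condition(s) {missing} present in the ground truth"
        )
    rows = []
    for lineage in true_tbl.index:
        for col in est.columns:
            cond = cond_of[col]
            if cond not in true_tbl.columns:
                continue
            t = float(true_tbl.loc[lineage, cond])
            e = float(est.loc[lineage, col]) if lineage in est.index else 0.0
            rows.append(
                {
                    "lineage": lineage,
                    "condition": col,
                    "true_percent": t,
                    "estimated_percent": e,
                    "abs_error": abs(t - e),
                }
            )
    report = pd.DataFrame(rows)
    summary = {
        "lineage": "(max)",
        "condition": "",
        "true_percent": np.nan,
        "estimated_percent": np.nan,
        "abs_error": report["abs_error"].max() if len(report) else 0.0,
    }
    return pd.concat([report, pd.DataFrame([summary])], ignore_index=True)
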