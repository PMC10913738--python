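"""End-to-end driver: quantify -> filter -> contribution -> calibrate ->
associate, with a JSON run manifest.

The run configuration is a JSON document with either a ``simulate`` section
(a :class:`~wamecfix.simulate.SimulationConfig` as a mapping) or an
``inputs`` section pointing at catalog/counts/samples files, plus optional
analysis settings::

    {
      "simulate": {"seed": 7, "library_depth": 200000},
      "ranks": ["supergroup", "order"],
      "tpm_threshold": 0.1,
      "min_occupancy": 6,
      "min_ncf_genes": 15,
      "calibrate": true,
      "mantel": {"n_perm": 999, "rank": "order", "pathway": "ncf"},
      "regress_orders": ["Flavobacteriales"],
      "correlate_taxa": [["supergroup", "Bacillariophyta"]]
    }

Every stage that drops records writes its count into the manifest; outputs
are stable-named TSVs in one directory per run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .associate import core_gene_correlation, mantel_env, ppr_ncf_regression
from .calibrate import calibrate as _calibrate
from .calibrate import condition_yields, fraction_share
from .io import (
    PathwaySet,
    SampleTable,
    UnigeneCatalog,
    ValidationError,
    load_default_pathways,
    read_catalog,
    read_counts,
    read_samples,
    write_matrix,
)
from .quantify import (
    ccf_activity,
    compute_tpm,
    completeness_filter,
    filter_low_expression,
    ncf_activity,
    pathway_gene_support,
    relative_contribution,
    rhodopsin_activity,
    taxon_normalize,
)
from .simulate import LineageSpec, EnvGradient, SimulationConfig, simulate_dataset

__all__ = ["RunManifest", "run_all", "simulation_config_from_dict"]


@dataclass
class RunManifest:
    """Structured record of one pipeline run: configuration snapshot, seeds,
    input digests, per-stage filter counts, library versions and warnings."""

    config: dict = field(default_factory=dict)
    seed: int | None = None
    input_digests: dict = field(default_factory=dict)
    filter_counts: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def simulation_config_from_dict(raw: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain JSON mapping."""
    kwargs = dict(raw)
    if "lineages" in kwargs:
        kwargs["lineages"] = tuple(
            LineageSpec(**l) if isinstance(l, dict) else l for l in kwargs["lineages"]
        )
    if "env_gradients" in kwargs:
        kwargs["env_gradients"] = {
            k: (EnvGradient(**v) if isinstance(v, dict) else v)
            for k, v in kwargs["env_gradients"].items()
        }
    if "stations" in kwargs:
        kwargs["stations"] = {k: tuple(v) for k, v in kwargs["stations"].items()}
    return SimulationConfig(**kwargs)


def run_all(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> Path:
    """Run the full pipeline; returns the output directory.

    Deterministic given the seed. On failure, files created during the run
    are removed and the stage name is reported.
    """
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = json.load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: v for k, v in config.items()},
        versions={
            "wamecfix": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )
    created: list[Path] = []

    def emit(frame: pd.DataFrame, name: str, index_name: str = "id") -> None:
        path = outdir / name
        write_matrix(frame, path, index_name=index_name)
        created.append(path)
        manifest.outputs.append(name)

    stage = "configure"
    try:
        pathways = (
            PathwaySet.from_json(config["pathways"])
            if config.get("pathways")
            else load_default_pathways()
        )
        do_calibrate = bool(config.get("calibrate", True))

        if "simulate" in config:
            sim_raw = dict(config["simulate"])
            if seed is not None:
                sim_raw["seed"] = seed
            sim_config = simulation_config_from_dict(sim_raw)
            manifest.seed = sim_config.seed
            stage = "simulate"
            catalog, counts, samples, truth = simulate_dataset(sim_config)
            manifest.warnings.extend(truth.warnings)
        elif "inputs" in config:
            stage = "load"
            inputs = config["inputs"]
            for key in ("catalog", "counts", "samples"):
                if key not in inputs:
                    raise ValidationError(f"config inputs section lacks '{key}'")
                manifest.input_digests[key] = _digest(inputs[key])
            catalog = read_catalog(inputs["catalog"])
            samples = read_samples(inputs["samples"])
            counts = read_counts(inputs["counts"], catalog, samples)
            manifest.seed = seed if seed is not None else int(config.get("seed", 0))
        else:
            raise ValidationError("config must have a 'simulate' or an 'inputs' section")

        # fail fast: calibration needs yields for every library
        if do_calibrate:
            f = samples.frame
            if (
                "rna_yield_per_L" not in f.columns
                or f["rna_yield_per_L"].isna().any()
                or (f["rna_yield_per_L"] <= 0).any()
            ):
                raise ValidationError(
                    "calibration requested but rna_yield_per_L is missing or "
                    "nonpositive for some library"
                )
            if set(f["size_fraction"]) != {"small", "large"}:
                do_calibrate = False
                manifest.warnings.append(
                    "calibration skipped: both size fractions are not present"
                )

        stage = "tpm"
        tpm = compute_tpm(counts, catalog)
        emit(tpm, "tpm.tsv", index_name="unigene_id")

        stage = "filter_low_expression"
        threshold = float(config.get("tpm_threshold", 0.1))
        tpm_f, n_excluded = filter_low_expression(tpm, threshold)
        manifest.filter_counts["unigenes_excluded_low_tpm"] = n_excluded

        ranks = list(config.get("ranks", ["supergroup", "order"]))
        stage = "contribution"
        activities: dict = {}
        for rank in ranks:
            ccf = ccf_activity(tpm_f, catalog, pathways, rank=rank, samples=samples)
            ncf = ncf_activity(tpm_f, catalog, pathways, rank=rank, samples=samples)
            activities[("ccf", rank)] = ccf
            activities[("ncf", rank)] = ncf
            emit(ccf.values, f"activity_ccf_{rank}.tsv", index_name=rank)
            emit(ncf.values, f"activity_ncf_{rank}.tsv", index_name=rank)
            for name, act in (("ccf", ccf), ("ncf", ncf)):
                contrib = relative_contribution(act)
                emit(contrib.values, f"contribution_{name}_{rank}.tsv", index_name=rank)

        stage = "completeness_filter"
        min_genes = int(config.get("min_ncf_genes", 15))
        support = pathway_gene_support(tpm_f, catalog, pathways.ncf_union, rank="order")
        retained, report = completeness_filter(support, min_genes=min_genes)
        manifest.filter_counts["orders_excluded_ncf_completeness"] = int(
            (~report["retained"]).sum()
        )
        emit(report, "ncf_completeness.tsv", index_name="order")

        if do_calibrate:
            stage = "calibrate"
            small = samples.subset("small")
            large = samples.subset("large")
            rank = ranks[0]
            act_s = ccf_activity(
                tpm_f[list(small.ids)], catalog, pathways, rank=rank, samples=small
            )
            act_l = ccf_activity(
                tpm_f[list(large.ids)], catalog, pathways, rank=rank, samples=large
            )
            cal = _calibrate(act_s.values, act_l.values, condition_yields(samples))
            emit(cal.pooled, "calibrated_ccf_pooled.tsv", index_name=rank)
            emit(fraction_share(cal), "ccf_fraction_share.tsv", index_name="condition")

        stage = "correlate"
        min_occ = int(config.get("min_occupancy", 6))
        for rank, label in config.get("correlate_taxa", []):
            tpm_taxon = taxon_normalize(tpm_f, catalog, (rank, label))
            mat = core_gene_correlation(
                tpm_taxon,
                catalog,
                pathways["photosynthesis_core"].gene_ids,
                pathways["endocytosis_core"].gene_ids,
                min_nonzero=min_occ,
            )
            emit(mat.r, f"correlation_r_{label}.tsv", index_name="gene")
            emit(mat.p, f"correlation_p_{label}.tsv", index_name="gene")

        stage = "regress"
        reg_rows = []
        ncf_order = activities.get(("ncf", "order"))
        if ncf_order is None:
            ncf_order = ncf_activity(tpm_f, catalog, pathways, rank="order", samples=samples)
        if "rhodopsin" in pathways:
            rho_act = rhodopsin_activity(tpm_f, catalog, pathways, rank="order", samples=samples)
            for order in config.get("regress_orders", list(rho_act.values.index)):
                if order not in rho_act.values.index or order not in ncf_order.values.index:
                    continue
                res = ppr_ncf_regression(
                    ncf_order.values.loc[order], rho_act.values.loc[order]
                )
                reg_rows.append(
                    {
                        "order": order,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "r_squared": res.r_squared,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )
        if reg_rows:
            emit(pd.DataFrame(reg_rows).set_index("order"), "rhodopsin_ncf_regression.tsv",
                 index_name="order")

        stage = "mantel"
        mantel_cfg = config.get("mantel", {})
        if mantel_cfg is not None:
            rank = mantel_cfg.get("rank", ranks[0])
            pathway = mantel_cfg.get("pathway", "ccf")
            act = activities.get((pathway, rank))
            if act is not None and len(act.values) >= 2 and act.values.shape[1] >= 4:
                contrib = relative_contribution(act)
                results = mantel_env(
                    contrib,
                    samples,
                    n_perm=int(mantel_cfg.get("n_perm", 999)),
                    seed=manifest.seed or 0,
                )
                rows = [
                    {
                        "env_var": var,
                        "mantel_r": r.statistic,
                        "p_value": r.p_value,
                        "significance": r.significance,
                        "n_permutations": r.n_permutations,
                    }
                    for var, r in results.items()
                ]
                emit(pd.DataFrame(rows).set_index("env_var"), "mantel_env.tsv",
                     index_name="env_var")

        stage = "manifest"
        manifest.write(outdir / "manifest.json")
        created.append(outdir / "manifest.json")
    except Exception as exc:
        for path in created:
            try:
                path.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return outdir
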