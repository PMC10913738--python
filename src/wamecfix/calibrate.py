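"""Size-fraction integration by RNA-yield weighting.

The two organismal size fractions (0.2-3 um and 3-200 um) are sequenced as
separate libraries, so their TPM values are not directly comparable: each
library is normalized to its own million. Weighting each fraction's
expression by its share of the total RNA recovered per litre of seawater
puts both on a whole-assemblage footing:

    calibrated_small = value_small * R_s / (R_s + R_l)
    calibrated_large = value_large * R_l / (R_s + R_l)

where R_s and R_l are the per-litre RNA yields of the small and large
fraction of the same water sample. The whole-assemblage value is the sum of
the two calibrated terms. Yield units cancel in the ratio, so any
consistent per-litre mass unit is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleTable, ValidationError

__all__ = ["CalibratedExpression", "condition_yields", "calibrate", "fraction_share"]


class PairingError(ValueError):
    """A condition lacks one of the two size fractions."""


@dataclass
class CalibratedExpression:
    """RNA-yield-weighted expression per (row, condition, fraction).

    ``small`` and ``large`` hold each fraction's weighted contribution;
    ``pooled`` is their sum (the whole-assemblage value); ``weights`` holds
    the normalized yield weights, which sum to 1 per condition.
    """

    small: pd.DataFrame
    large: pd.DataFrame
    pooled: pd.DataFrame
    weights: pd.DataFrame  # columns: weight_small, weight_large


def condition_yields(samples: SampleTable) -> pd.DataFrame:
    """Per-condition (station x layer) RNA yields per litre, one column per
    fraction, averaging replicate extractions."""
    f = samples.frame
    if "rna_yield_per_L" not in f.columns or f["rna_yield_per_L"].isna().any():
        raise ValidationError(
            "size-fraction calibration requires rna_yield_per_L for every library"
        )
    lab = f["station"].astype(str) + "_" + f["layer"].astype(str)
    out = (
        f.assign(condition=lab)
        .groupby(["condition", "size_fraction"])["rna_yield_per_L"]
        .mean()
        .unstack("size_fraction")
    )
    return out.rename(columns={"small": "rna_small", "large": "rna_large"})


def calibrate(
    values_small: pd.DataFrame,
    values_large: pd.DataFrame,
    yields: pd.DataFrame | SampleTable,
    allow_zero_yield: bool = False,
) -> CalibratedExpression:
    """Weight the two fractions' per-condition values by RNA yield.

    ``values_small``/``values_large`` are (row x condition) tables — TPM or
    activity values whose columns are condition labels. ``yields`` is either
    a frame with columns ``rna_small``/``rna_large`` indexed by condition,
    or a :class:`SampleTable` from which it is derived. Zero yields are
    rejected unless ``allow_zero_yield`` explicitly permits the degenerate
    single-fraction case.
    """
    if isinstance(yields, SampleTable):
        yields = condition_yields(yields)
    conditions = list(values_small.columns)
    if list(values_large.columns) != conditions:
        missing = set(conditions).symmetric_difference(values_large.columns)
        raise PairingError(f"fractions disagree on conditions: {sorted(missing)}")
    missing_y = [c for c in conditions if c not in yields.index]
    if missing_y:
        raise PairingError(f"no RNA yields for condition '{missing_y[0]}'")
    y = yields.loc[conditions]
    if y[["rna_small", "rna_large"]].isna().any().any():
        raise PairingError("a condition lacks the RNA yield of one fraction")
    vals = y[["rna_small", "rna_large"]].to_numpy(dtype=float)
    if (vals < 0).any() or (not allow_zero_yield and (vals <= 0).any()):
        raise ValidationError("RNA yields must be positive (or zero with explicit override)")
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError("both fractions have zero RNA yield in some condition")
    w_small = vals[:, 0] / totals
    w_large = vals[:, 1] / totals

    rows = values_small.index.union(values_large.index)
    vs = values_small.reindex(index=rows, fill_value=0.0)
    vl = values_large.reindex(index=rows, fill_value=0.0)
    small = vs * w_small[None, :]
    large = vl * w_large[None, :]
    weights = pd.DataFrame(
        {"weight_small": w_small, "weight_large": w_large}, index=pd.Index(conditions)
    )
    return CalibratedExpression(small=small, large=large, pooled=small + large, weights=weights)


def fraction_share(
    calibrated: CalibratedExpression, rows: list | None = None
) -> pd.DataFrame:
    """Percent contribution of the small versus large fraction per condition,
    for the calibrated values (optionally restricted to ``rows``, e.g. the
    unigenes or lineages of one pathway). Shares sum to 100; conditions with
    zero pooled value are NaN."""
    small, large = calibrated.small, calibrated.large
    if rows is not None:
        small = small.loc[small.index.intersection(rows)]
        large = large.loc[large.index.intersection(rows)]
    s = small.sum(axis=0)
    l = large.sum(axis=0)
    total = s + l
    with np.errstate(divide="ignore", invalid="ignore"):
        share_small = np.where(total > 0, s / total * 100.0, np.nan)
        share_large = np.where(total > 0, l / total * 100.0, np.nan)
    return pd.DataFrame(
        {"share_small": share_small, "share_large": share_large}, index=s.index
    )
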