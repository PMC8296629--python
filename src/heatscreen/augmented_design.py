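"""Adjustment of unreplicated entries via repeated controls, and the MSD.

An augmented design replicates a small set of check (control) varieties in
every block while each tested entry appears once. The controls estimate
additive block effects

    R_j = (B_j - M) / c

where ``B_j`` is the sum of control values in block ``j`` (within-block means
when a control is replicated inside a block), ``M`` the sum of the controls'
across-block means and ``c`` the number of controls. Entry values are adjusted
by subtracting their block's ``R_j``, which centres blocks: the mean of a
control's adjusted values across blocks equals its grand mean.

Significance of an adjusted entry against a control mean uses the minimum
significant difference

    S2_vc = CME (b+1)(c+1) / (b c),      MSD = t * sqrt(S2_vc)

with ``CME`` the residual mean square of the controls' block x control
two-way layout, ``b`` the number of blocks and ``t`` a Student quantile at
alpha = 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import ControlSpec, TraitObservation, to_frame

CALL_HIGHER = "higher"
CALL_LOWER = "lower"
CALL_NOT_DIFFERENT = "not_different"


@dataclass
class BlockFactors:
    """Per-block correction factors estimated from the controls."""

    r_by_block: dict[str, float]
    control_means: dict[str, float]  # across-block mean per control
    m: float  # sum of control means
    b: int
    c: int


@dataclass
class AugmentedAdjustment:
    """MSD threshold bundle for one trait x regime."""

    trait: str
    regime: str
    r_by_block: dict[str, float]
    control_grand_sum: float
    n_controls: int
    n_blocks: int
    cme: float
    s2_vc: float
    t_crit: float
    msd: float
    df: float
    alpha: float = 0.05
    control_means_adjusted: dict[str, float] = field(default_factory=dict)


def _control_table(control_values: pd.DataFrame) -> pd.DataFrame:
    """b x c table of within-block control means.

    ``control_values`` is long-format with columns block, genotype_id, value.
    Within-block replication of a control collapses to its within-block mean
    so unequal replication does not distort the block sums.
    """
    if control_values.empty:
        raise ValueError("no control observations supplied")
    table = (
        control_values.groupby(["block", "genotype_id"])["value"].mean().unstack("genotype_id")
    )
    if table.isna().any().any():
        holes = [
            f"control {table.columns[j]!r} absent from block {table.index[i]!r}"
            for i, j in zip(*np.where(table.isna().to_numpy()))
        ]
        raise ValueError("; ".join(holes))
    return table


def compute_block_factors(control_values: pd.DataFrame) -> BlockFactors:
    """Estimate R_j = (B_j - M)/c from control observations.

    Parameters
    ----------
    control_values:
        Long-format DataFrame with columns ``block``, ``genotype_id``,
        ``value`` holding every control observation for one trait x regime.
    """
    table = _control_table(control_values)
    b, c = table.shape
    control_means = table.mean(axis=0)  # across-block mean per control
    m = float(control_means.sum())
    bj = table.sum(axis=1)
    r_by_block = {str(block): float((bj_val - m) / c) for block, bj_val in bj.items()}
    return BlockFactors(
        r_by_block=r_by_block,
        control_means={str(g): float(v) for g, v in control_means.items()},
        m=m,
        b=b,
        c=c,
    )


def adjust_values(values: pd.DataFrame, r_by_block: Mapping[str, float]) -> pd.DataFrame:
    """Subtract each block's correction factor from raw values.

    ``values`` needs columns ``block`` and ``value``; the result carries both
    ``value`` (raw) and ``adjusted``. Entries in the same block shift by the
    same amount, so within-block differences are preserved.
    """
    unknown = set(values["block"].astype(str)) - set(r_by_block)
    if unknown:
        raise ValueError(f"no block factor for block(s): {sorted(unknown)}")
    out = values.copy()
    out["adjusted"] = out["value"] - out["block"].astype(str).map(r_by_block)
    return out


def control_anova_cme(control_values: pd.DataFrame) -> tuple[float, int]:
    """Residual mean square (CME) of the controls' block + control layout.

    Computed on the b x c table of within-block control means via the
    balanced two-way decomposition without interaction; returns
    ``(cme, (b-1)(c-1))``.
    """
    table = _control_table(control_values)
    b, c = table.shape
    if b < 2 or c < 2:
        raise ValueError(f"need >=2 blocks and >=2 controls for a residual (got b={b}, c={c})")
    y = table.to_numpy(float)
    grand = y.mean()
    block_eff = y.mean(axis=1, keepdims=True) - grand
    ctrl_eff = y.mean(axis=0, keepdims=True) - grand
    resid = y - grand - block_eff - ctrl_eff
    df = (b - 1) * (c - 1)
    return float((resid**2).sum() / df), df


def compute_msd(
    cme: float,
    b: int,
    c: int,
    alpha: float = 0.05,
    df_mode: str = "product",
    sided: str = "two",
) -> tuple[float, float, float, float]:
    """MSD threshold from the control mean square error.

    Returns ``(s2_vc, t_crit, msd, df)`` with
    ``s2_vc = cme (b+1)(c+1)/(b c)`` and ``msd = t_crit * sqrt(s2_vc)``.

    ``df_mode='product'`` uses the residual degrees of freedom of the control
    layout, (b-1)(c-1); ``'paper-literal'`` uses the ratio (b-1)/(c-1) as some
    published descriptions print it. ``sided`` selects a two-sided
    (t at 1-alpha/2) or one-sided (t at 1-alpha) quantile.
    """
    if cme < 0:
        raise ValueError("cme must be non-negative")
    if df_mode == "product":
        df = float((b - 1) * (c - 1))
    elif df_mode == "paper-literal":
        df = (b - 1) / (c - 1)
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    if sided == "two":
        q = 1 - alpha / 2
    elif sided == "one":
        q = 1 - alpha
    else:
        raise ValueError(f"sided must be 'two' or 'one', got {sided!r}")
    t_crit = float(stats.t.ppf(q, df))
    s2_vc = cme * (b + 1) * (c + 1) / (b * c)
    return s2_vc, t_crit, float(t_crit * np.sqrt(s2_vc)), df


def call_vs_control(adjusted_value: float, control_mean: float, msd: float) -> str:
    """Three-way call of an adjusted entry value against a control mean.

    ``higher`` iff the value strictly exceeds control_mean + MSD, ``lower``
    iff strictly below control_mean - MSD, else ``not_different``.
    """
    if msd < 0:
        raise ValueError("msd must be non-negative")
    if adjusted_value > control_mean + msd:
        return CALL_HIGHER
    if adjusted_value < control_mean - msd:
        return CALL_LOWER
    return CALL_NOT_DIFFERENT


def _trait_values(frame: pd.DataFrame, trait: str) -> pd.Series:
    trait = trait.upper()
    if trait == "FLN":
        return frame["fln"].astype(float)
    if trait == "FRN":
        return frame["frn"].astype(float)
    if trait == "FRS":
        fln = frame["fln"].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frs = 100.0 * frame["frn"].astype(float) / fln
        return frs.where(fln > 0)  # FLN = 0 -> undefined fruit set
    raise ValueError(f"unknown trait {trait!r}")


def screen_trait(
    observations: Sequence[TraitObservation] | pd.DataFrame,
    controls: Sequence[ControlSpec],
    trait: str = "FRS",
    regime: str = "T2",
    alpha: float = 0.05,
    df_mode: str = "product",
    sided: str = "two",
) -> tuple[pd.DataFrame, AugmentedAdjustment]:
    """Run the augmented-design screen for one trait at one regime.

    Block factors and the MSD are estimated from the controls; every value
    (controls included) is adjusted, and each tested entry is called against
    each control's mean of adjusted values.

    Returns a per-genotype table with columns ``genotype_id``, ``block``,
    ``raw``, ``adjusted`` and one ``vs_<control>`` call column per control,
    plus the :class:`AugmentedAdjustment` used.
    """
    frame = observations if isinstance(observations, pd.DataFrame) else to_frame(observations)
    frame = frame[frame["regime"] == regime].copy()
    if frame.empty:
        raise ValueError(f"no observations at regime {regime!r}")
    frame["value"] = _trait_values(frame, trait)
    frame = frame.dropna(subset=["value"])
    control_ids = [c.genotype_id for c in controls]
    is_control = frame["genotype_id"].isin(control_ids)
    control_values = frame.loc[is_control, ["block", "genotype_id", "value"]]
    factors = compute_block_factors(control_values)
    cme, _ = control_anova_cme(control_values)
    s2_vc, t_crit, msd, df = compute_msd(cme, factors.b, factors.c, alpha, df_mode, sided)
    adjusted = adjust_values(frame[["genotype_id", "block", "value"]], factors.r_by_block)
    adjusted_control_means = (
        adjusted[adjusted["genotype_id"].isin(control_ids)]
        .groupby("genotype_id")["adjusted"]
        .mean()
        .to_dict()
    )
    result = adjusted.rename(columns={"value": "raw"})
    for control in control_ids:
        mean = adjusted_control_means[control]
        result[f"vs_{control}"] = [
            call_vs_control(v, mean, msd) for v in result["adjusted"]
        ]
    result.insert(1, "is_control", result["genotype_id"].isin(control_ids))
    adjustment = AugmentedAdjustment(
        trait=trait.upper(),
        regime=regime,
        r_by_block=factors.r_by_block,
        control_grand_sum=factors.m,
        n_controls=factors.c,
        n_blocks=factors.b,
        cme=cme,
        s2_vc=s2_vc,
        t_crit=t_crit,
        msd=msd,
        df=df,
        alpha=alpha,
        control_means_adjusted={k: float(v) for k, v in adjusted_control_means.items()},
    )
    return result.reset_index(drop=True), adjustment
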