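"""Fruit-set computation, candidate selection and trajectory classification.

Fruit set percentage, FRS = 100 * FRN / FLN, is the tolerance criterion: a
genotype significantly above the sensitive control at a high-temperature
regime (T2 or T3) is a heat-tolerance candidate. Candidates are classified by
where they beat the control and by the shape of their FRS trajectory across
the three regimes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .augmented_design import CALL_HIGHER

PATTERN_T2_ONLY = "T2_only"
PATTERN_T2_T3_MONOTONE = "T2_T3_monotone"
PATTERN_T2_T3_RECOVERY = "T2_T3_recovery"
PATTERN_T3_ONLY = "T3_only"
PATTERN_NOT_TOLERANT = "not_tolerant"

PATTERNS = (
    PATTERN_T2_ONLY,
    PATTERN_T2_T3_MONOTONE,
    PATTERN_T2_T3_RECOVERY,
    PATTERN_T3_ONLY,
    PATTERN_NOT_TOLERANT,
)

#: response archetype implied by each trajectory pattern: a mild monotone
#: decline marks moderate-heat tolerance, a dip at T2 with recovery at T3
#: marks the adaptive response, and no significant call marks sensitivity.
PATTERN_TO_ARCHETYPE = {
    PATTERN_T2_ONLY: "tolerant",
    PATTERN_T2_T3_MONOTONE: "tolerant",
    PATTERN_T2_T3_RECOVERY: "adaptive",
    PATTERN_T3_ONLY: "adaptive",
    PATTERN_NOT_TOLERANT: "sensitive",
}


def compute_frs(fln: float, frn: float) -> float:
    """Fruit set percentage of one replicate; NaN when no flowers were set.

    A replicate with flowers but no fruit has FRS 0; a replicate with no
    flowers has no defined fruit set and is excluded from means downstream.
    """
    if frn > fln:
        raise ValueError(f"frn ({frn}) exceeds fln ({fln})")
    if fln == 0:
        return math.nan
    return 100.0 * frn / fln


def aggregate_frs(
    fln: Sequence[float], frn: Sequence[float], mode: str = "per_replicate_mean"
) -> float:
    """Genotype-level FRS from replicate counts.

    ``per_replicate_mean`` averages the replicate-level percentages (NaN
    replicates excluded); ``ratio_of_means`` computes
    100 * mean(FRN) / mean(FLN), the form applicable when only trait means
    are available.
    """
    fln_arr = np.asarray(fln, float)
    frn_arr = np.asarray(frn, float)
    if np.any(frn_arr > fln_arr):
        raise ValueError("frn exceeds fln in at least one replicate")
    if mode == "per_replicate_mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            per_rep = np.where(fln_arr > 0, 100.0 * frn_arr / fln_arr, np.nan)
        if np.all(np.isnan(per_rep)):
            return math.nan
        return float(np.nanmean(per_rep))
    if mode == "ratio_of_means":
        mean_fln = fln_arr.mean()
        if mean_fln == 0:
            return math.nan
        return float(100.0 * frn_arr.mean() / mean_fln)
    raise ValueError(f"unknown mode {mode!r}")


def select_candidates(calls: pd.DataFrame) -> list[str]:
    """Heat-tolerance candidates: genotypes called higher than the sensitive
    control at T2 or at T3 (T1 plays no role in selection).

    ``calls`` needs columns ``genotype_id``, ``regime``, ``call``.
    """
    high = calls[(calls["regime"].isin(["T2", "T3"])) & (calls["call"] == CALL_HIGHER)]
    return sorted(high["genotype_id"].unique())


def classify_pattern(
    higher_t2: bool, higher_t3: bool, frs_by_regime: Mapping[str, float]
) -> str:
    """Trajectory pattern of one candidate from its T2/T3 calls and FRS curve.

    Higher at T2 only -> moderate-stress tolerance; higher at T3 only -> the
    adaptive response (collapse at T2, recovery at T3); higher at both ->
    monotone decline or recovery depending on whether FRS rises from T2 to
    T3 (a tie is no evidence of recovery and stays monotone).
    """
    if higher_t2 and higher_t3:
        for regime in ("T2", "T3"):
            if regime not in frs_by_regime or pd.isna(frs_by_regime[regime]):
                raise ValueError(f"FRS at {regime} required to resolve the trajectory")
        if frs_by_regime["T3"] > frs_by_regime["T2"]:
            return PATTERN_T2_T3_RECOVERY
        return PATTERN_T2_T3_MONOTONE
    if higher_t2:
        return PATTERN_T2_ONLY
    if higher_t3:
        return PATTERN_T3_ONLY
    return PATTERN_NOT_TOLERANT


def classify_all(calls: pd.DataFrame, frs: pd.DataFrame) -> pd.DataFrame:
    """Pattern assignment for every genotype in a calls table.

    ``calls``: columns genotype_id, regime, call (vs the sensitive control).
    ``frs``: columns genotype_id, regime, frs (the trajectory, adjusted
    values for augmented screens).
    """
    frs_map = frs.set_index(["genotype_id", "regime"])["frs"]
    rows = []
    for genotype, sub in calls.groupby("genotype_id"):
        by_regime = sub.set_index("regime")["call"]
        higher_t2 = by_regime.get("T2") == CALL_HIGHER
        higher_t3 = by_regime.get("T3") == CALL_HIGHER
        trajectory = {
            regime: frs_map.get((genotype, regime), math.nan) for regime in ("T1", "T2", "T3")
        }
        pattern = classify_pattern(bool(higher_t2), bool(higher_t3), trajectory)
        rows.append(
            {
                "genotype_id": genotype,
                "pattern": pattern,
                "archetype": PATTERN_TO_ARCHETYPE[pattern],
            }
        )
    return pd.DataFrame(rows, columns=["genotype_id", "pattern", "archetype"])


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report style)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def summarize_groups(
    patterns: pd.DataFrame,
    groups: Mapping[str, str],
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-germplasm-group selection summary with a TOTAL row.

    ``patterns`` has one row per analyzed genotype with columns
    ``genotype_id`` and ``pattern``; ``groups`` maps genotype to germplasm
    group. Selected counts split by where tolerance was seen: T2 only, both
    T2 and T3 (either both-regime pattern), or T3 only. ``percent`` is
    100 * total_selected / analyzed rounded half away from zero;
    ``percent_exact`` keeps the unrounded value.
    """
    missing = [g for g in patterns["genotype_id"] if g not in groups]
    if missing:
        raise ValueError(f"no group for genotype(s): {missing[:5]}")
    frame = patterns.copy()
    frame["group"] = frame["genotype_id"].map(groups)
    order = list(group_order) if group_order else sorted(frame["group"].unique())
    rows = []
    for name in order + ["TOTAL"]:
        sub = frame if name == "TOTAL" else frame[frame["group"] == name]
        analyzed = len(sub)
        t2 = int((sub["pattern"] == PATTERN_T2_ONLY).sum())
        t2t3 = int(
            sub["pattern"].isin([PATTERN_T2_T3_MONOTONE, PATTERN_T2_T3_RECOVERY]).sum()
        )
        t3 = int((sub["pattern"] == PATTERN_T3_ONLY).sum())
        total = t2 + t2t3 + t3
        exact = 100.0 * total / analyzed if analyzed else 0.0
        rows.append(
            {
                "group": name,
                "analyzed": analyzed,
                "selected_T2": t2,
                "selected_T2T3": t2t3,
                "selected_T3": t3,
                "total_selected": total,
                "percent_exact": exact,
                "percent": _round_half_away(exact),
            }
        )
    return pd.DataFrame(rows)
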