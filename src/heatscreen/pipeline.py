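"""End-to-end screen -> adjust -> select -> classify orchestration."""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .augmented_design import AugmentedAdjustment, screen_trait
from .tolerance_calls import classify_all, select_candidates
from .trial_data import ControlSpec


@dataclass
class ScreenOutcome:
    """Full augmented-screen result for one trait across regimes."""

    calls: pd.DataFrame        # genotype_id, regime, call (vs sensitive control)
    frs: pd.DataFrame          # genotype_id, regime, frs (adjusted trajectory)
    patterns: pd.DataFrame     # genotype_id, pattern, archetype
    candidates: list[str]
    adjustments: dict[str, AugmentedAdjustment]
    per_regime: dict[str, pd.DataFrame]


def run_augmented_screen(
    observations: pd.DataFrame,
    controls: list[ControlSpec],
    sensitive_control: str,
    trait: str = "FRS",
    alpha: float = 0.05,
    df_mode: str = "product",
    sided: str = "two",
) -> ScreenOutcome:
    """Screen every tested genotype against the sensitive control.

    Runs the augmented adjustment and MSD call at each regime, selects
    candidates (higher than the sensitive control at T2 or T3) and
    classifies their FRS trajectory patterns. Control genotypes are excluded
    from candidate selection and classification.
    """
    if sensitive_control not in {c.genotype_id for c in controls}:
        raise ValueError(f"sensitive control {sensitive_control!r} not among the controls")
    control_ids = {c.genotype_id for c in controls}
    call_rows, frs_rows = [], []
    adjustments: dict[str, AugmentedAdjustment] = {}
    per_regime: dict[str, pd.DataFrame] = {}
    for regime in ("T1", "T2", "T3"):
        result, adjustment = screen_trait(
            observations, controls, trait=trait, regime=regime,
            alpha=alpha, df_mode=df_mode, sided=sided,
        )
        adjustments[regime] = adjustment
        per_regime[regime] = result
        tested = result[~result["is_control"]]
        for _, row in tested.iterrows():
            call_rows.append(
                {
                    "genotype_id": row["genotype_id"],
                    "regime": regime,
                    "call": row[f"vs_{sensitive_control}"],
                }
            )
        means = result.groupby("genotype_id")["adjusted"].mean()
        for genotype, value in means.items():
            frs_rows.append({"genotype_id": genotype, "regime": regime, "frs": float(value)})
    calls = pd.DataFrame(call_rows)
    frs = pd.DataFrame(frs_rows)
    frs = frs[~frs["genotype_id"].isin(control_ids)].reset_index(drop=True)
    patterns = classify_all(calls, frs)
    candidates = select_candidates(calls)
    return ScreenOutcome(
        calls=calls,
        frs=frs,
        patterns=patterns,
        candidates=candidates,
        adjustments=adjustments,
        per_regime=per_regime,
    )
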