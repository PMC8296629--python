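import numpy as np
import pandas as pd
import pytest

from heatscreen.trial_data import ControlSpec, TraitObservation


@pytest.fixture
def toy_control_values() -> pd.DataFrame:
    """2 blocks x 2 controls: block1 {10, 20}, block2 {12, 26}.

    Control means 11 and 23, M = 34, R1 = (30-34)/2 = -2, R2 = (38-34)/2 = +2.
    """
    return pd.DataFrame(
        {
            "block": ["B1", "B1", "B2", "B2"],
            "genotype_id": ["c1", "c2", "c1", "c2"],
            "value": [10.0, 20.0, 12.0, 26.0],
        }
    )


@pytest.fixture
def small_trial() -> tuple[list[TraitObservation], list[ControlSpec]]:
    """2 blocks, 2 controls in every block, 2 tested entries (one per block)."""
    obs = []
    layout = [
        ("chk1", "B1", 10, 8), ("chk2", "B1", 10, 5),
        ("chk1", "B2", 10, 9), ("chk2", "B2", 10, 4),
        ("g1", "B1", 12, 9), ("g2", "B2", 8, 2),
    ]
    for genotype, block, fln, frn in layout:
        for regime in ("T1", "T2", "T3"):
            obs.append(
                TraitObservation(
                    experiment_id="E", genotype_id=genotype, block=block,
                    replicate=1, regime=regime, fln=fln, frn=frn,
                )
            )
    controls = [ControlSpec("chk1", role="sensitive"), ControlSpec("chk2")]
    return obs, controls


def random_control_table(rng: np.random.Generator, b: int, c: int) -> pd.DataFrame:
    """Random long-format control observations for b blocks x c controls."""
    rows = []
    for i in range(b):
        for j in range(c):
            rows.append((f"B{i}", f"c{j}", rng.normal(50, 10)))
    return pd.DataFrame(rows, columns=["block", "genotype_id", "value"])
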