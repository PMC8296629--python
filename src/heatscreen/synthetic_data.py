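"""Simulators for screening trials and DEG tables with known ground truth.

The trial generator emulates an augmented greenhouse screen: repeated check
varieties in every block, unreplicated tested entries, three temperature
regimes, and three response archetypes for fruit set percentage —

* ``sensitive``: monotone collapse of FRS with temperature,
* ``tolerant``: mild monotone decline,
* ``adaptive``: collapse at the moderate regime, recovery at the extreme one.

Per replicate, the flower count FLN is an overdispersed (gamma-Poisson)
count around the archetype's regime mean plus an additive block effect, and
the fruit count FRN is binomial given FLN with a fruit-set probability drawn
from a beta distribution concentrated around the archetype curve. FRN <= FLN
holds by construction, so generated tables always validate.

The DEG generator emits null genes (small centred LFC, uniform p) and spiked
genes (|LFC| above a floor, p <= 1e-4) with per-sample RPKM values, a
configurable fraction of genes being silent in every sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trial_data import ControlSpec, TraitObservation

ARCHETYPES = ("sensitive", "tolerant", "adaptive")


@dataclass(frozen=True)
class ArchetypeCurve:
    """Mean FRS (%) and FLN per regime for one response archetype."""

    name: str
    frs_mean: Mapping[str, float]
    fln_mean: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.name!r}")
        for regime in ("T1", "T2", "T3"):
            if regime not in self.frs_mean or regime not in self.fln_mean:
                raise ValueError(f"archetype {self.name}: missing regime {regime}")
            if not 0 <= self.frs_mean[regime] <= 100:
                raise ValueError("frs_mean must be a percentage")
            if self.fln_mean[regime] <= 0:
                raise ValueError("fln_mean must be positive")
        t1, t2, t3 = (self.frs_mean[r] for r in ("T1", "T2", "T3"))
        if self.name == "sensitive" and not t1 > t2 > t3:
            raise ValueError("sensitive archetype requires a monotone FRS decline")
        if self.name == "adaptive" and not t3 > t2:
            raise ValueError("adaptive archetype requires recovery at T3")


#: Default archetype curves. FRS curves follow the three canonical response
#: shapes; FLN means are per-replicate flower totals (a replicate pools a
#: few plants and trusses over a multi-week regime), declining with heat.
DEFAULT_ARCHETYPES: dict[str, ArchetypeCurve] = {
    "sensitive": ArchetypeCurve(
        "sensitive", {"T1": 90.0, "T2": 40.0, "T3": 10.0}, {"T1": 80.0, "T2": 65.0, "T3": 35.0}
    ),
    "tolerant": ArchetypeCurve(
        "tolerant", {"T1": 90.0, "T2": 75.0, "T3": 50.0}, {"T1": 80.0, "T2": 70.0, "T3": 50.0}
    ),
    "adaptive": ArchetypeCurve(
        "adaptive", {"T1": 90.0, "T2": 25.0, "T3": 55.0}, {"T1": 80.0, "T2": 60.0, "T3": 45.0}
    ),
}

#: Default check set: three sensitive checks (one designated for tolerance
#: calls), one tolerant and one adaptive, mirroring a five-check screen.
DEFAULT_CONTROLS: tuple[tuple[ControlSpec, str], ...] = (
    (ControlSpec("CHK-SENS-1", role="sensitive"), "sensitive"),
    (ControlSpec("CHK-SENS-2", role="neutral"), "sensitive"),
    (ControlSpec("CHK-SENS-3", role="neutral"), "sensitive"),
    (ControlSpec("CHK-TOL", role="tolerant"), "tolerant"),
    (ControlSpec("CHK-ADAPT", role="neutral"), "adaptive"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings for a simulated screening trial.

    ``fln_dispersion`` is the gamma-Poisson excess 1/size (0 gives Poisson
    counts); ``frs_noise_kappa`` is the beta concentration of the fruit-set
    probability (None pins the probability to the archetype mean);
    ``block_effect_sd`` is the SD of additive block effects on the FLN
    latent mean, in flowers. The fully noise-free limit (dispersion 0,
    kappa None, block SD 0) produces deterministic rounded counts.
    """

    n_genotypes: Mapping[str, int] = field(
        default_factory=lambda: {"sensitive": 68, "tolerant": 66, "adaptive": 66}
    )
    n_blocks: int = 6
    controls: tuple[tuple[ControlSpec, str], ...] = DEFAULT_CONTROLS
    archetypes: Mapping[str, ArchetypeCurve] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    fln_dispersion: float = 0.05
    block_effect_sd: float = 5.0
    frs_noise_kappa: float | None = 150.0
    seed: int = 0
    experiment_id: str = "SYNTH"

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be positive")
        if any(n < 0 for n in self.n_genotypes.values()):
            raise ValueError("genotype counts must be non-negative")
        if self.fln_dispersion < 0:
            raise ValueError("fln_dispersion must be >= 0")
        if self.block_effect_sd < 0:
            raise ValueError("block_effect_sd must be >= 0")
        if self.frs_noise_kappa is not None and self.frs_noise_kappa <= 0:
            raise ValueError("frs_noise_kappa must be positive or None")
        unknown = set(self.n_genotypes) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s): {sorted(unknown)}")
        if not self.controls:
            raise ValueError("at least one control required")

    @property
    def deterministic(self) -> bool:
        return (
            self.fln_dispersion == 0
            and self.block_effect_sd == 0
            and self.frs_noise_kappa is None
        )

    @property
    def sensitive_control(self) -> str:
        for spec, _ in self.controls:
            if spec.role == "sensitive":
                return spec.genotype_id
        raise ValueError("no control with role 'sensitive'")


def _draw_fln(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    mean = max(mean, 1e-9)
    if dispersion == 0:
        return rng.poisson(mean, size=n)
    size = 1.0 / dispersion  # NB shape; variance = m + d m^2
    lam = rng.gamma(shape=size, scale=mean / size, size=n)
    return rng.poisson(lam)


def _draw_p(rng: np.random.Generator, mu: float, kappa: float | None, n: int) -> np.ndarray:
    mu = min(max(mu, 1e-6), 1 - 1e-6)
    if kappa is None:
        return np.full(n, mu)
    return rng.beta(mu * kappa, (1 - mu) * kappa, size=n)


def simulate_screen(
    config: SyntheticConfig, design: str = "augmented"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a screening trial; returns (trait table, truth labels).

    Under the augmented design each tested genotype appears once, in a
    single block, while every control appears in every block; under the
    randomized design every genotype (tested and control) is replicated in
    every block. The same genotype is observed at all three regimes.

    The trait table has the canonical long-format columns; truth labels map
    ``genotype_id`` to its ``archetype`` and ``is_control`` flag. The same
    seed reproduces identical tables.
    """
    if design not in ("augmented", "randomized"):
        raise ValueError(f"unknown design {design!r}")
    rng = np.random.default_rng(config.seed)
    blocks = [f"B{i + 1}" for i in range(config.n_blocks)]
    block_effects = {
        b: (0.0 if config.block_effect_sd == 0 else rng.normal(0.0, config.block_effect_sd))
        for b in blocks
    }
    # plan: (genotype_id, archetype, is_control, block, replicate)
    plan: list[tuple[str, str, bool, str, int]] = []
    for spec, archetype in config.controls:
        for block in blocks:
            for rep in range(1, spec.replicates_per_block + 1):
                plan.append((spec.genotype_id, archetype, True, block, rep))
    idx = 0
    for archetype in ARCHETYPES:
        for i in range(config.n_genotypes.get(archetype, 0)):
            genotype = f"G{idx + 1:04d}"
            idx += 1
            if design == "augmented":
                block = blocks[idx % len(blocks)]
                plan.append((genotype, archetype, False, block, 1))
            else:
                for block in blocks:
                    plan.append((genotype, archetype, False, block, 1))
    rows = []
    for genotype, archetype, is_control, block, rep in plan:
        curve = config.archetypes[archetype]
        for regime in ("T1", "T2", "T3"):
            mean_fln = curve.fln_mean[regime] + block_effects[block]
            if config.deterministic:
                fln = int(round(curve.fln_mean[regime]))
                frn = int(round(fln * curve.frs_mean[regime] / 100.0))
            else:
                fln = int(_draw_fln(rng, mean_fln, config.fln_dispersion, 1)[0])
                p = float(_draw_p(rng, curve.frs_mean[regime] / 100.0, config.frs_noise_kappa, 1)[0])
                frn = int(rng.binomial(fln, p)) if fln > 0 else 0
            rows.append(
                TraitObservation(
                    experiment_id=config.experiment_id,
                    genotype_id=genotype,
                    group=None,
                    block=block,
                    replicate=rep,
                    regime=regime,
                    fln=fln,
                    frn=frn,
                )
            )
    from .trial_data import to_frame

    table = to_frame(rows)
    truth = (
        pd.DataFrame(
            [(g, a, c) for g, a, c, _, _ in plan],
            columns=["genotype_id", "archetype", "is_control"],
        )
        .drop_duplicates("genotype_id")
        .reset_index(drop=True)
    )
    return table, truth


def simulate_deg_table(
    n_null: int,
    n_spiked: int,
    spike_lfc: float = 3.0,
    seed: int = 0,
    contrast_id: str = "SYNTH_contrast",
    n_samples: int = 4,
    null_lfc_sd: float = 0.5,
    zero_rpkm_fraction: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a per-contrast DEG table; returns (table, truth labels).

    Null genes draw LFC ~ Normal(0, ``null_lfc_sd``) and p ~ Uniform(0, 1);
    spiked genes draw |LFC| >= ``spike_lfc`` (random sign) and
    p ~ Uniform(0, 1e-4). A ``zero_rpkm_fraction`` of genes is silent (RPKM
    0 in every sample); the rest get log-normal positive RPKM.
    """
    if n_null < 0 or n_spiked < 0:
        raise ValueError("gene counts must be non-negative")
    if spike_lfc < 2.0:
        raise ValueError("spike_lfc must be >= 2")
    if not 0 <= zero_rpkm_fraction <= 1:
        raise ValueError("zero_rpkm_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    total = n_null + n_spiked
    gene_ids = [f"Syn{i:06d}" for i in range(total)]
    is_spiked = np.array([False] * n_null + [True] * n_spiked)
    lfc = np.empty(total)
    pval = np.empty(total)
    lfc[:n_null] = rng.normal(0.0, null_lfc_sd, n_null)
    pval[:n_null] = rng.uniform(0.0, 1.0, n_null)
    signs = rng.choice([-1.0, 1.0], n_spiked)
    lfc[n_null:] = signs * (spike_lfc + rng.exponential(0.5, n_spiked))
    pval[n_null:] = rng.uniform(0.0, 1e-4, n_spiked)
    silent = rng.random(total) < zero_rpkm_fraction
    samples = [f"S{i + 1}" for i in range(n_samples)]
    rpkm = np.where(
        silent[:, None], 0.0, rng.lognormal(mean=2.0, sigma=1.0, size=(total, n_samples))
    )
    table = pd.DataFrame({"gene_id": gene_ids, "lfc": lfc, "pvalue": pval})
    for j, s in enumerate(samples):
        table[f"rpkm_{s}"] = rpkm[:, j]
    table.insert(1, "contrast_id", contrast_id)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "spiked": is_spiked, "silent": silent}
    )
    return table, truth


def expected_null_pass_rate(
    lfc_min: float = 2.0, p_max: float = 0.01, null_lfc_sd: float = 0.5
) -> float:
    """Analytic probability that a null gene passes the DEG filter."""
    from scipy import stats

    return float(2.0 * stats.norm.sf(lfc_min / null_lfc_sd) * p_max)
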