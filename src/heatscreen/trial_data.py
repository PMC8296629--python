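"""Data model and I/O for multi-regime phenotyping trials and DEG tables.

The experimental unit is the replicate (a bag of plants grown together);
plant-level counts are assumed pre-aggregated to replicate level. Missing
counts are represented as absent records, never as zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

REGIME_LABELS = ("T1", "T2", "T3")

#: canonical columns of a long-format trait table
TRAIT_COLUMNS = (
    "experiment_id",
    "genotype_id",
    "group",
    "block",
    "replicate",
    "regime",
    "truss",
    "fln",
    "frn",
)


class GermplasmGroup(str, Enum):
    """Germplasm groups screened for heat tolerance."""

    wild = "wild"
    cerasiforme = "cerasiforme"
    traditional_penjar_serbo = "traditional_penjar_serbo"
    traditional_other = "traditional_other"
    modern_cultivar = "modern_cultivar"
    commercial_hybrid = "commercial_hybrid"


class ControlRole(str, Enum):
    sensitive = "sensitive"
    tolerant = "tolerant"
    neutral = "neutral"


@dataclass(frozen=True)
class TemperatureRegime:
    """A stepwise day/night greenhouse temperature treatment."""

    label: str
    day_temp: float
    night_temp: float

    def __post_init__(self) -> None:
        if self.label not in REGIME_LABELS:
            raise ValueError(f"regime label must be one of {REGIME_LABELS}, got {self.label!r}")
        if not self.day_temp > self.night_temp:
            raise ValueError(
                f"day_temp ({self.day_temp}) must exceed night_temp ({self.night_temp})"
            )


#: the three regimes used throughout: no stress, moderate and extreme heat stress
DEFAULT_REGIMES: dict[str, TemperatureRegime] = {
    "T1": TemperatureRegime("T1", 25.0, 20.0),
    "T2": TemperatureRegime("T2", 30.0, 25.0),
    "T3": TemperatureRegime("T3", 35.0, 30.0),
}


def validate_regimes(regimes: Sequence[TemperatureRegime]) -> None:
    """Check uniqueness and ordering (T1 < T2 < T3 by day temperature)."""
    labels = [r.label for r in regimes]
    if len(set(labels)) != len(labels):
        raise ValueError("regime labels must be unique within an experiment")
    ordered = sorted(regimes, key=lambda r: REGIME_LABELS.index(r.label))
    temps = [r.day_temp for r in ordered]
    if temps != sorted(temps) or len(set(temps)) != len(temps):
        raise ValueError("day temperatures must increase strictly T1 < T2 < T3")


@dataclass(frozen=True)
class TraitObservation:
    """One genotype x block x replicate x regime record of flower/fruit counts.

    ``fln`` is the flower count and ``frn`` the fruit count of the replicate;
    fruit set percentage is derived, never stored.
    """

    experiment_id: str
    genotype_id: str
    block: str
    replicate: int
    regime: str
    fln: int
    frn: int
    group: str | None = None
    truss: int | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")
        if self.truss is not None and self.truss < 1:
            raise ValueError(f"truss must be a positive integer, got {self.truss}")
        if self.regime not in REGIME_LABELS:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.fln < 0 or self.frn < 0:
            raise ValueError(f"counts must be non-negative (fln={self.fln}, frn={self.frn})")
        if self.frn > self.fln:
            raise ValueError(
                f"frn ({self.frn}) exceeds fln ({self.fln}) for genotype "
                f"{self.genotype_id!r} block {self.block!r} regime {self.regime}"
            )

    @property
    def key(self) -> tuple:
        return (
            self.experiment_id,
            self.genotype_id,
            self.block,
            self.replicate,
            self.regime,
            self.truss,
        )


@dataclass(frozen=True)
class ControlSpec:
    """A repeated check variety and its role in tolerance calls."""

    genotype_id: str
    role: str = ControlRole.neutral.value
    replicates_per_block: int = 1

    def __post_init__(self) -> None:
        ControlRole(self.role)
        if self.replicates_per_block < 1:
            raise ValueError("replicates_per_block must be >= 1")


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene statistics for one expression contrast."""

    gene_id: str
    contrast_id: str
    lfc: float
    pvalue: float
    rpkm: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue must lie in [0, 1], got {self.pvalue}")
        for sample, value in self.rpkm.items():
            if value < 0:
                raise ValueError(f"negative RPKM for sample {sample!r}: {value}")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def load_schema(path: str | Path) -> dict[str, str]:
    """Load a column-mapping config (YAML): canonical name -> file column."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError(f"schema file {path} must contain a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_trait_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[TraitObservation]:
    """Read a long-format trait table (CSV/TSV with header) into observations.

    Parameters
    ----------
    path:
        File to read; must exist. UTF-8, header row required.
    schema:
        Optional map from canonical column names (``TRAIT_COLUMNS``) to the
        file's column names. Unmapped canonical names fall back to identity.
    delimiter:
        Field delimiter; inferred from the file when ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        frame = pd.read_csv(path, sep=delimiter, dtype=str)
    colmap = {name: name for name in TRAIT_COLUMNS}
    if schema:
        colmap.update({k: v for k, v in schema.items() if k in TRAIT_COLUMNS})
    required = ("experiment_id", "genotype_id", "block", "replicate", "regime", "fln", "frn")
    for canonical in required:
        if colmap[canonical] not in frame.columns:
            raise SchemaError(f"required column {colmap[canonical]!r} (for {canonical!r}) missing")
    used = {colmap[c] for c in TRAIT_COLUMNS if colmap[c] in frame.columns}
    extras = [c for c in frame.columns if c not in used]
    if extras:
        logger.info("ignoring extra columns in %s: %s", path.name, ", ".join(extras))
    observations: list[TraitObservation] = []
    for idx, row in frame.iterrows():
        def cell(canonical: str) -> str | None:
            col = colmap[canonical]
            if col not in frame.columns:
                return None
            value = row[col]
            return None if pd.isna(value) else str(value)

        try:
            observations.append(
                TraitObservation(
                    experiment_id=cell("experiment_id"),
                    genotype_id=cell("genotype_id"),
                    group=cell("group"),
                    block=cell("block"),
                    replicate=int(cell("replicate")),
                    regime=cell("regime"),
                    truss=int(cell("truss")) if cell("truss") is not None else None,
                    fln=int(cell("fln")),
                    frn=int(cell("frn")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx} of {path.name}: {exc}") from exc
    keys = [o.key for o in observations]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValueError(f"duplicate observation key {dup}")
    return observations


def write_trait_table(
    observations: Iterable[TraitObservation], path: str | Path, delimiter: str = ","
) -> None:
    """Write observations back to a delimited text table (round-trip safe)."""
    frame = to_frame(observations)
    # keep optional integer columns integral in the text output
    frame["truss"] = frame["truss"].astype("Int64")
    frame.to_csv(path, sep=delimiter, index=False)


def to_frame(observations: Iterable[TraitObservation]) -> pd.DataFrame:
    """Long-format DataFrame view of a collection of observations."""
    rows = [
        {
            "experiment_id": o.experiment_id,
            "genotype_id": o.genotype_id,
            "group": o.group,
            "block": o.block,
            "replicate": o.replicate,
            "regime": o.regime,
            "truss": o.truss,
            "fln": o.fln,
            "frn": o.frn,
        }
        for o in observations
    ]
    return pd.DataFrame(rows, columns=list(TRAIT_COLUMNS))


def from_frame(frame: pd.DataFrame) -> list[TraitObservation]:
    """Inverse of :func:`to_frame` with full validation."""
    observations = []
    for _, row in frame.iterrows():
        observations.append(
            TraitObservation(
                experiment_id=str(row["experiment_id"]),
                genotype_id=str(row["genotype_id"]),
                group=None if pd.isna(row.get("group")) else str(row["group"]),
                block=str(row["block"]),
                replicate=int(row["replicate"]),
                regime=str(row["regime"]),
                truss=None if pd.isna(row.get("truss")) else int(row["truss"]),
                fln=int(row["fln"]),
                frn=int(row["frn"]),
            )
        )
    return observations


@dataclass
class DesignReport:
    """Structural summary of a trial layout."""

    design: str
    n_blocks: int
    n_controls: int
    controls_per_block: dict[str, int]
    replicated_entries: list[str]
    missing_cells: list[tuple[str, str]]

    @property
    def has_flags(self) -> bool:
        return bool(self.replicated_entries or self.missing_cells)


def validate_design(
    observations: Sequence[TraitObservation],
    controls: Sequence[ControlSpec],
    design: str = "augmented",
) -> DesignReport:
    """Check a trial layout against its declared design.

    For an augmented design every block must contain every control, and
    tested (non-control) genotypes with more than one replicate per block are
    flagged. ``missing_cells`` lists genotype x regime combinations with no
    record.
    """
    if design not in ("augmented", "randomized"):
        raise ValueError(f"unknown design {design!r}")
    if not observations:
        raise ValueError("no observations supplied")
    if design == "augmented" and not controls:
        raise ValueError("augmented design requires at least one control")
    control_ids = {c.genotype_id for c in controls}
    frame = to_frame(observations)
    blocks = sorted(frame["block"].unique())
    controls_per_block: dict[str, int] = {}
    for block in blocks:
        present = set(frame.loc[frame["block"] == block, "genotype_id"]) & control_ids
        controls_per_block[block] = len(present)
        if design == "augmented" and not present:
            raise ValueError(f"augmented design: block {block!r} contains no control")
    replicated: list[str] = []
    if design == "augmented":
        tested = frame[~frame["genotype_id"].isin(control_ids)]
        counts = tested.groupby(["genotype_id", "block", "regime"]).size()
        replicated = sorted(counts[counts > 1].index.get_level_values(0).unique())
    regimes = sorted(frame["regime"].unique())
    missing: list[tuple[str, str]] = []
    seen = set(zip(frame["genotype_id"], frame["regime"]))
    for genotype in sorted(frame["genotype_id"].unique()):
        for regime in regimes:
            if (genotype, regime) not in seen:
                missing.append((genotype, regime))
    return DesignReport(
        design=design,
        n_blocks=len(blocks),
        n_controls=len(control_ids & set(frame["genotype_id"])),
        controls_per_block=controls_per_block,
        replicated_entries=replicated,
        missing_cells=missing,
    )
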