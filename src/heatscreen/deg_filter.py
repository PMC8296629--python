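"""Transcriptome post-processing: expression calls, DEG thresholds, overlaps.

Consumes tabular per-gene results of an upstream differential-expression
pipeline (one table per contrast: log2 fold change, p-value, per-sample
RPKM). A gene counts as expressed when its RPKM exceeds zero in at least one
sample; it passes the DEG filter when |LFC| >= 2 and p < 0.01 (both
configurable; the LFC boundary is inclusive, the p boundary strict).
Positive LFC means higher expression in the first-named genotype of the
contrast.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .trial_data import DEGRecord

DEFAULT_LFC_MIN = 2.0
DEFAULT_P_MAX = 0.01


@dataclass
class ContrastResult:
    """DEG-filter outcome for one contrast."""

    contrast_id: str
    records: list[DEGRecord]  # the genes passing the filter
    n_up: int
    n_down: int
    lfc_min: float = DEFAULT_LFC_MIN
    p_max: float = DEFAULT_P_MAX
    pooled: bool = False  # pooled-RNA contrast: no replicate-based statistics

    @property
    def n_kept(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.records}

    def side(self, gene_id: str) -> str | None:
        """'first'/'second' genotype of the contrast with higher expression."""
        for record in self.records:
            if record.gene_id == gene_id:
                return "first" if record.lfc > 0 else "second"
        return None


def mark_expressed(record: DEGRecord) -> bool:
    """A gene is expressed iff RPKM > 0 in at least one sample."""
    if not record.rpkm:
        raise ValueError(f"gene {record.gene_id!r}: empty RPKM map")
    return any(v > 0 for v in record.rpkm.values())


def filter_deg(
    records: Iterable[DEGRecord],
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
    pooled: bool = False,
) -> ContrastResult:
    """Apply the DEG threshold |lfc| >= lfc_min and p < p_max.

    ``n_up`` counts kept genes with positive LFC (higher in the first-named
    genotype), ``n_down`` those with negative LFC.
    """
    records = list(records)
    contrast_ids = {r.contrast_id for r in records}
    if len(contrast_ids) > 1:
        raise ValueError(f"records span multiple contrasts: {sorted(contrast_ids)}")
    contrast_id = contrast_ids.pop() if contrast_ids else ""
    kept = [r for r in records if abs(r.lfc) >= lfc_min and r.pvalue < p_max]
    n_up = sum(1 for r in kept if r.lfc > 0)
    n_down = sum(1 for r in kept if r.lfc < 0)
    return ContrastResult(
        contrast_id=contrast_id,
        records=kept,
        n_up=n_up,
        n_down=n_down,
        lfc_min=lfc_min,
        p_max=p_max,
        pooled=pooled,
    )


def compare_contrasts(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Cross-contrast intersection table of DEG sets.

    One row per gene present in at least one contrast's DEG set; per
    contrast a column ``in_<contrast>`` (bool) and ``side_<contrast>``
    ('first'/'second' by which genotype overexpresses, empty when absent).
    ``common_all`` flags genes kept in every contrast, ``unique_to`` names
    the single contrast for genes kept in exactly one.
    """
    ids = [r.contrast_id for r in results]
    if len(results) < 2:
        raise ValueError("need at least two contrasts to compare")
    if len(set(ids)) != len(ids):
        raise ValueError("contrast ids must be distinct")
    all_genes = sorted(set().union(*(r.gene_ids for r in results)))
    rows = []
    for gene in all_genes:
        row: dict[str, object] = {"gene_id": gene}
        present_in = []
        for result in results:
            present = gene in result.gene_ids
            row[f"in_{result.contrast_id}"] = present
            row[f"side_{result.contrast_id}"] = result.side(gene) or ""
            if present:
                present_in.append(result.contrast_id)
        row["n_contrasts"] = len(present_in)
        row["common_all"] = len(present_in) == len(results)
        row["unique_to"] = present_in[0] if len(present_in) == 1 else ""
        rows.append(row)
    return pd.DataFrame(rows)


def read_deg_table(
    path: str | Path, contrast_id: str | None = None, use_padj: bool = False
) -> list[DEGRecord]:
    """Read a per-contrast DEG TSV: gene_id, lfc, pvalue[, padj], rpkm_<sample>...

    With ``use_padj`` the adjusted p-value column feeds the filter's p slot.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "lfc", "pvalue"):
        if col not in frame.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    if use_padj and "padj" not in frame.columns:
        raise ValueError(f"{path.name}: --use-padj requested but no 'padj' column")
    rpkm_cols = [c for c in frame.columns if c.startswith("rpkm_")]
    cid = contrast_id if contrast_id is not None else path.stem
    records = []
    for _, row in frame.iterrows():
        records.append(
            DEGRecord(
                gene_id=str(row["gene_id"]),
                contrast_id=cid,
                lfc=float(row["lfc"]),
                pvalue=float(row["padj"] if use_padj else row["pvalue"]),
                rpkm={c[len("rpkm_"):]: float(row[c]) for c in rpkm_cols},
            )
        )
    return records
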