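"""Target panel handling.

A hybrid-capture panel is a set of named exon intervals (BED convention:
0-based, half-open) over which coverage, pileups and local assembly windows
are keyed.  Intron intervals for rearrangement-prone genes may be carried in
the panel but are not used by any caller in this package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TargetPanel", "read_panel", "write_panel", "default_panel"]


class PanelError(ValueError):
    pass


@dataclass
class TargetPanel:
    """Sorted, gene-annotated exon intervals (0-based, half-open)."""

    exons: pd.DataFrame  # columns: contig, start, end, gene
    introns: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        required = ["contig", "start", "end", "gene"]
        missing = [c for c in required if c not in self.exons.columns]
        if missing:
            raise PanelError(f"panel missing columns: {missing}")
        bad = self.exons[self.exons.start >= self.exons.end]
        if len(bad):
            raise PanelError(f"empty/inverted intervals at rows {list(bad.index)}")
        self.exons = (
            self.exons.sort_values(["contig", "start", "end"])
            .reset_index(drop=True)[required]
        )

    def __len__(self) -> int:
        return len(self.exons)

    @property
    def genes(self) -> list[str]:
        return sorted(self.exons.gene.unique())

    def gene_exon_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each gene's exons in panel order."""
        return {g: idx.to_numpy() for g, idx in self.exons.groupby("gene").groups.items()}

    def contains(self, contig: str, pos_1based: int) -> bool:
        e = self.exons
        hit = (e.contig == contig) & (e.start < pos_1based) & (pos_1based <= e.end)
        return bool(hit.any())


def read_panel(path) -> TargetPanel:
    """Read a 4-column BED file into a validated panel.

    Malformed lines raise with their line number; overlapping exons of the
    same gene are merged.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise PanelError(f"{path}:{lineno}: expected 4 BED columns, got {len(parts)}")
            contig, start, end, gene = parts[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i >= end_i:
                raise PanelError(f"{path}:{lineno}: start >= end ({start_i} >= {end_i})")
            rows.append((contig, start_i, end_i, gene))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "gene"])
    df = _merge_same_gene_overlaps(df)
    return TargetPanel(df)


def write_panel(panel: TargetPanel, path) -> None:
    panel.exons.to_csv(path, sep="\t", header=False, index=False)


def _merge_same_gene_overlaps(df: pd.DataFrame) -> pd.DataFrame:
    out = []
    for (contig, gene), grp in df.groupby(["contig", "gene"], sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end = row.start, row.end
            elif row.start <= cur_end:  # overlap or book-ended: merge
                cur_end = max(cur_end, row.end)
            else:
                out.append((contig, cur_start, cur_end, gene))
                cur_start, cur_end = row.start, row.end
        out.append((contig, cur_start, cur_end, gene))
    res = pd.DataFrame(out, columns=["contig", "start", "end", "gene"])
    return res.sort_values(["contig", "start"]).reset_index(drop=True)


# Genes given non-zero alteration prevalence in the bundled two-group cohort
# template; the remainder of the synthetic panel is filler to provide a
# diploid background and error-only sites.
HEADLINE_GENES = [
    "TP53", "CCND1", "CDKN2A", "CDKN2B", "PIK3CA", "PTEN",
    "FBXW7", "SOX2", "NOTCH1", "STK11",
]


def default_panel(n_filler_genes: int = 10, exons_per_gene: int = 10,
                  exon_length: int = 150, gap: int = 2000) -> TargetPanel:
    """Synthetic reduced-scale panel emulating a multi-gene capture design.

    One contig per gene keeps gene-level segmentation honest (no cross-gene
    segments joining unrelated loci through genome adjacency).
    """
    genes = HEADLINE_GENES + [f"GENE{i:03d}" for i in range(n_filler_genes)]
    rows = []
    for g in genes:
        pos = 10_000
        for _ in range(exons_per_gene):
            rows.append((f"chr_{g}", pos, pos + exon_length, g))
            pos += exon_length + gap
    return TargetPanel(pd.DataFrame(rows, columns=["contig", "start", "end", "gene"]))
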