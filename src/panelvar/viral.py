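"""HPV status from hybrid-capture viral read counts.

Read pairs mapping to each captured viral genome are normalised to reads
per million total sequenced pairs; an HPV-16 rate of >= 5 reads per million
is called positive and <= 2 negative.  The open interval between the two
printed thresholds maps to an explicit ``indeterminate`` status (borderline
samples were excluded from the study design rather than forced to a side).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ViralReadReport", "reads_per_million", "classify_hpv_status",
           "classify_counts"]

POSITIVE_RPM = 5.0
NEGATIVE_RPM = 2.0


def reads_per_million(viral_count: int, total: int) -> float:
    """Viral read(-pair) count per million total sequenced read pairs."""
    if total <= 0:
        raise ValueError("total read count must be positive")
    if viral_count < 0:
        raise ValueError("viral read count must be non-negative")
    return 1e6 * viral_count / total


def classify_hpv_status(rpm: float, positive: float = POSITIVE_RPM,
                        negative: float = NEGATIVE_RPM) -> str:
    """Three-way HPV status with closed thresholds as printed."""
    if rpm < 0:
        raise ValueError("reads-per-million cannot be negative")
    if rpm >= positive:
        return "positive"
    if rpm <= negative:
        return "negative"
    return "indeterminate"


@dataclass
class ViralReadReport:
    sample: str
    virus: str
    viral_reads: int
    total_reads: int

    @property
    def reads_per_million(self) -> float:
        return reads_per_million(self.viral_reads, self.total_reads)

    @property
    def status(self) -> str:
        return classify_hpv_status(self.reads_per_million)

    def as_row(self) -> dict:
        return {
            "sample": self.sample, "virus": self.virus,
            "viral_reads": self.viral_reads, "total_reads": self.total_reads,
            "rpm": self.reads_per_million, "status": self.status,
        }


def classify_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification of a (sample, virus, viral_reads,
    total_reads) table; returns the table with ``rpm`` and ``status`` added."""
    reports = [
        ViralReadReport(r.sample, r.virus, int(r.viral_reads), int(r.total_reads))
        for r in counts.itertuples()
    ]
    return pd.DataFrame([r.as_row() for r in reports])
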