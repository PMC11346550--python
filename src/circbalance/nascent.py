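"""Nascent-RNA analysis: per-gene circRNA fraction of newly made transcripts.

Metabolic labeling captures newly transcribed RNA, so these quantities
measure biogenesis rather than steady-state abundance. For each gene the
circRNA fraction is the gene's BSJ reads over all nascent reads assigned to
the gene (linear plus backspliced). Genes enter the WT/KO comparison only
when they show both linear splicing and backsplicing in the condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "NascentGeneRecord",
    "NascentDEConfig",
    "nascent_circ_fraction",
    "compare_fractions",
    "classify_nascent_up",
]


@dataclass
class NascentGeneRecord:
    gene_id: str
    total_nascent_reads: dict[str, int] = field(default_factory=dict)
    # (circ_id, sample) -> BSJ reads
    circ_nascent_reads: dict[tuple[str, str], int] = field(default_factory=dict)

    def circ_reads(self, sample: str) -> int:
        return sum(
            v for (cid, s), v in self.circ_nascent_reads.items() if s == sample
        )

    def linear_reads(self, sample: str) -> int:
        return self.total_nascent_reads.get(sample, 0) - self.circ_reads(sample)


@dataclass(frozen=True)
class NascentDEConfig:
    fc_up_nascent: float = 1.4

    def __post_init__(self) -> None:
        if self.fc_up_nascent <= 1:
            raise ValueError("fc_up_nascent must exceed 1")


def nascent_circ_fraction(rec: NascentGeneRecord, sample: str) -> float:
    """Gene's nascent BSJ reads / all nascent reads of the gene, in [0, 1]."""
    total = rec.total_nascent_reads.get(sample, 0)
    if total <= 0:
        raise ValueError(
            f"{rec.gene_id}: no nascent reads in sample {sample!r}; "
            "fraction undefined"
        )
    circ = rec.circ_reads(sample)
    if circ > total:
        raise ValueError(
            f"{rec.gene_id}: circ reads exceed total nascent reads"
        )
    return circ / total


def compare_fractions(
    wt_fracs: Mapping[str, float], ko_fracs: Mapping[str, float]
) -> dict:
    """Two-tailed t-test of per-gene circRNA fractions, WT vs KO.

    Only genes present in both mappings are compared. The test is unpaired
    (Welch-free, pooled variance two-sample t); the report records which
    variant was used.
    """
    shared = sorted(set(wt_fracs) & set(ko_fracs))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genes shared between conditions; need >= 3"
        )
    wt = np.array([wt_fracs[g] for g in shared], dtype=float)
    ko = np.array([ko_fracs[g] for g in shared], dtype=float)
    t, p = stats.ttest_ind(ko, wt)
    return {
        "n_genes": len(shared),
        "mean_wt": float(wt.mean()),
        "mean_ko": float(ko.mean()),
        "mean_difference": float(ko.mean() - wt.mean()),
        "t_statistic": float(t),
        "p_value": float(p),
        "test": "two-tailed unpaired t-test",
        "genes": shared,
    }


def classify_nascent_up(
    fold_changes: Mapping[str, float] | Sequence[float],
    config: NascentDEConfig = NascentDEConfig(),
) -> dict[str, str] | list[str]:
    """Two-way labels on nascent fold changes: "up" iff FC >= threshold.

    The boundary is inclusive (FC exactly at the threshold is "up");
    everything else, including decreased circRNAs, is "non-up".
    """
    thr = config.fc_up_nascent

    def lab(fc: float) -> str:
        return "up" if fc >= thr else "non-up"

    if isinstance(fold_changes, Mapping):
        return {k: lab(v) for k, v in fold_changes.items()}
    return [lab(v) for v in fold_changes]
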