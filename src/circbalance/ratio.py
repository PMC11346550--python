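"""Per-gene circRNA:mRNA ratios and their KO/WT fold-change classes.

A gene's ratio in one condition is (summed circRNA RPM + pc) / (mRNA RPM +
pc); the fold change is the KO ratio over the WT ratio. The printed class
boundaries are applied verbatim: increased when fc > 2, decreased when
fc < 1, unchanged when 1 <= fc <= 2 — so a gene whose circRNA exactly
doubles against an unchanged mRNA sits on the "unchanged" boundary.

Also provides the per-row Z-score normalisation used for nascent expression
heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatioRecord",
    "circ_mrna_ratio",
    "classify_ratio_fc",
    "compute_ratio_records",
    "summarize_ratio_labels",
    "zscore_rows",
]


@dataclass(frozen=True)
class RatioRecord:
    gene_id: str
    circ_norm_wt: float
    mrna_norm_wt: float
    circ_norm_ko: float
    mrna_norm_ko: float
    ratio_wt: float
    ratio_ko: float
    ratio_fc: float  # KO / WT
    label: str  # increased | decreased | unchanged


def circ_mrna_ratio(
    circ_norm: float, mrna_norm: float, pseudocount: float = 0.5
) -> float:
    """(circ RPM + pc) / (mRNA RPM + pc); multi-circRNA genes pass summed RPM."""
    if circ_norm < 0 or mrna_norm < 0:
        raise ValueError("normalised values must be non-negative")
    return (circ_norm + pseudocount) / (mrna_norm + pseudocount)


def classify_ratio_fc(ratio_wt: float, ratio_ko: float) -> tuple[float, str]:
    """KO/WT ratio fold change and its class label.

    increased: fc > 2; decreased: fc < 1; unchanged: 1 <= fc <= 2.
    """
    if ratio_wt <= 0 or ratio_ko <= 0:
        raise ValueError("ratios must be positive")
    fc = ratio_ko / ratio_wt
    if fc > 2:
        label = "increased"
    elif fc < 1:
        label = "decreased"
    else:
        label = "unchanged"
    return fc, label


def compute_ratio_records(
    circ_rpm: Mapping[str, Mapping[str, float]],
    mrna_rpm: Mapping[str, Mapping[str, float]],
    pseudocount: float = 0.5,
) -> list[RatioRecord]:
    """Ratio records for genes quantified in both tables.

    Both arguments map gene_id -> {"WT": rpm, "KO": rpm}; circRNA RPM must
    already be summed over the gene's circRNAs (and averaged over
    replicates).
    """
    out = []
    for gid in sorted(set(circ_rpm) & set(mrna_rpm)):
        cw, ck = circ_rpm[gid]["WT"], circ_rpm[gid]["KO"]
        mw, mk = mrna_rpm[gid]["WT"], mrna_rpm[gid]["KO"]
        rw = circ_mrna_ratio(cw, mw, pseudocount)
        rk = circ_mrna_ratio(ck, mk, pseudocount)
        fc, label = classify_ratio_fc(rw, rk)
        out.append(
            RatioRecord(
                gene_id=gid,
                circ_norm_wt=cw,
                mrna_norm_wt=mw,
                circ_norm_ko=ck,
                mrna_norm_ko=mk,
                ratio_wt=rw,
                ratio_ko=rk,
                ratio_fc=fc,
                label=label,
            )
        )
    return out


def summarize_ratio_labels(records: Sequence[RatioRecord]) -> dict[str, int]:
    counts = {"increased": 0, "decreased": 0, "unchanged": 0}
    for r in records:
        counts[r.label] += 1
    return counts


def zscore_rows(matrix):
    """Row-wise Z-score (population sd): each row to mean 0, sd 1.

    Accepts a 2-D ndarray or DataFrame and returns the same type. A row
    with zero variance is an error naming the row.
    """
    df = isinstance(matrix, pd.DataFrame)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    means = arr.mean(axis=1, keepdims=True)
    sds = arr.std(axis=1, ddof=0, keepdims=True)
    flat = np.where(sds.ravel() == 0)[0]
    if flat.size:
        name = matrix.index[flat[0]] if df else int(flat[0])
        raise ValueError(f"zero-variance row: {name!r}")
    z = (arr - means) / sds
    if df:
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z
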