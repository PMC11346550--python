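"""Steady-state circRNA quantification and fold-change classification.

Detection requires a minimum number of backsplice-junction (BSJ) reads
(default 2). Counts are normalised to reads per million mapped reads (RPM),
replicates are averaged, and circRNAs shared by both conditions are
classified by the KO/WT fold change with inclusive boundaries: up when
FC >= 2, down when FC <= 0.5, unchanged otherwise. A pseudocount keeps the
ratio finite; it enters the fold change only, never the reported RPM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import CircRNA

__all__ = [
    "DEConfig",
    "DEResult",
    "normalize_rpm",
    "detected_set",
    "overlap_sets",
    "classify_de",
    "summarize_de",
    "cumulative_fraction",
]


@dataclass(frozen=True)
class DEConfig:
    min_bsj_reads: int = 2
    fc_up: float = 2.0
    fc_down: float = 0.5
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not (self.fc_up > 1 > self.fc_down > 0):
            raise ValueError("require fc_up > 1 > fc_down > 0")
        if self.min_bsj_reads < 1:
            raise ValueError("min_bsj_reads must be >= 1")


@dataclass(frozen=True)
class DEResult:
    circ_id: str
    norm_wt: float  # RPM, replicate-averaged
    norm_ko: float
    fold_change: float  # (norm_ko + pc) / (norm_wt + pc)
    log2fc: float
    mean_expr: float  # log2 mean of the two pseudocounted RPMs (MA x-axis)
    label: str  # up | down | unchanged


def normalize_rpm(
    counts: Mapping[str, int], library_sizes: Mapping[str, int]
) -> dict[str, float]:
    """Reads per million mapped reads, per sample."""
    out = {}
    for sample, c in counts.items():
        lib = library_sizes[sample]
        if lib <= 0:
            raise ValueError(f"non-positive library size for sample {sample!r}")
        if c < 0:
            raise ValueError(f"negative count for sample {sample!r}")
        out[sample] = c / lib * 1e6
    return out


def detected_set(
    circs: Iterable[CircRNA], sample: str, min_bsj_reads: int = 2
) -> set[str]:
    """circ_ids with at least ``min_bsj_reads`` BSJ reads in ``sample``."""
    out = set()
    for c in circs:
        if sample not in c.counts:
            raise KeyError(f"{c.circ_id}: no count for sample {sample!r}")
        if c.counts[sample] >= min_bsj_reads:
            out.add(c.circ_id)
    return out


def overlap_sets(
    wt: set[str], ko: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """(shared, wt_only, ko_only) — three disjoint sets covering wt | ko."""
    return wt & ko, wt - ko, ko - wt


def classify_de(
    circs: Sequence[CircRNA],
    library_sizes: Mapping[str, int],
    wt_samples: Sequence[str],
    ko_samples: Sequence[str],
    config: DEConfig = DEConfig(),
) -> list[DEResult]:
    """Fold-change classification of circRNAs shared by both conditions.

    Each circRNA's counts are RPM-normalised per sample, averaged within
    condition, and the fold change computed as
    ``(KO + pc) / (WT + pc)``. Labels use the inclusive printed thresholds.
    """
    pc = config.pseudocount
    results = []
    for c in circs:
        wt_rpm = float(
            np.mean(
                [c.counts[s] / library_sizes[s] * 1e6 for s in wt_samples]
            )
        )
        ko_rpm = float(
            np.mean(
                [c.counts[s] / library_sizes[s] * 1e6 for s in ko_samples]
            )
        )
        if wt_rpm < 0 or ko_rpm < 0:
            raise ValueError(f"{c.circ_id}: negative normalised count")
        fc = (ko_rpm + pc) / (wt_rpm + pc)
        if fc >= config.fc_up:
            label = "up"
        elif fc <= config.fc_down:
            label = "down"
        else:
            label = "unchanged"
        results.append(
            DEResult(
                circ_id=c.circ_id,
                norm_wt=wt_rpm,
                norm_ko=ko_rpm,
                fold_change=fc,
                log2fc=math.log2(fc),
                mean_expr=math.log2(((wt_rpm + pc) + (ko_rpm + pc)) / 2),
                label=label,
            )
        )
    return results


def summarize_de(results: Sequence[DEResult]) -> dict:
    """Counts and percentages of differentially expressed circRNAs.

    Percentages are of the DE set (up + down), rounded to one decimal.
    With no DE circRNAs the percentages are NaN (undefined), not zero.
    """
    n_up = sum(1 for r in results if r.label == "up")
    n_down = sum(1 for r in results if r.label == "down")
    n_de = n_up + n_down
    if n_de == 0:
        pct_up = pct_down = float("nan")
    else:
        pct_up = round(100.0 * n_up / n_de, 1)
        pct_down = round(100.0 * n_down / n_de, 1)
    return {
        "n_tested": len(results),
        "n_de": n_de,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": pct_up,
        "pct_down": pct_down,
    }


def cumulative_fraction(values: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical CDF points (value, fraction of values <= value).

    Returns one point per distinct value, non-decreasing and ending at 1.0.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cumulative_fraction of empty input")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values")
    uniq, counts = np.unique(vals, return_counts=True)
    fracs = np.cumsum(counts) / vals.size
    return list(zip(uniq.tolist(), fracs.tolist()))
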