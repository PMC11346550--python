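"""Descriptive figures for a pipeline run.

Every number plotted is re-derivable from the emitted TSVs; the figures are
renderings, not analyses.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["plot_summaries"]


def plot_summaries(outdir: str | Path) -> list[Path]:
    """Render MA, cumulative-fraction, feature-distribution and FI figures.

    Reads the TSVs a pipeline run wrote into ``outdir`` and writes PNGs next
    to them. Returns the list of files written; missing inputs are skipped
    with a warning.
    """
    outdir = Path(outdir)
    written: list[Path] = []

    de_path = outdir / "de_circ.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t")
        if len(de):
            fig, ax = plt.subplots(figsize=(5, 4))
            colors = de["label"].map(
                {"up": "crimson", "down": "royalblue", "unchanged": "grey"}
            )
            ax.scatter(de["mean_expr"], de["log2fc"], s=6, c=colors, alpha=0.6)
            ax.axhline(0, color="black", lw=0.5)
            ax.set_xlabel("log2 mean RPM")
            ax.set_ylabel("log2 fold change (KO/WT)")
            ax.set_title(f"circRNA MA plot (n={len(de)})")
            fig.tight_layout()
            p = outdir / "ma_plot.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

            fig, ax = plt.subplots(figsize=(5, 4))
            for cond, col in (("WT", "norm_wt"), ("KO", "norm_ko")):
                vals = np.sort(np.log2(de[col] + 0.5))
                ax.step(vals, np.arange(1, len(vals) + 1) / len(vals), label=cond)
            ax.set_xlabel("log2 RPM")
            ax.set_ylabel("cumulative fraction")
            ax.set_ylim(0, 1.02)
            ax.legend()
            fig.tight_layout()
            p = outdir / "cumulative_fraction.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        else:
            logger.warning("empty DE table; MA plot skipped")

    comp_path = outdir / "nucleotide_composition.tsv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t").iloc[0]
        fig, ax = plt.subplots(figsize=(4, 3.2))
        ax.bar(comp.index, comp.values, color="teal")
        ax.set_ylabel("frequency in binding peaks")
        fig.tight_layout()
        p = outdir / "nucleotide_composition.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    fi_path = outdir / "fi_profiles_steady.tsv"
    if fi_path.exists():
        fi = pd.read_csv(fi_path, sep="\t")
        if len(fi):
            fi["grp"] = np.where(
                fi["klass"] == "NE", "NE", "circ-E:" + fi["group"].astype(str)
            )
            bound = fi[fi["n_sites"] > 0]
            fig, axes = plt.subplots(1, 3, figsize=(10, 3.4))
            for ax, col, label in zip(
                axes,
                ["length", "n_sites", "total_intensity"],
                ["FI length (bp)", "binding sites per FI", "binding intensity"],
            ):
                groups = sorted(bound["grp"].unique())
                ax.boxplot(
                    [bound.loc[bound["grp"] == g, col] for g in groups],
                    tick_labels=groups,
                )
                ax.set_ylabel(label)
                ax.tick_params(axis="x", rotation=30)
            fig.tight_layout()
            p = outdir / "flanking_introns.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

    ratio_path = outdir / "ratio_records.tsv"
    if ratio_path.exists():
        rr = pd.read_csv(ratio_path, sep="\t")
        if len(rr):
            counts = rr["label"].value_counts()
            fig, ax = plt.subplots(figsize=(4, 3.2))
            order = ["increased", "unchanged", "decreased"]
            ax.bar(
                order,
                [counts.get(k, 0) for k in order],
                color=["crimson", "grey", "royalblue"],
            )
            ax.set_ylabel("genes")
            ax.set_title("circRNA:mRNA ratio fold-change classes")
            fig.tight_layout()
            p = outdir / "ratio_classes.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    return written
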