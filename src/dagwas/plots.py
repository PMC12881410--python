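"""Minimal PNG renderings of the screening diagnostics.

The authoritative outputs are the plot-ready TSV tables written by
``screening_report``; these helpers exist so the CLI can drop quick-look
figures next to them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _savefig(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def plot_manhattan(manhattan: pd.DataFrame, path: str | Path,
                   threshold: float | None = None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks = []
    for i, (chrom, grp) in enumerate(manhattan.groupby("chrom", sort=True)):
        x = offset + np.arange(len(grp))
        ax.scatter(x, grp["neglog10_p"], s=6,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        ticks.append((offset + len(grp) / 2, str(chrom)))
        offset += len(grp)
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=1)
    ax.set_xticks([t for t, _ in ticks])
    ax.set_xticklabels([c for _, c in ticks], fontsize=7)
    ax.set_ylabel(r"$-\log_{10} P$")
    _savefig(fig, path)
    plt.close(fig)


def plot_qq(qq: pd.DataFrame, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(qq["expected_neglog10_p"], qq["observed_neglog10_p"], s=6)
    lim = max(qq["expected_neglog10_p"].max(), qq["observed_neglog10_p"].max())
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    lam = float(qq["lambda_gc"].iloc[0])
    ax.set_title(rf"$\lambda_{{GC}} = {lam:.2f}$")
    ax.set_xlabel("expected")
    ax.set_ylabel("observed")
    _savefig(fig, path)
    plt.close(fig)
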