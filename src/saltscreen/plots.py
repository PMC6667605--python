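"""Figure helpers: treatment box-whisker panels, index regressions, biplot.

All functions draw onto matplotlib axes/figures and can save SVG or PNG;
they are display conveniences over the statistics computed elsewhere
(:func:`saltscreen.stats.boxplot_summary` defines the whisker rule).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless backend; must precede pyplot import

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pca import PCAResult
from .stats import boxplot_summary
from .traits import TREATMENTS


def treatment_boxplot(table: pd.DataFrame, trait: str, path=None):
    """Box-whisker panel of one trait across salinity levels.

    Boxes span Q1-Q3 with the median; whiskers sit at the 5th/95th
    percentiles; points outside the whiskers are drawn as outliers.
    """
    sub = table[table["trait"] == trait]
    groups = {s: sub.loc[sub["treatment"] == s, "value"].to_numpy()
              for s in TREATMENTS if s in set(sub["treatment"])}
    summaries = boxplot_summary(groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    stats = [{
        "label": s, "med": bs.median, "q1": bs.q1, "q3": bs.q3,
        "whislo": bs.p5, "whishi": bs.p95, "fliers": bs.outliers,
    } for s, bs in summaries.items()]
    ax.bxp(stats, showfliers=True)
    ax.set_ylabel(trait)
    ax.set_xlabel("salinity treatment")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def index_regression_panels(scores: pd.DataFrame, path=None):
    """TSSRI against its component sub-indices, with OLS fit and R^2.

    One panel per available sub-index column (category totals, then the
    moderate/high cumulative indices).
    """
    from .stats import regression_r2

    panels = [c for c in scores.columns
              if c.endswith("_total")] + ["cmssri", "chssri"]
    panels = [c for c in panels if c in scores.columns]
    fig, axes = plt.subplots(1, len(panels), figsize=(3.2 * len(panels), 3.2))
    axes = np.atleast_1d(axes)
    for ax, col in zip(axes, panels):
        x = scores[col].to_numpy()
        y = scores["tssri"].to_numpy()
        fit = regression_r2(x, y)
        ax.scatter(x, y, s=12, alpha=0.7)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, fit.slope * xs + fit.intercept, color="k", lw=1)
        ax.set_xlabel(col)
        ax.set_ylabel("TSSRI")
        ax.set_title(f"$R^2$ = {fit.r2:.2f}", fontsize=10)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def biplot(result: PCAResult, classes: pd.Series | None = None, path=None,
           scale_vectors: float = 3.0):
    """PC1 vs PC2 biplot: genotype points, trait loading vectors, quadrant
    shading (upper-right = most tolerant)."""
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = result.scores
    colors = {"sensitive": "#c0392b", "low": "#e67e22",
              "moderate": "#2980b9", "high": "#27ae60"}
    if classes is not None:
        for cls, color in colors.items():
            m = (classes == cls).to_numpy()
            ax.scatter(sc.iloc[m, 0], sc.iloc[m, 1], s=16, color=color, label=cls)
        ax.legend(fontsize=8)
    else:
        ax.scatter(sc.iloc[:, 0], sc.iloc[:, 1], s=16)
    for trait in result.loadings.index:
        lx, ly = result.loadings.loc[trait, ["PC1", "PC2"]] * scale_vectors
        ax.annotate(trait, (lx, ly), fontsize=7)
        ax.plot([0, lx], [0, ly], color="gray", lw=0.6)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    vf = result.variance_fraction
    ax.set_xlabel(f"PC1 ({vf[0]:.0%})")
    ax.set_ylabel(f"PC2 ({vf[1]:.0%})")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
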