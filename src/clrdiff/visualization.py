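"""MW and MA diagnostic plots with significance-based point coloring.

Points are classed, in priority order: expected BH value below the fdr cut
(red), expected p below the p cut (cyan), median clr relative abundance
below the sample geometric mean, i.e. rab_all < 0 (black), everything else
(gray).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


@dataclass(frozen=True)
class PlotStyle:
    p_cut: float = 0.05
    fdr_cut: float = 0.05
    colors: dict = field(
        default_factory=lambda: {
            "significant_fdr": "red",
            "significant_p_only": "cyan",
            "rare_nonsig": "black",
            "abundant_nonsig": "gray",
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.p_cut <= 1:
            raise ValueError("p_cut must lie in (0, 1]")
        if not 0 < self.fdr_cut <= 1:
            raise ValueError("fdr_cut must lie in (0, 1]")


def classify(
    ep: np.ndarray,
    ebh: np.ndarray,
    rab_all: np.ndarray,
    style: PlotStyle = PlotStyle(),
) -> np.ndarray:
    """Assign each feature exactly one class name (pure function)."""
    ep = np.asarray(ep, dtype=float)
    ebh = np.asarray(ebh, dtype=float)
    rab_all = np.asarray(rab_all, dtype=float)
    out = np.full(ep.shape, "abundant_nonsig", dtype=object)
    out[rab_all < 0] = "rare_nonsig"
    out[ep < style.p_cut] = "significant_p_only"
    out[ebh < style.fdr_cut] = "significant_fdr"
    return out


def mw_plot(
    results: pd.DataFrame,
    path: str | Path,
    style: PlotStyle = PlotStyle(),
    stat: str = "welch",
) -> None:
    """Between-condition difference vs within-condition dispersion.

    Dashed identity lines y = +/-x mark equal variation within and between
    conditions.
    """
    _scatter(results, path, style, stat, x_col="diff_win", identity=True)


def ma_plot(
    results: pd.DataFrame,
    path: str | Path,
    style: PlotStyle = PlotStyle(),
    stat: str = "welch",
) -> None:
    """Between-condition difference vs overall median relative abundance."""
    _scatter(results, path, style, stat, x_col="rab_all", identity=False)


def _scatter(
    results: pd.DataFrame,
    path: str | Path,
    style: PlotStyle,
    stat: str,
    x_col: str,
    identity: bool,
) -> None:
    if len(results) == 0:
        raise ValueError("cannot plot an empty result table")
    ep_col, ebh_col = ("we_ep", "we_eBH") if stat == "welch" else ("wi_ep", "wi_eBH")
    classes = classify(
        results[ep_col].to_numpy(),
        results[ebh_col].to_numpy(),
        results["rab_all"].to_numpy(),
        style,
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    x = results[x_col].to_numpy()
    y = results["diff_btw"].to_numpy()
    # draw non-significant classes first so significant points sit on top
    for cls in ("abundant_nonsig", "rare_nonsig", "significant_p_only", "significant_fdr"):
        mask = classes == cls
        if mask.any():
            ax.scatter(x[mask], y[mask], s=6, c=style.colors[cls], label=cls)
    if identity:
        lim = max(np.max(np.abs(x)), np.max(np.abs(y)), 1e-6)
        grid = np.linspace(0, lim, 2)
        ax.plot(grid, grid, "k--", lw=0.8)
        ax.plot(grid, -grid, "k--", lw=0.8)
        ax.set_xlabel("median within-condition difference (log2)")
    else:
        ax.set_xlabel("median clr relative abundance (log2)")
    ax.set_ylabel("median between-condition difference (log2)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
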