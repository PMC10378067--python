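"""Diagnostic and report figures (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .classify import CVReport
from .survival import KMSplitResult

__all__ = ["residual_plots", "roc_band_plot", "km_plot", "scree_plot"]


def residual_plots(resid: np.ndarray, fitted: np.ndarray, path: str | Path, title: str = "") -> Path:
    """QQ plot and residual-vs-fitted panel for one linear-model fit."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    stats.probplot(resid, dist="norm", plot=ax1)
    ax1.set_title("Normal QQ")
    ax2.scatter(fitted, resid, s=10, alpha=0.7)
    ax2.axhline(0.0, color="grey", lw=0.8)
    ax2.set_xlabel("fitted")
    ax2.set_ylabel("residual")
    ax2.set_title("Residual vs fitted")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def roc_band_plot(report: CVReport, path: str | Path) -> Path:
    """Mean cross-validated ROC curve with the empirical 95% band."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lo, hi = report.roc_band
    ax.fill_between(report.roc_grid, lo, hi, alpha=0.25, label="95% band")
    ax.plot(report.roc_grid, report.roc_mean, lw=1.5,
            label=f"mean ROC (AUC={report.mean_auc:.3f})")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def km_plot(split: KMSplitResult, path: str | Path, parameter: str = "PC3") -> Path:
    """Kaplan–Meier curves for the two median-split arms."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, kmf in split.fitters.items():
        kmf.plot_survival_function(ax=ax, ci_show=True)
    ax.set_xlabel("Years from sample collection")
    ax.set_ylabel("Overall survival")
    ax.set_title(f"{parameter} median split (log-rank p={split.logrank_p:.3g})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def scree_plot(explained_fraction: np.ndarray, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    k = len(explained_fraction)
    ax.bar(np.arange(1, k + 1), 100 * np.asarray(explained_fraction))
    ax.set_xlabel("Principal component")
    ax.set_ylabel("% variance explained")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
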