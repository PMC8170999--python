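"""Optional plotting helpers (spectra, Bland-Altman, ROC).

All functions write a figure to ``path`` and return it; they use the Agg
backend so they work headless.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .spectral import Spectrum
from .stats import AgreementReport, ROCReport

__all__ = ["plot_spectra", "plot_bland_altman", "plot_roc"]


def plot_spectra(spectra: dict[str, Spectrum], path):
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, s in spectra.items():
        ax.plot(s.wavelengths, s.intensities, label=label)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_bland_altman(values_a, values_b, report: AgreementReport, path):
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2.0, a - b, s=12, alpha=0.7)
    for y, style in ((report.bias, "-"), (report.loa_low, "--"), (report.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a - b)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_roc(reports: dict[str, ROCReport], path):
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, r in reports.items():
        ax.plot(r.fpr, r.tpr, label=f"{label} (AUC {r.auc:.4f})")
    ax.plot([0, 1], [0, 1], "k:", linewidth=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig
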