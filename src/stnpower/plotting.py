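"""Minimal figures: spectra with bootstrap error bands and forest plots."""

from __future__ import annotations

import numpy as np

from .stats import bootstrap_spectrum_se


def plot_mean_spectrum(spectra, frequencies, ax=None, label=None, color=None,
                       n_boot: int = 1000, seed: int | None = 0):
    """Mean spectrum with a +/-1 bootstrap-SE band on a log power axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    arr = np.atleast_2d(np.asarray(spectra, dtype=float))
    mean = arr.mean(axis=0)
    se = bootstrap_spectrum_se(arr, n_boot=n_boot, seed=seed)
    ax.plot(frequencies, mean, label=label, color=color)
    ax.fill_between(frequencies, mean - se, mean + se, alpha=0.3, color=color)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power")
    ax.set_yscale("log")
    if label:
        ax.legend()
    return ax


def forest_plot(forest_table, ax=None):
    """Per-dataset correlation coefficients with CIs, one row per cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(forest_table) + 1))
    ys = np.arange(len(forest_table))[::-1]
    ax.errorbar(
        forest_table["rho"], ys,
        xerr=[
            forest_table["rho"] - forest_table["ci_low"],
            forest_table["ci_high"] - forest_table["rho"],
        ],
        fmt="o", capsize=2,
    )
    labels = [
        f"{r.dataset} {r.state}/{r.unit}/{r.band}" for r in forest_table.itertuples()
    ]
    ax.set_yticks(ys)
    ax.set_yticklabels(labels, fontsize=7)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("Spearman rho")
    return ax
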