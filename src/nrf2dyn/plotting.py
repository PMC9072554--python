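"""Diagnostic plots: data with one-standard-deviation bands and model overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_fit_overlay"]


def plot_fit_overlay(dataset_records: pd.DataFrame, simulated_log: np.ndarray,
                     sigmas: dict[str, float], out_path: str | Path,
                     title: str = "") -> Path:
    """Per-observable panels: data points and model curve with a +-1 sd band.

    The noise model is log-normal with constant per-target sd, so the band is
    multiplicative: model * exp(+-sigma).
    """
    df = dataset_records.assign(sim=np.exp(np.asarray(simulated_log)))
    names = list(pd.unique(df["observable"]))
    ncol = min(3, len(names))
    nrow = int(np.ceil(len(names) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False)
    for ax, name in zip(axes.flat, names):
        sub = df[df["observable"] == name]
        sig = sigmas.get(name, 0.0)
        for cid, grp in sub.groupby("condition"):
            grp = grp.sort_values("time")
            (line,) = ax.plot(grp["time"], grp["sim"], lw=1.5, label=str(cid))
            ax.fill_between(grp["time"], grp["sim"] * np.exp(-sig),
                            grp["sim"] * np.exp(sig), alpha=0.2,
                            color=line.get_color())
            ax.plot(grp["time"], grp["value"], "o", ms=3,
                    color=line.get_color())
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("time after treatment (h)")
        ax.set_yscale("log")
    for ax in axes.flat[len(names):]:
        ax.set_visible(False)
    if names:
        axes.flat[0].legend(fontsize=6)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
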