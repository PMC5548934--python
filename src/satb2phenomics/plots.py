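"""Figure helpers (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .flip_quant import FlipTrace
from .phenotype_stats import PhenotypeMatrix
from .variant_spectrum import DensityTrack, GeneModel, VariantRecord


def plot_spectrum(variants: list[VariantRecord], track: DensityTrack,
                  g: GeneModel, path) -> None:
    """Lollipop plot of study variants over a population missense-density
    track, with domain intervals shaded."""
    fig, (ax_d, ax_v) = plt.subplots(
        2, 1, figsize=(9, 4), sharex=True,
        gridspec_kw={"height_ratios": [2, 1]})
    ax_d.fill_between(track.positions, track.density, color="steelblue",
                      alpha=0.6)
    ax_d.set_ylabel("population missense density")
    colors = {"missense": "tab:green", "nonsense": "tab:red",
              "frameshift": "tab:purple", "splice_donor": "tab:orange",
              "splice_acceptor": "tab:orange"}
    for v in variants:
        if v.protein_pos is None:
            continue
        y = 1.0 if v.raw_class == "missense" else -1.0
        ax_v.plot([v.protein_pos, v.protein_pos], [0, y],
                  color=colors[v.raw_class], lw=1.5)
        ax_v.plot(v.protein_pos, y, "o", color=colors[v.raw_class], ms=4)
    for ax in (ax_d, ax_v):
        for name, (lo, hi) in g.domains.items():
            ax.axvspan(lo, hi, color="gray", alpha=0.2)
    ax_v.set_ylim(-1.5, 1.5)
    ax_v.set_yticks([-1, 1], ["LoF", "missense"])
    ax_v.set_xlabel("amino acid position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_recovery_curves(traces_by_construct: dict[str, list[FlipTrace]],
                         path) -> None:
    """Mean trace per construct with per-timepoint SD error bars."""
    fig, ax = plt.subplots(figsize=(8, 4))
    for construct, traces in sorted(traces_by_construct.items()):
        stack = np.stack([t.intensity for t in traces])
        t = traces[0].time_s
        mean, sd = stack.mean(axis=0), stack.std(axis=0, ddof=1)
        ax.plot(t, mean, label=construct)
        step = max(1, len(t) // 40)
        ax.errorbar(t[::step], mean[::step], yerr=sd[::step], fmt="none",
                    alpha=0.4, capsize=2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ROI fluorescence (rel. pre-bleach)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_phenotype_heatmap(m: PhenotypeMatrix, counts: pd.Series, path) -> None:
    """Heat map of the recurrent (count >= 2) terms across individuals,
    individuals grouped by mutation class."""
    order = list(m.mutation_class.sort_values(kind="stable").index)
    data = m.values.loc[order, counts.index].to_numpy(float)
    fig, ax = plt.subplots(figsize=(0.45 * len(order) + 2,
                                    0.4 * len(counts) + 2))
    masked = np.ma.masked_invalid(data.T)
    ax.imshow(masked, cmap="Reds", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(order)),
                  [f"{i} ({m.mutation_class[i][0]})" for i in order],
                  rotation=90, fontsize=7)
    ax.set_yticks(range(len(counts)),
                  [f"{t} ({counts[t]})" for t in counts.index], fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
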