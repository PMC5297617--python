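"""Optional figures: per-chromosome positions of significant CA loci."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_genome_scan(frame: pd.DataFrame, chrom_lengths: dict[str, int], path=None):
    """Scatter significant loci along chromosomes, one row per chromosome,
    coloured by favorable/unfavorable sign.  ``frame`` is
    :attr:`hybridca.association.ScanResults.frame`."""
    sig = frame[frame["significant"]]
    chroms = list(chrom_lengths)
    fig, ax = plt.subplots(figsize=(9, 0.45 * len(chroms) + 1.5))
    for i, c in enumerate(chroms):
        ax.hlines(i, 0, chrom_lengths[c] / 1e6, color="0.8", lw=4, zorder=1)
        sub = sig[sig["chrom"] == c]
        for sign, color in (("favorable", "tab:green"), ("unfavorable", "tab:red")):
            pts = sub[sub["sign_class"] == sign]
            ax.scatter(pts["pos"] / 1e6, [i] * len(pts), s=14, color=color, zorder=2, label=sign)
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (Mb)")
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    if seen:
        ax.legend(seen.values(), seen.keys(), loc="upper right", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
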