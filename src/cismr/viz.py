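"""Plot helpers: effect heatmap, bi-directional Manhattan, PheWAS scatter."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .downstream import EffectMatrix, PhewasTable, euclidean_cluster  # noqa: E402

__all__ = ["plot_effect_heatmap", "plot_bidirectional_manhattan",
           "plot_phewas"]


def plot_effect_heatmap(matrix: EffectMatrix, path) -> None:
    """Clustered heatmap of standardized MR effects (genes x traits)."""
    _, row_order, col_order = euclidean_cluster(matrix)
    df = matrix.to_frame().loc[row_order, col_order]
    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * len(col_order), 2 + 0.25 * len(row_order)))
    vmax = np.nanmax(np.abs(df.to_numpy())) or 1.0
    im = ax.imshow(df.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(len(col_order)), col_order, rotation=90)
    ax.set_yticks(range(len(row_order)), row_order, fontsize=6)
    fig.colorbar(im, ax=ax, label="standardized MR beta")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bidirectional_manhattan(primary, proxy, path,
                                 threshold_primary: float = None,
                                 threshold_proxy: float = None) -> None:
    """Mirrored -log10(p) per gene: primary tissue up, proxy tissue down.

    ``primary`` and ``proxy`` are DataFrames with columns exposure_id, pval
    (and optionally pos for the x ordering).
    """
    fig, ax = plt.subplots(figsize=(10, 4))
    x1 = np.arange(len(primary))
    ax.scatter(x1, -np.log10(primary["pval"]), s=8, color="purple",
               label="primary tissue")
    prox = proxy.set_index("exposure_id").reindex(primary["exposure_id"])
    ax.scatter(x1, np.log10(prox["pval"]), s=8, color="firebrick",
               label="proxy tissue")
    if threshold_primary:
        ax.axhline(-np.log10(threshold_primary), ls="--", lw=0.8, color="gray")
    if threshold_proxy:
        ax.axhline(np.log10(threshold_proxy), ls="--", lw=0.8, color="gray")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("gene")
    ax.set_ylabel(r"$\pm\log_{10}(p)$")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_phewas(table: PhewasTable, path) -> None:
    """Signed -log10(p) per outcome with the phenome-wide threshold."""
    rows = table.rows.sort_values("outcome_id").reset_index(drop=True)
    y = -np.log10(rows["pval"]) * np.sign(rows["beta"])
    fig, ax = plt.subplots(figsize=(8, 4))
    colors = np.where(rows["flagged"], "crimson", "steelblue")
    ax.scatter(range(len(rows)), y, s=10, c=colors)
    thr = -np.log10(table.bonferroni_threshold)
    ax.axhline(thr, ls="--", lw=0.8, color="gray")
    ax.axhline(-thr, ls="--", lw=0.8, color="gray")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("outcome")
    ax.set_ylabel(r"signed $-\log_{10}(p)$")
    ax.set_title(f"{table.gene_id}: {table.pleiotropy_count} outcomes below "
                 f"p = {table.bonferroni_threshold:.2e}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
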