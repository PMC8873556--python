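"""Optional diagnostic plots (requires matplotlib, installed via the 'plot' extra)."""

from __future__ import annotations

import numpy as np


def plot_k_scan(report, path=None):
    """Three-panel k-scan: inertia (with knee), mean silhouette, Davies-Bouldin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    ks = list(report.k_values)
    axes[0].plot(ks, report.inertia, "o-")
    if report.knee_k is not None:
        axes[0].axvline(report.knee_k, ls="--", c="gray")
    axes[0].set(title="Inertia", xlabel="k")
    axes[1].plot(ks, report.silhouette_mean, "o-")
    axes[1].set(title="Mean silhouette", xlabel="k")
    axes[2].plot(ks, report.davies_bouldin, "o-")
    axes[2].set(title="Davies-Bouldin", xlabel="k")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_pca(projection, labels, path=None):
    """Scatter of the 2-d projection, one marker per cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for marker, c in zip("o^sxD*", np.unique(labels)):
        pts = projection.coordinates[labels == c]
        ax.scatter(pts[:, 0], pts[:, 1], marker=marker, s=12, label=f"cluster {c + 1}")
    ev = projection.explained_variance_pct
    ax.set_xlabel(f"pca-one ({ev[0]:.2f}%)")
    ax.set_ylabel(f"pca-two ({ev[1]:.2f}%)" if len(ev) > 1 else "pca-two")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
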