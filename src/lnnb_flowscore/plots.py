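"""Optional plots: agreement scatter with linear trend, ROC with band."""

from __future__ import annotations

import numpy as np

from .validation import ROCResult, RocBand


def plot_agreement(conv, img, task_id: int, r: float, out_path: str) -> None:
    """Scatter of conventional vs image-derived scores with a linear trend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conv = np.asarray(conv, dtype=float)
    img = np.asarray(img, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(conv, img, s=18, color="k", alpha=0.7)
    slope, intercept = np.polyfit(conv, img, 1)
    xs = np.linspace(conv.min(), conv.max(), 50)
    ax.plot(xs, slope * xs + intercept, "k-")
    ax.set_xlabel("conventional score (count)")
    ax.set_ylabel("image-derived score (degree/s)")
    ax.set_title(f"Task {task_id}: r = {r:.2f}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_roc(roc: ROCResult, band: RocBand | None, task_id: int, out_path: str) -> None:
    """ROC curve with optional bootstrap band and the chance diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    if band is not None:
        ax.fill_between(
            band.fpr_grid, band.tpr_low, band.tpr_high, color="0.8",
            label=f"{int(band.level * 100)}% band",
        )
    ax.plot(1.0 - roc.specificity, roc.sensitivity, "k-", label=f"AUC = {roc.auc:.2f}")
    ax.plot([0, 1], [0, 1], color="0.5", ls="--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"Task {task_id}")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
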