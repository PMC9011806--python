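"""Optional figures: per-frame error curves and fitted logistic latencies."""

from __future__ import annotations

import numpy as np


def plot_error_curves(summaries: dict, path, protocol=None) -> None:
    """Mean absolute heading error per frame for every condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for label, s in summaries.items():
        ax.plot(s["mean_error_per_frame"], label=label)
    if protocol is not None:
        for start in protocol.analysis_windows():
            ax.axvline(start, ls="--", c="gray", lw=0.6)
            ax.axvline(start + protocol.transition_frames, ls="--", c="gray", lw=0.6)
    ax.set_xlabel("frame")
    ax.set_ylabel("mean absolute heading error (deg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_logistics(summaries: dict, path, n_frames: int = 33) -> None:
    """Averaged normalized-error logistic curve per condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(n_frames)
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, s in summaries.items():
        fit = s["logistic"]
        ax.plot(t, fit(t), label=f"{label} (conv {fit.convergence_frame:.1f})")
        ax.axvline(fit.convergence_frame, ls=":", lw=0.8)
    ax.set_xlabel("frame since transition onset")
    ax.set_ylabel("normalized heading error")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
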