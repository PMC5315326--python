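"""Trajectory and summary figures."""

from __future__ import annotations

import numpy as np

from .cue_world import PATTERNS
from .learner import TrajectoryRecord

__all__ = ["plot_trajectory"]


def plot_trajectory(trajectory: TrajectoryRecord, ax=None):
    """Response-vs-epoch curves for all 16 patterns.

    The legend lists patterns by final response, descending, so its order
    matches the vertical stacking of the curves at the right edge.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    final = trajectory.responses[-1]
    order = np.argsort(final)[::-1]
    for i in order:
        ax.plot(trajectory.epochs, trajectory.responses[:, i], label=PATTERNS[i].label)
    ax.set_xlabel("epoch")
    ax.set_ylabel("response")
    ax.set_ylim(0, 1)
    ax.set_title("Responses to the 16 cue patterns during training")
    ax.legend(fontsize=7, ncol=2, loc="center left", bbox_to_anchor=(1.0, 0.5))
    ax.figure.tight_layout()
    return ax
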