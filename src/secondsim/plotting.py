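"""Minimal diagnostic plots: session stacking and across-session densities."""

from __future__ import annotations

import numpy as np

from .simulate import SessionRecord
from .validation import KLD_VARIABLES, kde_estimate, reference_beta


def session_stacking_plot(record: SessionRecord, ax=None):
    """Stacked blocks showing when each member plays other-directed.

    Bottom band: child other-directed; top band: parent other-directed.  Two
    stacked blocks mean joint play, a single block an initiation attempt, and
    no blocks both playing alone.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2))
    minutes = np.arange(record.n_steps) * record.step_seconds / 60.0
    ax.fill_between(minutes, 0, record.child_behavior, step="post",
                    alpha=0.8, label="child other-directed")
    ax.fill_between(minutes, 1, 1 + record.parent_behavior, step="post",
                    alpha=0.8, label="parent other-directed")
    ax.set_xlabel("session time (min)")
    ax.set_yticks([])
    ax.legend(loc="upper right", fontsize="small")
    return ax


def density_comparison_plot(rows_by_label, null_means=None, axes=None):
    """KDEs of the six time-allocation variables for several dyads.

    ``rows_by_label`` maps a label to a per-session summary table (percent
    columns); the beta reference density is drawn in black when ``null_means``
    is given.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
    axes = np.asarray(axes).ravel()
    for ax, var in zip(axes, KLD_VARIABLES):
        for label, rows in rows_by_label.items():
            est = kde_estimate(rows[var].to_numpy(dtype=float) / 100.0)
            ax.plot(est.grid * 100, est.density / 100, label=label)
        if null_means is not None:
            ref = reference_beta(null_means[var])
            ax.plot(ref.grid * 100, ref.density / 100, "k-", lw=1,
                    label="beta reference")
        ax.set_title(var)
        ax.set_xlabel("% of session time")
    axes[0].legend(fontsize="small")
    return axes
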