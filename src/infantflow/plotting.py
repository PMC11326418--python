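"""Quick-look plots for trajectory fits and alignment curves."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_trajectory_fit", "plot_alignment_trajectory"]


def plot_trajectory_fit(age, y, fit=None, segmented_fit=None, ax=None):
    """Scatter CBF against age with fitted curve overlays.

    ``fit`` is a :class:`~infantflow.trajectory.ModelFit` (its fitted
    values are drawn against age); ``segmented_fit`` a
    :class:`~infantflow.segmented.SegmentedResults` whose piecewise
    prediction is drawn on a fine grid.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    age = np.asarray(age, dtype=float)
    order = np.argsort(age)
    ax.scatter(age, y, s=14, alpha=0.6, color="0.3", label="subjects")
    if fit is not None:
        ax.plot(age[order], np.asarray(fit.fitted)[order], color="crimson",
                label=f"{fit.family} fit (r={fit.r:.2f})")
    if segmented_fit is not None:
        grid = np.linspace(age.min(), age.max(), 300)
        ax.plot(grid, segmented_fit.predict(grid), color="navy",
                label=f"segmented ({segmented_fit.n_breakpoints} bp)")
        for psi in segmented_fit.psi:
            ax.axvline(psi, ls="--", color="navy", alpha=0.4)
    ax.set_xlabel("age (months)")
    ax.set_ylabel("CBF (ml/100g/min)")
    ax.legend(frameon=False)
    return ax


def plot_alignment_trajectory(ages, r_curve, breakpoint=None, ax=None):
    """Correlation-with-reference curve across the fitted age stack."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ages, r_curve, color="teal")
    if breakpoint is not None:
        ax.axvline(breakpoint, ls="--", color="0.5")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("Pearson r with reference map")
    ax.set_ylim(min(0, np.min(r_curve)) - 0.05, 1.02)
    return ax
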