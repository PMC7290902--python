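"""Convenience plots for sweep results (requires matplotlib)."""

from __future__ import annotations

from .experiments import SweepResult

__all__ = ["plot_sweep"]


def plot_sweep(result: SweepResult, x_key: str, ax=None, **line_kwargs):
    """Plot ensemble mean prevalence (with +-1 SE band) against one swept
    fraction; infeasible points are skipped."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = result.feasible_points()
    xs = [p.params[x_key] for p in pts]
    ys = [p.ensemble.x_mean for p in pts]
    ses = [p.ensemble.x_se for p in pts]
    (line,) = ax.plot(xs, ys, marker="o", **line_kwargs)
    ax.fill_between(
        xs,
        [y - s for y, s in zip(ys, ses)],
        [y + s for y, s in zip(ys, ses)],
        alpha=0.2,
        color=line.get_color(),
    )
    ax.set_xlabel(x_key)
    ax.set_ylabel("mean prevalence $\\bar{x}$")
    return ax
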