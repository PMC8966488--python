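"""Optional diagnostic plots (matplotlib): equilibrium curves over B with
simulated estimates overlaid.  CSV tables are the primary artifact; these
panels exist for eyeballing sweeps."""

from __future__ import annotations

import pandas as pd

_STYLE = {"ssv": dict(color="tab:blue", label="small slope variance"),
          "wm_cv": dict(color="tab:green", label="weak mismatch, constant variance"),
          "wm_ssv": dict(color="tab:red", label="weak mismatch, small slope variance"),
          "numeric_full": dict(color="black", ls="--", label="numeric (exact)")}


def plot_equilibrium_curves(curves: pd.DataFrame, sim_table: pd.DataFrame | None = None,
                            axes=None):
    """Two stacked panels (equilibrium intercept and slope vs B).

    ``curves`` comes from :func:`plastinorm.equilibria.equilibrium_curve`;
    ``sim_table`` optionally from a simulator sweep (columns ``value``,
    ``mu_i_hat``, ``mu_b_hat``).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 7))
    for trait, ax in zip(("mu_i_star", "mu_b_star"), axes):
        for method, grp in curves.groupby("method"):
            grp = grp.sort_values("B")
            ax.plot(grp["B"], grp[trait], **_STYLE.get(method, {"label": method}))
        if sim_table is not None:
            col = "mu_i_hat" if trait == "mu_i_star" else "mu_b_hat"
            est = sim_table.groupby("value")[col].mean()
            ax.plot(est.index, est.to_numpy(), "o", color="0.3", label="simulation")
        ax.set_ylabel({"mu_i_star": r"$\mu_i^*$ (days)",
                       "mu_b_star": r"$\mu_b^*$"}[trait])
    axes[1].set_xlabel("B (days per nutrition unit)")
    handles, labels = axes[0].get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    axes[0].legend(uniq.values(), uniq.keys(), fontsize=8)
    return axes
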