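"""Matplotlib views: tornado diagram, CE plane scatter, acceptability curves."""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_survival(results, ax=None):
    """Calibrated PFS survival curves for both arms."""
    ax = _ax(ax)
    structure = results.bundle.structure
    months = np.linspace(0, structure.horizon_years * 12.0, 400)
    for arm, wp in results.weibull.items():
        ax.plot(months, wp.survival(months), label=arm)
    ax.axhline(0.5, ls=":", color="grey", lw=0.8)
    ax.set_xlabel("months")
    ax.set_ylabel("progression-free survival")
    ax.legend()
    return ax


def plot_tornado(tornado_df, base_icer: float | None = None, ax=None, top: int = 10):
    """Horizontal bars of ICER spread, widest at the top."""
    ax = _ax(ax)
    df = tornado_df[~tornado_df["unstable"]].head(top).iloc[::-1]
    lo = np.minimum(df["icer_low"], df["icer_high"])
    hi = np.maximum(df["icer_low"], df["icer_high"])
    ax.barh(df["parameter"], hi - lo, left=lo, color="steelblue")
    if base_icer is not None:
        ax.axvline(base_icer, color="black", lw=1)
    ax.set_xlabel("ICER (USD/QALY)")
    return ax


def plot_ce_plane(psa, ax=None, wtp: float | None = None):
    """Incremental cost vs incremental QALY scatter (CG minus erlotinib)."""
    ax = _ax(ax)
    s = psa.samples
    ax.scatter(s["delta_qaly"], s["delta_cost"], s=6, alpha=0.5)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    wtp = psa.wtp.wtp_threshold if wtp is None else wtp
    q = np.linspace(*ax.get_xlim(), 50)
    ax.plot(q, wtp * q, ls="--", color="firebrick", lw=0.8,
            label=f"WTP {wtp:.0f} USD/QALY")
    ax.set_xlabel("incremental QALYs (CG - erlotinib)")
    ax.set_ylabel("incremental cost, USD (CG - erlotinib)")
    ax.legend()
    return ax


def plot_ceac(psa, ax=None):
    """Probability each strategy is cost-effective across WTP thresholds."""
    ax = _ax(ax)
    curve = psa.ceac()
    ax.plot(curve["wtp"], curve["p_erlotinib"], label="erlotinib")
    ax.plot(curve["wtp"], curve["p_cg"], label="CG")
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax
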