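"""Optional plotting helpers over the pipeline's figure-data CSVs.

The core contract is CSV data layers (KM curve, CE plane, CEAC); these
helpers render them with matplotlib for quick inspection.
"""

from __future__ import annotations

import pandas as pd


def plot_km(km_csv, ax=None):
    """Step plot of the recurrence-free survival curves per arm."""
    import matplotlib.pyplot as plt

    df = pd.read_csv(km_csv)
    ax = ax or plt.gca()
    for arm, sub in df.groupby("arm"):
        ax.step(sub["time"], sub["survival"], where="post", label=arm)
    ax.set_xlabel("months since intervention")
    ax.set_ylabel("recurrence-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_ce_plane(plane_csv, ax=None):
    """Scatter of (ΔQALY, ΔCost) Monte Carlo draws."""
    import matplotlib.pyplot as plt

    df = pd.read_csv(plane_csv)
    ax = ax or plt.gca()
    ax.scatter(df["delta_qaly"], df["delta_cost"], s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (CNY)")
    return ax


def plot_ceac(ceac_csv, ax=None):
    """Cost-effectiveness acceptability curve."""
    import matplotlib.pyplot as plt

    df = pd.read_csv(ceac_csv)
    ax = ax or plt.gca()
    ax.plot(df["wtp_cny_per_qaly"], df["probability"])
    ax.set_xlabel("willingness to pay (CNY per QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1.02)
    return ax
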