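"""Plot helpers: calibrated curves, trace occupancy, sensitivity tornado."""

from __future__ import annotations

import numpy as np

from .cohort import CohortTrace
from .sensitivity import SensitivityGrid


def plot_cumulative_incidence(curves, horizon: int = 72, ax=None):
    """Calibrated vaginal-delivery cumulative incidence, one line per
    (arm, parity); `curves` as returned by calibrate_from_config."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(0, horizon, 4 * horizon + 1)
    for arm, strata in curves.items():
        for parity, curve in strata.items():
            ax.plot(t, 100 * curve.cdf(t), label=f"{arm} {parity}")
    ax.set_xlabel("hours since induction")
    ax.set_ylabel("vaginal deliveries (%)")
    ax.legend()
    return ax


def plot_trace(trace: CohortTrace, ax=None):
    """Stacked state occupancy over time for one stratum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    occ = trace.occupancy[["pre_active", "active_stage1", "active_stage2",
                           "inpatient", "discharged"]]
    ax.stackplot(occ.index, occ.T.values, labels=occ.columns)
    ax.set_xlabel("cycle (h)")
    ax.set_ylabel("expected women")
    ax.set_title(f"{trace.profile.arm} / {trace.profile.parity}")
    ax.legend(loc="center right", fontsize="small")
    return ax


def plot_tornado(grid: SensitivityGrid, ax=None):
    """Tornado-style view of shift savings across one-way perturbations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = grid.table[grid.table["label"] != "base"]
    ax.barh(tab["label"], tab["delta_shifts_saved_vs_base"])
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("change in midwife shifts saved vs base case")
    return ax
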