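"""Optional matplotlib views of profiles, depth curves and DVHs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_lateral_profile", "plot_depth_curves", "plot_dvh"]


def plot_lateral_profile(profile, ax=None):
    """Lateral dose profile with detected peaks and valleys marked."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.positions, profile.dose, lw=0.8)
    ax.plot(profile.peak_positions, profile.peak_doses, "v", ms=4, label="peaks")
    ax.plot(profile.valley_positions, profile.valley_doses, "^", ms=4,
            label="valleys")
    ax.set_xlabel("modulation axis x [mm]")
    ax.set_ylabel("dose [a.u.]")
    ax.set_title(f"depth {profile.depth:g} mm")
    ax.legend()
    return ax


def plot_depth_curves(curves: dict, ax=None, ylabel="dose [a.u.]"):
    """Overlay named :class:`DepthCurve` objects."""
    if ax is None:
        _, ax = plt.subplots()
    for name, c in curves.items():
        ax.plot(c.depths, c.values, label=name)
    ax.set_xlabel("depth below skin [mm]")
    ax.set_ylabel(ylabel)
    ax.legend()
    return ax


def plot_dvh(dvh_table, ax=None):
    """DVH curves from the long-format table of a metrics bundle."""
    if ax is None:
        _, ax = plt.subplots()
    for (plan, structure), sub in dvh_table.groupby(["plan", "structure"]):
        ax.plot(sub.dose, 100 * sub.volume_fraction, label=f"{plan}/{structure}")
    ax.set_xlabel("dose (normalized to mean PTV dose)")
    ax.set_ylabel("volume [%]")
    ax.legend(fontsize=7)
    return ax
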