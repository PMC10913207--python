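"""Minimal matplotlib views of portraits and paired responses."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_phase_portrait", "plot_paired_response"]


def plot_phase_portrait(pp, path, title: str = "") -> None:
    """Quiver field, trajectories and equilibria in the (y, z) plane."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    Y, Z = np.meshgrid(pp.grid_y, pp.grid_z)
    U, V = pp.field[:, :, 0], pp.field[:, :, 1]
    norm = np.hypot(U, V)
    norm[norm == 0] = 1.0
    ax.quiver(Y, Z, U / norm, V / norm, angles="xy", color="0.7", width=0.003)
    for traj in pp.trajectories:
        if traj is not None:
            ax.plot(traj.states[:, 0], traj.states[:, 1], lw=0.5, color="C4", alpha=0.6)
    for eq, marker in zip(pp.equilibria, ("x", "o")):
        ax.plot(eq.y, eq.z, marker, color="red", ms=8)
    ax.set_xlabel("y")
    ax.set_ylabel("z")
    ax.set_xlim(pp.grid_y[0], pp.grid_y[-1])
    ax.set_ylim(pp.grid_z[0], pp.grid_z[-1])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_paired_response(report, path) -> None:
    """Output difference of a paired invariance run against time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(report.times, report.output_diff, "g--", lw=1)
    ax.axhline(0.0, color="0.8", lw=0.5)
    p1, p2 = report.value_pair
    ax.set_xlabel("t")
    ax.set_ylabel(r"$y_1(t) - y_2(t)$")
    ax.set_title(
        f"{report.parameter_name}: {p1} vs {p2} -> {report.verdict.value} "
        f"(max |dy| = {report.max_abs_output_diff:.2e})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
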