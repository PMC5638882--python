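"""Plotting helpers: 3D trajectory with orientation, intensity traces."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_trajectory_3d", "plot_intensity_trace"]


def plot_trajectory_3d(df, ax=None, orientation_every: int = 0, stick_nm: float = 80.0):
    """3D trajectory coloured by time, optionally with orientation sticks.

    ``df`` needs columns ``x_nm, y_nm, z_nm`` (and ``phi_deg, psi_deg`` when
    ``orientation_every > 0``, which draws the rod axis every that many
    frames as a stick of length ``stick_nm``).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    x, y, z = df["x_nm"], df["y_nm"], df["z_nm"]
    ax.scatter(x, y, z, c=np.arange(len(df)), cmap="viridis", s=4)
    if orientation_every > 0:
        for i in range(0, len(df), orientation_every):
            phi = np.deg2rad(df["phi_deg"].iloc[i])
            psi = np.deg2rad(df["psi_deg"].iloc[i])
            u = np.array(
                [np.sin(psi) * np.cos(phi), np.sin(psi) * np.sin(phi), np.cos(psi)]
            )
            p0 = np.array([x.iloc[i], y.iloc[i], z.iloc[i]])
            seg = np.stack([p0 - u * stick_nm / 2, p0 + u * stick_nm / 2])
            ax.plot(seg[:, 0], seg[:, 1], seg[:, 2], c="crimson", lw=1)
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.set_zlabel("z (nm)")
    return ax


def plot_intensity_trace(t, b, d, segments=None, ax=None):
    """Bright/dark intensity traces with optional active/quiet shading.

    ``segments`` is the data frame from activity segmentation (columns
    ``start``, ``end``, ``state``); quiet periods are shaded.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t, b, color="tab:blue", lw=0.8, label="bright")
    ax.plot(t, d, color="saddlebrown", lw=0.8, label="dark")
    if segments is not None:
        for _, row in segments.iterrows():
            if row["state"] == "quiet":
                ax.axvspan(t[row["start"]], t[row["end"] - 1], alpha=0.15, color="gray")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("intensity (counts)")
    ax.legend(frameon=False, fontsize=8)
    return ax
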