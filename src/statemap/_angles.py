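"""Small circular-arithmetic helpers (degrees in, degrees out)."""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_360", "wrap_180", "circ_dist", "circ_mean"]


def wrap_360(angles):
    """Wrap angles into [0, 360)."""
    return np.asarray(angles, dtype=float) % 360.0


def wrap_180(angles):
    """Wrap angles into (-180, 180]."""
    w = (np.asarray(angles, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(np.isclose(w, -180.0), 180.0, w)
    return w if w.ndim else float(w)


def circ_dist(a, b):
    """Absolute circular distance between two angles, in [0, 180]."""
    return np.abs(wrap_180(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def circ_mean(angles_deg):
    """Circular mean of angles, reported in (-180, 180]."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    mean = np.angle(np.exp(1j * rad).mean())
    return float(wrap_180(np.rad2deg(mean)))
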