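"""Built-in 10-20/10-10 electrode layout.

2-D positions come from the standard azimuthal-equidistant ("top-down")
projection of the idealised spherical 10-20 layout: each electrode has a
polar angle theta (degrees from the vertex Cz) and an azimuth phi (degrees,
0 = towards the nasion, positive to the right).  x = sin(phi') * theta/90,
y = cos(phi') * theta/90, so Cz sits at the origin and the head rim is the
unit circle.  These conventional coordinates are sufficient for topographic
interpolation and for generating smooth synthetic scalp maps; no individual
digitisation is modelled.
"""

from __future__ import annotations

import numpy as np

# (theta from vertex, phi from nasion, clockwise positive) in degrees.
_ANGLES: dict[str, tuple[float, float]] = {
    "FP1": (92, -18), "FPz": (92, 0), "FP2": (92, 18),
    "F7": (92, -54), "F3": (60, -39), "Fz": (46, 0), "F4": (60, 39), "F8": (92, 54),
    "FC5": (72, -69), "FC3": (50, -62), "FC1": (32, -45),
    "FCz": (23, 0),
    "FC2": (32, 45), "FC4": (50, 62), "FC6": (72, 69),
    "T7": (92, -90), "C5": (69, -90), "C3": (46, -90), "C1": (23, -90),
    "Cz": (0, 0),
    "C2": (23, 90), "C4": (46, 90), "C6": (69, 90), "T8": (92, 90),
    "CP5": (72, -111), "CP3": (50, -118), "CP1": (32, -135),
    "CPz": (23, 180),
    "CP2": (32, 135), "CP4": (50, 118), "CP6": (72, 111),
    "P7": (92, -126), "P3": (60, -141), "Pz": (46, 180), "P4": (60, 141), "P8": (92, 126),
    "PO7": (92, -144), "PO3": (74, -157), "POz": (69, 180), "PO4": (74, 157), "PO8": (92, 144),
    "O1": (92, -162), "Oz": (92, 180), "O2": (92, 162),
}

#: 28-channel montage used by default throughout the package (FP1 ... O2),
#: mirroring a typical ERP lab cap.
DEFAULT_28 = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4", "T7", "C3", "Cz", "C4", "T8",
    "CP3", "CPz", "CP4", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "POz", "PO8", "O1", "O2",
)


def channel_positions(channel_names) -> np.ndarray:
    """Return (n_channels, 2) x/y positions on the unit head disc.

    Raises ``KeyError`` listing every unknown channel name.
    """
    unknown = [ch for ch in channel_names if ch not in _ANGLES]
    if unknown:
        raise KeyError(f"unknown channel name(s): {unknown}; known: {sorted(_ANGLES)}")
    pos = np.empty((len(channel_names), 2))
    for i, ch in enumerate(channel_names):
        theta, phi = _ANGLES[ch]
        r = theta / 92.0  # rim electrodes (theta=92) on the unit circle
        a = np.deg2rad(phi)
        pos[i] = (r * np.sin(a), r * np.cos(a))
    return pos
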