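"""Standard polar (azimuthal equidistant) projection baseline.

This is the conventional whole-array flattening: centre the sensor cloud on
its own centroid, pick a superior axis from the cloud itself, map polar
angle to 2D radius and preserve azimuth, then rescale so the outermost
sensor sits on the unit circle.  By construction the result depends on
*which* sensors are present -- the property the anatomical projection is
designed to fix.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .projection import Layout2D, SensorLocation2D, _sensor_table


def polar_projection(sensors, rotation: np.ndarray | None = None) -> Layout2D:
    """Azimuthal-equidistant 2D layout of a labelled sensor set.

    Parameters
    ----------
    sensors
        DataFrame with label/x/y/z columns, or mapping label -> xyz (mm).
    rotation
        Optional (3, 3) rotation applied to all positions first (the manual
        'centre and rotate' adjustment conventional tools require).
    """
    df = _sensor_table(sensors)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    if rotation is not None:
        pos = pos @ np.asarray(rotation, dtype=float).T
    if len(pos) < 3:
        raise InputError("polar projection needs at least 3 sensors")

    centred = pos - pos.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        raise InputError("sensors are collinear; polar projection undefined")

    # superior axis: principal direction of the cloud closest to +z
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    zhat = np.array([0.0, 0.0, 1.0])
    axis = vt[int(np.argmax(np.abs(vt @ zhat)))]
    if axis @ zhat < 0:
        axis = -axis

    u3 = axis
    u1 = np.array([1.0, 0.0, 0.0]) - (np.array([1.0, 0.0, 0.0]) @ u3) * u3
    if np.linalg.norm(u1) < 1e-9:
        u1 = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ u3) * u3
    u1 = u1 / np.linalg.norm(u1)
    u2 = np.cross(u3, u1)

    r = np.linalg.norm(centred, axis=1)
    safe_r = np.where(r > 0, r, 1.0)
    polar = np.arccos(np.clip(centred @ u3 / safe_r, -1.0, 1.0))
    polar = np.where(r > 0, polar, 0.0)
    azimuth = np.arctan2(centred @ u2, centred @ u1)

    rmax = polar.max()
    if rmax <= 0:
        raise InputError("degenerate sensor cloud: all sensors on the polar axis")
    rho = polar / rmax

    channels = {}
    for label, rr, az in zip(df["label"], rho, azimuth):
        channels[label] = SensorLocation2D.from_polar(label, float(rr), float(np.rad2deg(az)))
    return Layout2D(channels=channels)
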