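"""Group-statistics pipeline over 2D topographies.

Per subject: interpolate per-channel scalars onto a raster over the head
circle, z-score within subject; across subjects: per-pixel one-sample t
statistics.  Channel-subselection experiments (random 'sparse' removal or
peak-neighbourhood 'focal' arrays) drive the comparison between anatomical
and polar projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .errors import GeometryError, InputError
from .grid1020 import build_grid
from .mesh import build_head_mesh, project_to_scalp
from .polar import polar_projection
from .projection import Layout2D, make_layout
from .synthetic import Subject, make_field

#: raster half-width: the grid spans [-EXTENT, EXTENT]^2 and pixels outside
#: the circle of radius EXTENT are masked
EXTENT = 1.2
DEFAULT_RESOLUTION = 67


@dataclass
class TopoImage:
    """Square raster of interpolated channel values over the head circle."""

    grid: np.ndarray  # NaN where masked
    mask: np.ndarray
    resolution: int
    extent: float = EXTENT

    def valid_values(self) -> np.ndarray:
        return self.grid[self.mask]


@dataclass
class GroupStatMap:
    """Per-pixel one-sample t statistics across subjects."""

    t: np.ndarray  # NaN where masked
    n_effective: np.ndarray
    mask: np.ndarray
    resolution: int
    extent: float = EXTENT

    def mean_abs_t(self) -> float:
        return float(np.mean(np.abs(self.t[self.mask])))

    def mean_t(self) -> float:
        return float(np.mean(self.t[self.mask]))


def _pixel_axes(resolution: int, extent: float = EXTENT):
    ax = np.linspace(-extent, extent, resolution)
    return np.meshgrid(ax, ax, indexing="xy")


def interpolate_topo(
    layout: Layout2D,
    values,
    resolution: int = DEFAULT_RESOLUTION,
) -> TopoImage:
    """Delaunay-linear interpolation of per-channel values onto the raster.

    ``values`` maps channel label -> scalar and must cover every layout
    channel.  Pixels outside the convex hull of the channel positions, or
    outside the plot circle, are masked (NaN).
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    missing = [l for l in layout.labels if l not in values]
    if missing:
        raise InputError(f"values missing for channels: {missing}")
    if len(layout) < 3:
        raise InputError("need at least 3 channels to interpolate")
    pts = layout.xy
    vals = np.array([float(values[l]) for l in layout.labels])
    try:
        interp = LinearNDInterpolator(pts, vals)
    except QhullError as exc:
        raise GeometryError(f"channel positions are degenerate (collinear?): {exc}") from exc
    xx, yy = _pixel_axes(resolution)
    grid = interp(np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    inside_circle = xx**2 + yy**2 <= EXTENT**2
    mask = np.isfinite(grid) & inside_circle
    grid = np.where(mask, grid, np.nan)
    return TopoImage(grid=grid, mask=mask, resolution=resolution)


def zscore_image(img: TopoImage) -> TopoImage:
    """Within-subject z-scoring over all valid pixels (population sd)."""
    vals = img.valid_values()
    if vals.size < 2:
        raise InputError("need at least 2 valid pixels to z-score")
    mu = float(vals.mean())
    sd = float(vals.std())  # population sd; a sample-sd variant only rescales
    if sd <= 1e-15 * max(abs(mu), 1.0):
        raise InputError("zero spread: z-score undefined")
    grid = (img.grid - mu) / sd
    grid = np.where(img.mask, grid, np.nan)
    return TopoImage(grid=grid, mask=img.mask.copy(), resolution=img.resolution, extent=img.extent)


def group_t_map(images: list[TopoImage]) -> GroupStatMap:
    """Pixelwise one-sample t across subjects (sample sd, ddof=1).

    A pixel contributes only for subjects where it is valid; pixels with
    fewer than 2 contributing subjects, or zero variance, are masked.
    """
    if len(images) < 2:
        raise InputError("need at least 2 images for a group map")
    res = images[0].resolution
    if any(im.resolution != res for im in images):
        raise InputError("images must share one raster resolution")
    data = np.stack([im.grid for im in images])
    valid = np.stack([im.mask for im in images])
    n_eff = valid.sum(axis=0)
    if not np.any(n_eff >= 2):
        raise GeometryError("no pixel is valid in at least 2 subjects")
    import warnings

    stacked = np.where(valid, data, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu = np.nanmean(stacked, axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=1)
        t = mu / (sd / np.sqrt(n_eff))
    mask = (n_eff >= 2) & np.isfinite(t) & (sd > 0)
    t = np.where(mask, t, np.nan)
    return GroupStatMap(t=t, n_effective=n_eff, mask=mask, resolution=res, extent=images[0].extent)


def subselect_channels(
    labels,
    positions: np.ndarray,
    n_keep: int,
    mode: str,
    values=None,
    seed: int | None = None,
) -> list[str]:
    """Pick a channel subset.

    ``sparse``: seeded random removal, one channel at a time, so subsets are
    nested across decreasing ``n_keep``.  ``focal``: the peak-value channel
    plus its ``n_keep - 1`` nearest neighbours in 3D.
    """
    labels = list(labels)
    n = len(labels)
    if n_keep < 1:
        raise InputError("n_keep must be >= 1")
    if n_keep > n:
        raise InputError(f"n_keep={n_keep} exceeds the {n} available channels")
    if mode == "sparse":
        rng = np.random.default_rng(seed)
        removal_order = rng.permutation(n)
        removed = set(removal_order[: n - n_keep].tolist())
        return [l for i, l in enumerate(labels) if i not in removed]
    if mode == "focal":
        if values is None:
            raise InputError("focal subselection needs per-channel values")
        if isinstance(values, pd.Series):
            vals = values.reindex(labels).to_numpy(dtype=float)
        else:
            vals = np.array([float(values[l]) for l in labels])
        positions = np.asarray(positions, dtype=float)
        peak = int(np.argmax(vals))
        d = np.linalg.norm(positions - positions[peak], axis=1)
        keep = np.argsort(d, kind="stable")[:n_keep]
        return [labels[i] for i in sorted(keep)]
    raise InputError(f"unknown mode {mode!r}")


def run_comparison(
    subjects: list[Subject],
    target_directions: dict[str, np.ndarray],
    n_keep_schedule,
    modes=("sparse", "focal"),
    methods=("anatomical", "polar"),
    sigma: float = 40.0,
    resolution: int = DEFAULT_RESOLUTION,
    seed: int = 0,
    signed: bool = False,
) -> pd.DataFrame:
    """Full projection-method comparison on a synthetic cohort.

    For each (method, mode, n_keep, target): per-subject subset layout and
    z-scored topography, then the across-subject t-map and its mean |t|
    (or signed mean t with ``signed=True``) over valid pixels.

    Returns a tidy table with columns method, mode, n_keep, target, mean_t.
    """
    if len(subjects) < 2:
        raise InputError("need at least 2 subjects")
    n_keep_schedule = list(n_keep_schedule)
    if not n_keep_schedule:
        raise InputError("empty n_keep schedule")

    # per-subject precomputation: mesh, grid, full anatomical layout, fields
    prepared = []
    for subj in subjects:
        mesh = build_head_mesh(subj.scan)
        grid = build_grid(mesh, subj.scan.fiducials)
        full_layout = make_layout(subj.scan, subj.sensors, grid=grid)
        pos3d = subj.sensors[["x", "y", "z"]].to_numpy(dtype=float)
        fields = {}
        for name, direction in target_directions.items():
            d = np.asarray(direction, dtype=float)
            d = d / np.linalg.norm(d)
            d_subj = subj.rotation @ d
            target = project_to_scalp(mesh.origin + d_subj * mesh.bbox_diagonal, mesh)
            fields[name] = make_field(mesh, subj.sensors, target, sigma=sigma)
        prepared.append(
            {
                "subject": subj,
                "labels": subj.sensors["label"].tolist(),
                "pos3d": pos3d,
                "layout_full": full_layout,
                "fields": fields,
            }
        )

    # per-subject sparse removal sequences (shared across targets/n_keep so
    # subsets are nested)
    sparse_seeds = [
        int(s.generate_state(1)[0])
        for s in np.random.SeedSequence(seed).spawn(len(subjects))
    ]

    rows = []
    for mode in modes:
        for target_name in target_directions:
            for n_keep in n_keep_schedule:
                per_method_images: dict[str, list[TopoImage]] = {m: [] for m in methods}
                for si, prep in enumerate(prepared):
                    labels = prep["labels"]
                    keep = subselect_channels(
                        labels,
                        prep["pos3d"],
                        n_keep,
                        mode,
                        values=prep["fields"][target_name],
                        seed=sparse_seeds[si],
                    )
                    vals = prep["fields"][target_name][keep]
                    for method in methods:
                        if method == "anatomical":
                            # exact subset independence: reuse the full layout
                            lay = prep["layout_full"].subset(keep)
                        elif method == "polar":
                            sub = prep["subject"].sensors
                            lay = polar_projection(sub[sub["label"].isin(keep)])
                        else:
                            raise InputError(f"unknown method {method!r}")
                        img = zscore_image(interpolate_topo(lay, vals, resolution=resolution))
                        per_method_images[method].append(img)
                for method in methods:
                    stat = group_t_map(per_method_images[method])
                    mean_t = stat.mean_t() if signed else stat.mean_abs_t()
                    rows.append(
                        {
                            "method": method,
                            "mode": mode,
                            "n_keep": int(n_keep),
                            "target": target_name,
                            "mean_t": mean_t,
                        }
                    )
    return pd.DataFrame(rows)
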