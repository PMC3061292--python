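"""Conversion of sensor data to NIfTI summary-statistic images.

Scalp maps are built by Delaunay triangulation of the good-channel 2D
layout positions and barycentric (piecewise-linear) interpolation;
pixels outside the convex hull are missing (NaN).  Stacking one map per
time frame yields a 3D space x space x time image; averaging over a
time window first yields a 2D spatial image.

Layout coordinates live on the unit head disc; for physically meaningful
smoothing kernels the disc radius is mapped to a nominal 100 mm, and
the time axis keeps its native ms sampling, so kernels are specified in
[mm x mm x ms] for space-time images and [Hz x ms] for time-frequency
images.  Missing pixels ("holes" from removed bad channels) are
excluded from the smoothing kernel mass and persist through smoothing
and, downstream, through the statistical analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, cKDTree

from topostat.core_data import (
    IMAGING_TYPES,
    AveragedDataset,
    ChannelLayout2D,
    EpochedDataset,
    validate_dataset,
)

#: Nominal physical scale of the unit layout disc, mm.
LAYOUT_SCALE_MM = 100.0

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class ImageGrid:
    """Regular pixel grid over the 2D layout bounding box (+5% margin)."""

    n_pixels: int = 64
    bounds: tuple[float, float, float, float] = None  # (x0, x1, y0, y1)

    def __post_init__(self):
        if self.n_pixels < 8:
            raise ValueError("grid needs at least 8 pixels per dimension")

    @classmethod
    def for_layout(cls, layout: ChannelLayout2D, n_pixels: int = 64,
                   margin: float = 0.05) -> "ImageGrid":
        pos = layout.positions2d
        x0, y0 = pos.min(axis=0)
        x1, y1 = pos.max(axis=0)
        mx, my = margin * (x1 - x0), margin * (y1 - y0)
        return cls(n_pixels, (x0 - mx, x1 + mx, y0 - my, y1 + my))

    @property
    def pixel_size(self) -> tuple[float, float]:
        x0, x1, y0, y1 = self.bounds
        return ((x1 - x0) / self.n_pixels, (y1 - y0) / self.n_pixels)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, x1, y0, y1 = self.bounds
        px, py = self.pixel_size
        xs = x0 + px * (np.arange(self.n_pixels) + 0.5)
        ys = y0 + py * (np.arange(self.n_pixels) + 0.5)
        return xs, ys


@dataclass
class StatImage:
    """A 2D/3D image with physical axis metadata and optional field info.

    ``axis_units`` names each dimension's physical unit (e.g.
    ``("mm", "mm", "ms")`` or ``("Hz", "ms")``); ``axis_scales`` are the
    voxel sizes in those units; ``axis_origins`` the physical coordinate
    of voxel 0 along each dimension.  Statistical maps also carry
    ``field`` ("t", "F" or "gaussian") and degrees of freedom.
    """

    data: np.ndarray
    axis_units: tuple[str, ...]
    axis_scales: tuple[float, ...]
    axis_origins: tuple[float, ...] = None
    field: str | None = None
    dof: tuple[float, ...] | None = None
    provenance: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim > 3:
            raise ValueError("images are limited to 3 dimensions or less")
        if len(self.axis_units) != self.data.ndim or len(self.axis_scales) != self.data.ndim:
            raise ValueError("axis metadata must cover every dimension")
        if self.axis_origins is None:
            self.axis_origins = (0.0,) * self.data.ndim
        self.axis_units = tuple(self.axis_units)
        self.axis_scales = tuple(float(s) for s in self.axis_scales)
        self.axis_origins = tuple(float(o) for o in self.axis_origins)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    # -- NIfTI round trip ------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.eye(4)
        for i, (sc, og) in enumerate(zip(self.axis_scales, self.axis_origins)):
            affine[i, i] = sc
            affine[i, 3] = og
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(self.axis_scales)
        descr = "topostat " + "x".join(self.axis_units)
        if self.field:
            dof = ",".join(f"{d:g}" for d in (self.dof or ()))
            descr += f" field={self.field} dof={dof}"
        img.header["descrip"] = descr.encode()[:79]
        return img

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path, axis_units: tuple[str, ...] | None = None) -> "StatImage":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        data = np.squeeze(data)
        scales = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        origins = tuple(float(img.affine[i, 3]) for i in range(data.ndim))
        descr = bytes(img.header["descrip"]).decode(errors="ignore").strip("\x00")
        units = axis_units
        if units is None:
            toks = descr.split()
            units = tuple(toks[1].split("x")) if len(toks) > 1 and "x" in toks[1] \
                else ("mm",) * data.ndim
        fieldtype = None
        dof = None
        for tok in descr.split():
            if tok.startswith("field="):
                fieldtype = tok[6:]
            if tok.startswith("dof="):
                dof = tuple(float(v) for v in tok[4:].split(",") if v)
        return cls(data, units, scales, origins, field=fieldtype, dof=dof)


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def interpolate_scalp_map(
    values: np.ndarray,
    layout: ChannelLayout2D,
    grid: ImageGrid | None = None,
    bad_channels: np.ndarray | None = None,
    bad_channel_mode: str = "interpolate",
) -> np.ndarray:
    """Linear (barycentric) interpolation of channel values onto a grid.

    Good channels are Delaunay-triangulated; each in-hull pixel is a
    barycentric combination of its triangle's vertices, out-of-hull
    pixels are NaN.  With ``bad_channel_mode="interpolate"`` bad
    channels are simply left out of the triangulation; with ``"remove"``
    every pixel whose nearest channel is bad additionally becomes NaN,
    leaving a hole (distance ties go to the good channel).
    """
    values = np.asarray(values, dtype=float)
    pos = layout.positions2d
    if grid is None:
        grid = ImageGrid.for_layout(layout)
    if bad_channels is None:
        bad_channels = np.zeros(pos.shape[0], dtype=bool)
    bad_channels = np.asarray(bad_channels, dtype=bool)
    if bad_channel_mode not in ("interpolate", "remove"):
        raise ValueError("bad_channel_mode must be 'interpolate' or 'remove'")
    good = ~bad_channels
    gp = pos[good]
    if gp.shape[0] < 3:
        raise ValueError("need at least 3 good channels to interpolate")
    # collinearity makes Delaunay degenerate; detect via singular values
    s = np.linalg.svd(gp - gp.mean(axis=0), compute_uv=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("good channels are collinear; cannot triangulate")
    tri = Delaunay(gp)
    interp = LinearNDInterpolator(tri, values[good], fill_value=np.nan)
    xs, ys = grid.pixel_centers()
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    img = interp(np.column_stack([X.ravel(), Y.ravel()])).reshape(X.shape)
    if bad_channel_mode == "remove" and bad_channels.any():
        tree_all = cKDTree(pos)
        d_all, idx_all = tree_all.query(np.column_stack([X.ravel(), Y.ravel()]))
        tree_good = cKDTree(gp)
        d_good, _ = tree_good.query(np.column_stack([X.ravel(), Y.ravel()]))
        # ties in favour of the good channel (less masking)
        hole = bad_channels[idx_all] & (d_all < d_good - 1e-12)
        img.ravel()[hole] = np.nan
    return img


def _image_axes(grid: ImageGrid) -> tuple[tuple[float, float], tuple[float, float]]:
    """Pixel sizes and origins in nominal mm for a layout grid."""
    px, py = grid.pixel_size
    x0, _, y0, _ = grid.bounds
    scales = (px * LAYOUT_SCALE_MM, py * LAYOUT_SCALE_MM)
    origins = ((x0 + px / 2) * LAYOUT_SCALE_MM, (y0 + py / 2) * LAYOUT_SCALE_MM)
    return scales, origins


def _stack_frames(
    frames: np.ndarray,  # (n_channels, n_time)
    layout: ChannelLayout2D,
    grid: ImageGrid,
    bad: np.ndarray,
    mode: str,
    dt_ms: float,
    t0_ms: float,
    provenance: dict,
) -> StatImage:
    maps = [
        interpolate_scalp_map(frames[:, k], layout, grid, bad, mode)
        for k in range(frames.shape[1])
    ]
    vol = np.stack(maps, axis=-1)
    (sx, sy), (ox, oy) = _image_axes(grid)
    return StatImage(
        vol, ("mm", "mm", "ms"), (sx, sy, dt_ms), (ox, oy, t0_ms),
        provenance=provenance,
    )


def dataset_to_volumes(
    ds: EpochedDataset | AveragedDataset,
    out_dir: str | Path,
    grid: ImageGrid | None = None,
    bad_channel_mode: str = "interpolate",
    modality: str | None = None,
    name: str | None = None,
) -> list[dict]:
    """Export a dataset to per-condition NIfTI volumes (space x space x time).

    A directory named after the dataset is created with one
    subdirectory per condition.  Averaged input yields a single 3D image
    per condition; epoched input yields one image per non-rejected
    trial.  Mixed imaging modalities must be disambiguated with
    ``modality``.  Returns the manifest: one dict per written file with
    condition, trial index and path.
    """
    out_dir = Path(out_dir)
    if isinstance(ds, EpochedDataset):
        rep = validate_dataset(ds)
        if not rep.ok:
            raise ValueError(f"dataset invalid: {rep.violations}")
    types_present = sorted(
        {t for t in ds.channel_types if t in IMAGING_TYPES}
    )
    if modality is None:
        if len(types_present) > 1:
            raise ValueError(
                f"dataset mixes modalities {types_present}; pass modality="
            )
        if not types_present:
            raise ValueError("no imaging channels (EEG/MEG) in dataset")
        modality = types_present[0]
    sel = np.array([i for i, t in enumerate(ds.channel_types) if t == modality])
    if sel.size == 0:
        raise ValueError(f"no channels of modality {modality!r}")
    sub_layout = ChannelLayout2D(ds.layout.positions2d[sel])
    bad_sub = np.asarray(ds.bad_channels, dtype=bool)[sel]
    if grid is None:
        grid = ImageGrid.for_layout(sub_layout)
    name = name or "dataset"
    root = out_dir / name
    root.mkdir(parents=True, exist_ok=True)
    t0 = float(ds.time_axis[0])
    manifest: list[dict] = []
    if isinstance(ds, AveragedDataset):
        for k, cond in enumerate(ds.condition_order):
            cdir = root / _safe(cond)
            cdir.mkdir(exist_ok=True)
            img = _stack_frames(
                ds.data[k][sel], sub_layout, grid, bad_sub, bad_channel_mode,
                ds.dt_ms, t0, {"condition": cond},
            )
            path = img.save(cdir / "average.nii")
            manifest.append({"condition": cond, "trial": None, "path": str(path)})
    else:
        for cond in ds.conditions:
            cdir = root / _safe(cond)
            cdir.mkdir(exist_ok=True)
            for j, tr in enumerate(ds.retained_trial_indices(cond)):
                img = _stack_frames(
                    ds.data[tr][sel], sub_layout, grid, bad_sub,
                    bad_channel_mode, ds.dt_ms, t0,
                    {"condition": cond, "trial": int(tr)},
                )
                path = img.save(cdir / f"trial{j:04d}.nii")
                manifest.append(
                    {"condition": cond, "trial": int(tr), "path": str(path)}
                )
    return manifest


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in label) or "cond"


def average_time_window_image(
    ds: EpochedDataset | AveragedDataset,
    window_ms: tuple[float, float],
    grid: ImageGrid | None = None,
    condition: str | None = None,
    bad_channel_mode: str = "interpolate",
) -> StatImage:
    """Average channel data over a known time window, then interpolate once.

    Produces a 2D spatial image — the summary of choice when the peak
    latency of an ERP/ERF component is known in advance.
    """
    t1, t2 = window_ms
    keep = (ds.time_axis >= min(t1, t2)) & (ds.time_axis <= max(t1, t2))
    if not keep.any():
        raise ValueError("time window does not intersect the epoch")
    if isinstance(ds, AveragedDataset):
        conds = ds.condition_order
        k = conds.index(condition) if condition is not None else 0
        chan = ds.data[k][:, keep].mean(axis=1)
        bad = ds.bad_channels
    else:
        idx = ds.retained_trial_indices(condition)
        chan = ds.data[idx][:, :, keep].mean(axis=(0, 2))
        bad = ds.bad_channels
    sel = np.array([i for i, t in enumerate(ds.channel_types) if t in IMAGING_TYPES])
    sub_layout = ChannelLayout2D(ds.layout.positions2d[sel])
    if grid is None:
        grid = ImageGrid.for_layout(sub_layout)
    img = interpolate_scalp_map(
        chan[sel], sub_layout, grid, np.asarray(bad, bool)[sel], bad_channel_mode
    )
    (sx, sy), (ox, oy) = _image_axes(grid)
    return StatImage(img, ("mm", "mm"), (sx, sy), (ox, oy))


def combine_planar_rms(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Combine paired planar gradiometers: sqrt((g1^2 + g2^2) / 2) per location."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("planar gradiometer pair arrays must have equal shape")
    return np.sqrt((g1**2 + g2**2) / 2.0)


def pair_planar_channels(channel_names: list[str], channel_types: list[str]):
    """Group MEGPLANAR channels into location pairs by shared name stem.

    Names are expected to encode the location plus an orientation suffix
    (e.g. ``MEG0112``/``MEG0113``: common stem, distinct last character).
    Raises if any planar channel is left unpaired.
    """
    planar = [i for i, t in enumerate(channel_types) if t == "MEGPLANAR"]
    stems: dict[str, list[int]] = {}
    for i in planar:
        stems.setdefault(channel_names[i][:-1], []).append(i)
    pairs = []
    for stem, idx in stems.items():
        if len(idx) != 2:
            raise ValueError(f"unpaired planar channel(s) at location {stem!r}")
        pairs.append(tuple(idx))
    return pairs


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def gaussian_smooth_image(
    img: StatImage, fwhm: tuple[float, ...] | dict[str, float]
) -> StatImage:
    """Separable Gaussian smoothing with physical-unit kernel sizes.

    ``fwhm`` gives the kernel FWHM per dimension in the image's own axis
    units (mm/ms/Hz); a dict keyed by unit name is also accepted.  The
    kernel is truncated at 4 sigma.  Missing voxels contribute no mass
    and stay missing: the convolution is masked and renormalized by the
    smoothed mask, which also renormalizes at the image border.
    """
    if isinstance(fwhm, dict):
        missing = set(fwhm) - set(img.axis_units)
        if missing:
            raise ValueError(f"fwhm given for absent dimension(s): {sorted(missing)}")
        fwhm = tuple(fwhm.get(u, 0.0) for u in img.axis_units)
    fwhm = tuple(float(f) for f in fwhm)
    if len(fwhm) != img.data.ndim:
        raise ValueError("fwhm must specify one value per image dimension")
    if any(f < 0 for f in fwhm):
        raise ValueError("fwhm must be >= 0")
    sigmas = [f * FWHM_TO_SIGMA / sc for f, sc in zip(fwhm, img.axis_scales)]
    data = img.data
    valid = np.isfinite(data)
    filled = np.where(valid, data, 0.0)
    sm = ndimage.gaussian_filter(filled, sigma=sigmas, mode="constant",
                                 cval=0.0, truncate=4.0)
    mass = ndimage.gaussian_filter(valid.astype(float), sigma=sigmas,
                                   mode="constant", cval=0.0, truncate=4.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sm / mass
    out[~valid] = np.nan
    return StatImage(
        out, img.axis_units, img.axis_scales, img.axis_origins,
        field=img.field, dof=img.dof, provenance=dict(img.provenance),
    )
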