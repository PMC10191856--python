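"""Extraction of transcription-site intensity traces from time-lapse movies.

Pipeline: xy-drift correction on the maximum-intensity projection, Otsu +
watershed cell segmentation, then per-cell spot detection and iterative
2D Gaussian-mask photometry with a detection-tier cascade:

* ``primary``  — brightest local maximum above 6x the background s.d.;
* ``fallback`` — retry near previously detected positions at 4x;
* ``carried-over`` — quantify at the last known position (no detection).

The end of each trace is set automatically to the last frame with a primary
or fallback detection; cells with no detection in any frame are flagged
``no_ts`` and excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import ransac, regionprops
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed
from skimage.transform import AffineTransform, warp

from .photometry import gaussian_mask_2d

__all__ = [
    "ImageStack",
    "CellMask",
    "IntensityTrace",
    "TIER_PRIMARY",
    "TIER_FALLBACK",
    "TIER_CARRIED",
    "drift_correct",
    "segment_cells",
    "quantify_ts",
    "traces_to_frame",
    "save_label_mask",
]

TIER_PRIMARY = "primary-6sd"
TIER_FALLBACK = "fallback-4sd"
TIER_CARRIED = "carried-over"


@dataclass
class ImageStack:
    """Time-lapse stack indexed (t[, z], y, x)."""

    data: np.ndarray
    frame_interval: float = 15.0  # seconds
    pixel_size: float | None = None  # micron

    def __post_init__(self) -> None:
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (t, y, x) or (t, z, y, x)")
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def max_project(self) -> np.ndarray:
        """Per-frame maximum-intensity projection over z (no-op for 2D+t)."""
        return self.data if self.data.ndim == 3 else self.data.max(axis=1)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, np.asarray(self.data, dtype=np.float32))

    @classmethod
    def from_tiff(cls, path, frame_interval: float = 15.0) -> "ImageStack":
        import tifffile

        return cls(data=tifffile.imread(path), frame_interval=frame_interval)


@dataclass
class CellMask:
    labels: np.ndarray  # integer label image, background = 0

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def bounding_boxes(self) -> dict:
        return {p.label: p.bbox for p in regionprops(self.labels)}


@dataclass
class IntensityTrace:
    cell_id: int
    intensity: np.ndarray           # a.u., per frame
    x: np.ndarray                   # sub-pixel TS position per frame
    y: np.ndarray
    tier: np.ndarray                # object array of tier strings
    end_frame: int                  # last frame with primary/fallback detection
    no_ts: bool = False
    frame_interval: float = 15.0    # seconds

    @property
    def n_frames(self) -> int:
        return len(self.intensity)


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def _estimate_affine(ref: np.ndarray, mov: np.ndarray) -> AffineTransform | None:
    """ORB-feature + RANSAC affine estimate; None when features are too few."""
    from skimage.feature import ORB, match_descriptors

    try:
        orb = ORB(n_keypoints=200, fast_threshold=0.05)
        orb.detect_and_extract(ref)
        k_ref, d_ref = orb.keypoints, orb.descriptors
        orb.detect_and_extract(mov)
        k_mov, d_mov = orb.keypoints, orb.descriptors
    except (RuntimeError, ValueError):
        return None
    matches = match_descriptors(d_ref, d_mov, cross_check=True)
    if len(matches) < 6:
        return None
    src = k_mov[matches[:, 1]][:, ::-1]
    dst = k_ref[matches[:, 0]][:, ::-1]
    model, inliers = ransac(
        (src, dst), AffineTransform, min_samples=3, residual_threshold=2, max_trials=200
    )
    if model is None or inliers is None or inliers.sum() < 4:
        return None
    return model


def drift_correct(stack: ImageStack, mode: str = "translation", upsample: int = 20):
    """Register every frame to frame 0 on the max-intensity projection.

    ``mode='translation'`` uses sub-pixel phase correlation (stage drift is
    translational); ``mode='affine'`` estimates a full affine transform from
    matched ORB features, falling back to translation per frame when feature
    matching fails.  Frames are resampled by linear interpolation.

    Returns ``(registered ImageStack, offsets)`` where offsets is an
    (n_frames, 2) array of (dy, dx) shifts applied.
    """
    if stack.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    proj = stack.max_project()
    ref = proj[0]
    out = np.array(stack.data, dtype=float, copy=True)
    offsets = np.zeros((stack.n_frames, 2))
    if ref.std() == 0:
        warnings.warn("featureless reference frame: identity transform used")
        return ImageStack(out, stack.frame_interval, stack.pixel_size), offsets

    for t in range(1, stack.n_frames):
        if proj[t].std() == 0:
            warnings.warn(f"featureless frame {t}: identity transform used")
            continue
        if mode == "affine":
            model = _estimate_affine(ref, proj[t])
            if model is not None:
                offsets[t] = model.translation[::-1]
                if stack.data.ndim == 3:
                    out[t] = warp(out[t], model, order=1, preserve_range=True)
                else:
                    for z in range(out.shape[1]):
                        out[t, z] = warp(out[t, z], model, order=1, preserve_range=True)
                continue
        shift, _, _ = phase_cross_correlation(ref, proj[t], upsample_factor=upsample)
        offsets[t] = shift
        if stack.data.ndim == 3:
            out[t] = ndi.shift(out[t], shift, order=1, mode="nearest")
        else:
            out[t] = ndi.shift(out[t], (0, *shift), order=1, mode="nearest")
    return ImageStack(out, stack.frame_interval, stack.pixel_size), offsets


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _drop_small(fg: np.ndarray, min_area: int) -> np.ndarray:
    lab, n = ndi.label(fg)
    if n == 0:
        return fg
    counts = np.bincount(lab.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[lab]


def segment_cells(
    reference_image: np.ndarray,
    min_area: int = 100,
    min_peak_distance: int = 10,
    log_compress: bool = True,
) -> CellMask:
    """Otsu threshold + distance-transform watershed segmentation.

    ``reference_image`` is typically the time-averaged max projection.  The
    threshold is computed on a log-compressed copy (``log_compress``) so
    that the small, very bright TS spots cannot dominate Otsu's
    between-class variance and push the threshold above the cell-body
    level.  Touching cells are split at the watershed between
    distance-transform peaks; objects smaller than ``min_area`` pixels are
    dropped.
    """
    img = np.asarray(reference_image, dtype=float)
    if img.max() == img.min():
        warnings.warn("blank reference image: empty mask")
        return CellMask(np.zeros(img.shape, dtype=np.int32))
    work = np.log1p(img - img.min()) if log_compress else img
    fg = work > threshold_otsu(work)
    fg = _drop_small(fg, min_area)
    if not fg.any():
        warnings.warn("empty foreground after Otsu threshold")
        return CellMask(np.zeros(img.shape, dtype=np.int32))
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_peak_distance, labels=fg)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    labels = watershed(-dist, markers, mask=fg)
    # drop fragments below min_area, relabel contiguously from 1
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_area]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return CellMask(remap[labels])


# ---------------------------------------------------------------------------
# TS quantification
# ---------------------------------------------------------------------------

def _local_maxima(img: np.ndarray) -> np.ndarray:
    return img == ndi.maximum_filter(img, size=3)


def quantify_ts(
    stack: ImageStack,
    masks: CellMask,
    bg_sd,
    psf_sigma: float = 1.5,
    primary_factor: float = 6.0,
    fallback_factor: float = 4.0,
    fallback_radius: float = 5.0,
    end_frame_override: dict | None = None,
) -> list:
    """Quantify one TS intensity trace per segmented cell.

    ``bg_sd`` is the per-pixel background s.d. (scalar, or mapping
    cell label -> value).  Detection operates on the per-frame max
    projection after subtracting each cell's median (the cell body level);
    photometry is 2D on the same projection.  ``end_frame_override`` maps
    cell labels to manually curated endpoints, replacing the automatic
    last-detection rule.
    """
    proj = stack.max_project()
    n_frames = stack.n_frames
    labels = masks.labels
    cell_ids = [int(i) for i in np.unique(labels) if i > 0]

    def sd_of(cid: int) -> float:
        return float(bg_sd[cid]) if isinstance(bg_sd, dict) else float(bg_sd)

    traces = []
    for cid in cell_ids:
        sel = labels == cid
        ys, xs = np.nonzero(sel)
        sd = sd_of(cid)
        intensity = np.zeros(n_frames)
        px = np.full(n_frames, np.nan)
        py = np.full(n_frames, np.nan)
        tier = np.array([TIER_CARRIED] * n_frames, dtype=object)
        last_pos: tuple | None = None
        last_detect = -1
        for t in range(n_frames):
            frame = proj[t]
            vals = frame[ys, xs]
            baseline = float(np.median(vals))
            resid = vals - baseline
            cand = None
            is_max = _local_maxima(frame)[ys, xs]
            ok = is_max & (resid > primary_factor * sd)
            if ok.any():
                # brightest qualifying maximum; ties -> lowest (y, x)
                best = np.flatnonzero(ok)[np.lexsort((xs[ok], ys[ok], -resid[ok]))[0]]
                cand = (ys[best], xs[best], TIER_PRIMARY)
            elif last_pos is not None:
                near = (ys - last_pos[0]) ** 2 + (xs - last_pos[1]) ** 2 <= fallback_radius**2
                ok = is_max & near & (resid > fallback_factor * sd)
                if ok.any():
                    best = np.flatnonzero(ok)[np.lexsort((xs[ok], ys[ok], -resid[ok]))[0]]
                    cand = (ys[best], xs[best], TIER_FALLBACK)
            if cand is not None:
                fit = gaussian_mask_2d(frame, cand[0], cand[1], psf_sigma)
                intensity[t] = fit.intensity
                py[t], px[t] = fit.pos
                tier[t] = cand[2]
                last_pos = (fit.pos[0], fit.pos[1])
                last_detect = t
            elif last_pos is not None:
                fit = gaussian_mask_2d(frame, last_pos[0], last_pos[1], psf_sigma, fixed_position=True)
                intensity[t] = fit.intensity
                py[t], px[t] = last_pos
        no_ts = last_detect < 0
        if not no_ts:
            # frames before the first detection: measure at the first detected site
            first = int(np.flatnonzero(tier != TIER_CARRIED)[0])
            for t in range(first):
                fit = gaussian_mask_2d(proj[t], py[first], px[first], psf_sigma, fixed_position=True)
                intensity[t] = fit.intensity
                py[t], px[t] = py[first], px[first]
        end = last_detect
        if end_frame_override and cid in end_frame_override:
            end = int(end_frame_override[cid])
        traces.append(
            IntensityTrace(
                cell_id=cid,
                intensity=intensity,
                x=px,
                y=py,
                tier=tier,
                end_frame=end,
                no_ts=no_ts,
                frame_interval=stack.frame_interval,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def traces_to_frame(traces) -> "object":
    """Long-format table of quantified traces:
    cell_id, frame, time_s, intensity, tier, x, y."""
    import pandas as pd

    rows = []
    for t in traces:
        for f in range(t.n_frames):
            rows.append(
                (t.cell_id, f, f * t.frame_interval, t.intensity[f],
                 t.tier[f], t.x[f], t.y[f])
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "frame", "time_s", "intensity", "tier", "x", "y"]
    )


def save_label_mask(mask: CellMask, path) -> None:
    """Write a cell mask as a 16-bit label TIFF."""
    import tifffile

    tifffile.imwrite(path, mask.labels.astype(np.uint16))
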