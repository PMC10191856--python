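"""smFISH quantification: nascent-RNA counting at the transcription site and
DAPI-based cell-cycle classification.

Per cell, the transcription site (TS) is the brightest nuclear spot; its
intensity is converted to a nascent-RNA count by dividing by the median
intensity of the cytoplasmic single RNAs pooled over all cells.  Cells with
fewer than five RNAs at the TS are inactive; five or more, active.

Cell-cycle stages come from the total nuclear DAPI content: a two-component
Gaussian mixture separates 1C (G1) and 2C (G2) populations, and cells are
assigned to G1 within [c1 - sd1, c1 + 0.75 sd1], to G2 within
[c2 - 0.5 sd2, c2 + 1.5 sd2], to S in between, and left unclassified in the
extreme tails.  The asymmetric windows keep the replication-intermediate
(S-phase) shoulder between the peaks out of the G1/G2 gates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.mixture import GaussianMixture

from .photometry import gaussian_mask_3d

__all__ = [
    "detect_spots_3d",
    "quantify_cells",
    "classify_cell_cycle",
    "summarize_replicates",
]

ACTIVITY_THRESHOLD = 5.0  # nascent RNAs at the TS


# ---------------------------------------------------------------------------
# spots
# ---------------------------------------------------------------------------

def detect_spots_3d(
    stack: np.ndarray,
    cell_masks: np.ndarray,
    nucleus_masks: np.ndarray,
    bg_sd: float | None = None,
    threshold_factor: float = 6.0,
    psf_sigma_xy: float = 1.5,
    psf_sigma_z: float = 1.5,
) -> pd.DataFrame:
    """Detect and quantify diffraction-limited spots in a 3D smFISH stack.

    Local maxima above ``threshold_factor`` times the background s.d. are
    quantified by iterative 3D Gaussian-mask photometry and assigned to the
    nuclear or cytoplasmic compartment of their cell.  ``bg_sd`` defaults to
    a robust (MAD-based) estimate over the whole stack.  Cells in which no
    spot is detected are excluded (absent from the table); segmentation or
    permeabilization failures present exactly that way.
    """
    if stack.ndim != 3:
        raise ValueError("stack must be (z, y, x)")
    if cell_masks.shape != stack.shape[1:]:
        raise ValueError("cell_masks must match the stack's (y, x) shape")
    if bg_sd is None:
        med = np.median(stack)
        bg_sd = 1.4826 * float(np.median(np.abs(stack - med)))
    rows = []
    if cell_masks.max() == 0:
        return pd.DataFrame(columns=["cell_id", "z", "y", "x", "intensity", "compartment"])
    maxima = stack == ndi.maximum_filter(stack, size=3)
    med = float(np.median(stack))
    cand = np.argwhere(maxima & (stack - med > threshold_factor * bg_sd))
    for z0, y0, x0 in cand:
        cid = int(cell_masks[y0, x0])
        if cid == 0:
            continue
        fit = gaussian_mask_3d(stack, z0, y0, x0, psf_sigma_xy, psf_sigma_z)
        zc, yc, xc = fit.pos
        iy, ix = int(round(yc)), int(round(xc))
        iy = np.clip(iy, 0, cell_masks.shape[0] - 1)
        ix = np.clip(ix, 0, cell_masks.shape[1] - 1)
        compartment = "nuclear" if nucleus_masks[iy, ix] else "cytoplasmic"
        rows.append((cid, zc, yc, xc, fit.intensity, compartment))
    return pd.DataFrame(rows, columns=["cell_id", "z", "y", "x", "intensity", "compartment"])


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def quantify_cells(spots: pd.DataFrame, activity_threshold: float = ACTIVITY_THRESHOLD):
    """Convert a spot table into per-cell nascent counts and activity calls.

    The intensity unit (one RNA) is the median cytoplasmic spot intensity
    over all cells; the TS of each cell is its brightest nuclear spot.

    Returns ``(cells, summary)``: a DataFrame (cell_id, ts_intensity,
    nascent, active) and a dict with the active fraction and the mean
    nascent count of active cells.
    """
    cyto = spots.loc[spots["compartment"] == "cytoplasmic", "intensity"]
    if len(cyto) == 0:
        raise ValueError("no cytoplasmic spots: cannot define the single-RNA unit")
    unit = float(cyto.median())
    rows = []
    for cid, grp in spots.groupby("cell_id"):
        nuc = grp[grp["compartment"] == "nuclear"]
        ts = float(nuc["intensity"].max()) if len(nuc) else 0.0
        nascent = ts / unit
        rows.append((cid, ts, nascent, nascent >= activity_threshold))
    cells = pd.DataFrame(rows, columns=["cell_id", "ts_intensity", "nascent", "active"])
    active = cells["active"]
    summary = {
        "n_cells": len(cells),
        "unit_intensity": unit,
        "active_fraction": float(active.mean()) if len(cells) else np.nan,
        "mean_nascent_active": float(cells.loc[active, "nascent"].mean()) if active.any() else np.nan,
    }
    return cells, summary


# ---------------------------------------------------------------------------
# cell cycle
# ---------------------------------------------------------------------------

def classify_cell_cycle(
    dapi_sums,
    n_bins: int = 50,
    symmetric_g1: bool = False,
    seed: int = 0,
):
    """Classify cells into G1/S/G2 from total nuclear DAPI intensity.

    A 2-component Gaussian mixture is fitted to the raw DAPI sums, with
    means initialized from the two largest modes of a ``n_bins``-bin
    histogram.  Gates: G1 = [c1 - sd1, c1 + 0.75 sd1] (or +- sd1 with
    ``symmetric_g1``), G2 = [c2 - 0.5 sd2, c2 + 1.5 sd2]; between the gates
    is S; beyond either extreme is unclassified.  A collapsed mixture
    (overlapping components) classifies nothing and warns.

    Returns ``(stages, fit_info)`` where stages is an object array of
    {'G1','S','G2','unclassified'}.
    """
    x = np.asarray(dapi_sums, dtype=float)
    if len(x) < 4 or np.ptp(x) == 0:
        warnings.warn("degenerate DAPI distribution: mixture collapse")
        return np.full(len(x), "unclassified", dtype=object), {"collapsed": True}
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    order = np.argsort(counts)[::-1]
    m1 = centers[order[0]]
    # second initial mean: strongest bin at least 5 bins away from the first
    far = order[np.abs(centers[order] - m1) > 5 * (edges[1] - edges[0])]
    m2 = centers[far[0]] if len(far) else np.percentile(x, 75)
    gmm = GaussianMixture(
        n_components=2,
        means_init=np.sort([[m1], [m2]], axis=0),
        random_state=seed,
        n_init=1,
    ).fit(x[:, None])
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    lo, hi = np.argsort(means)
    c1, sd1 = float(means[lo]), float(sds[lo])
    c2, sd2 = float(means[hi]), float(sds[hi])
    info = {"c1": c1, "sd1": sd1, "c2": c2, "sd2": sd2, "collapsed": False}
    if c2 - c1 < 0.5 * (sd1 + sd2):
        warnings.warn("mixture collapse: component means overlap; nothing classified")
        info["collapsed"] = True
        return np.full(len(x), "unclassified", dtype=object), info

    g1_lo = c1 - sd1
    g1_hi = c1 + (sd1 if symmetric_g1 else 0.75 * sd1)
    g2_lo = c2 - 0.5 * sd2
    g2_hi = c2 + 1.5 * sd2
    stages = np.full(len(x), "unclassified", dtype=object)
    stages[(x >= g1_lo) & (x <= g1_hi)] = "G1"
    stages[(x >= g2_lo) & (x <= g2_hi)] = "G2"
    stages[(x > g1_hi) & (x < g2_lo)] = "S"
    return stages, info


# ---------------------------------------------------------------------------
# replicates
# ---------------------------------------------------------------------------

def summarize_replicates(replicate_summaries, stratify_by_stage: bool = False) -> pd.DataFrame:
    """Condition-level mean +- s.e.m. over replicate experiments.

    ``replicate_summaries`` is a list of dicts as produced by
    :func:`quantify_cells` (optionally containing per-stage sub-dicts under
    ``'stages'`` when stratifying).  With fewer than two replicates the
    s.e.m. is undefined and flagged NaN.
    """
    def sem(v):
        v = np.asarray(v, dtype=float)
        if len(v) < 2:
            warnings.warn("fewer than 2 replicates: s.e.m. undefined")
            return np.nan
        return float(np.std(v, ddof=1) / np.sqrt(len(v)))

    rows = []
    keys = ["active_fraction", "mean_nascent_active"]
    groups = {"all": replicate_summaries}
    if stratify_by_stage:
        stages = sorted({s for r in replicate_summaries for s in r.get("stages", {})})
        for st in stages:
            groups[st] = [r["stages"][st] for r in replicate_summaries if st in r.get("stages", {})]
    for label, reps in groups.items():
        for key in keys:
            vals = [r[key] for r in reps if key in r and np.isfinite(r[key])]
            rows.append(
                {
                    "group": label,
                    "parameter": key,
                    "mean": float(np.mean(vals)) if vals else np.nan,
                    "sem": sem(vals) if vals else np.nan,
                    "n_replicates": len(vals),
                }
            )
    return pd.DataFrame(rows)
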