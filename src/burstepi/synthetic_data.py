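"""Generative models for every input of the bursting/epistasis/nucleosome pipeline.

The live-cell generator draws each cell from a two-state (telegraph) promoter:
after an induction delay distributed as the sum of ``n_steps`` identical
exponential activation steps (i.e. Gamma(n_steps, 1/step_rate)), the promoter
alternates between exponentially distributed ON (burst) and OFF (inter-burst)
dwells.  The transcription-site intensity is the product of the promoter state
and a lognormal burst brightness, plus additive Gaussian background noise.

The smFISH generator produces per-cell cytoplasmic spot intensities around a
unit median, a single nuclear transcription site whose intensity equals the
nascent-RNA count times that unit, and a bimodal (2C/4C) DAPI content with
known component labels.

The MNase generator plants nucleosome dyads on small chromosomes and draws
paired-end fragment midpoints around them, with per-condition occupancies and
positions so that remodeler-depletion phenotypes (nucleosome shifts, NDR
fill-in) can be planted and recovered.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BurstSimParams",
    "GroundTruth",
    "TraceSet",
    "NucSimModel",
    "simulate_traces",
    "render_movie",
    "simulate_smfish",
    "simulate_mnase",
]


# ---------------------------------------------------------------------------
# live-cell traces
# ---------------------------------------------------------------------------

@dataclass
class BurstSimParams:
    """Parameters of the two-state bursting generator.

    Rates and dwell means are in minutes; ``frame_interval`` is in seconds to
    match acquisition metadata.  ``dead_time`` models the delay between
    stimulus (galactose) addition and the start of acquisition, which the
    amplitude parameter of the induction-time fit absorbs.
    """

    n_steps: int = 3
    step_rate: float = 0.5           # per minute, per activation step
    mean_on: float = 2.0             # minutes
    mean_off: float = 8.0            # minutes
    mean_intensity: float = 10.0     # a.u., mean TS intensity while ON
    intensity_cv: float = 0.2
    background_sd: float = 1.0       # a.u., additive Gaussian noise per frame
    frame_interval: float = 15.0     # seconds
    movie_length: float = 60.0       # minutes
    active_prob: float = 1.0
    dead_time: float = 0.0           # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1 or int(self.n_steps) != self.n_steps:
            raise ValueError("n_steps must be a positive integer")
        for name in ("step_rate", "mean_on", "mean_off", "mean_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.active_prob <= 1.0:
            raise ValueError("active_prob must be in [0, 1]")
        if self.intensity_cv < 0 or self.background_sd < 0 or self.dead_time < 0:
            raise ValueError("intensity_cv, background_sd, dead_time must be >= 0")
        n = self.movie_length * 60.0 / self.frame_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("frame_interval must divide the movie evenly")

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_length * 60.0 / self.frame_interval))

    @property
    def dt_min(self) -> float:
        return self.frame_interval / 60.0


@dataclass
class TraceSet:
    """Per-cell TS intensity traces on a common time base."""

    intensity: np.ndarray            # (n_cells, n_frames), a.u.
    frame_interval: float            # seconds

    @property
    def n_cells(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]

    @property
    def time_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval / 60.0

    def to_frame(self) -> pd.DataFrame:
        n_c, n_f = self.intensity.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n_c), n_f),
                "frame": np.tile(np.arange(n_f), n_c),
                "time_s": np.tile(np.arange(n_f) * self.frame_interval, n_c),
                "intensity": self.intensity.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        df = pd.read_csv(path)
        n_c = df["cell_id"].nunique()
        n_f = df["frame"].nunique()
        wide = df.pivot(index="cell_id", columns="frame", values="intensity")
        dt = df.loc[df["frame"] == 1, "time_s"].iloc[0] if n_f > 1 else 15.0
        return cls(intensity=wide.to_numpy(float), frame_interval=float(dt))


@dataclass
class GroundTruth:
    """Generative truth for a :class:`TraceSet` (per-cell bookkeeping)."""

    induction_time: np.ndarray            # (n_cells,), min; NaN for never-active
    on_intervals: list                    # per cell: list of (start, end) min
    off_intervals: list                   # per cell: list of (start, end) min
    state: np.ndarray                     # (n_cells, n_frames) bool
    true_intensity: np.ndarray            # (n_cells, n_frames), noise-free signal
    movie_length: float                   # minutes

    def to_json(self, path) -> None:
        obj = {
            "induction_time": [None if np.isnan(t) else t for t in self.induction_time],
            "on_intervals": self.on_intervals,
            "off_intervals": self.off_intervals,
            "movie_length": self.movie_length,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def simulate_traces(params: BurstSimParams, n_cells: int):
    """Simulate ``n_cells`` telegraph-model TS intensity traces.

    Returns
    -------
    (TraceSet, GroundTruth)
        Identical ``(params, n_cells)`` always produce byte-identical output;
        per-cell RNG streams are spawned from the top-level seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    n_frames = params.n_frames
    dt = params.dt_min
    t_frames = np.arange(n_frames) * dt
    T = params.movie_length

    streams = np.random.SeedSequence(params.seed).spawn(n_cells)
    intensity = np.empty((n_cells, n_frames))
    state = np.zeros((n_cells, n_frames), dtype=bool)
    true_int = np.zeros((n_cells, n_frames))
    induction = np.full(n_cells, np.nan)
    ons: list = []
    offs: list = []

    for i in range(n_cells):
        rng = np.random.default_rng(streams[i])
        cell_on: list = []
        cell_off: list = []
        if rng.random() < params.active_prob:
            t0 = params.dead_time + rng.gamma(params.n_steps, 1.0 / params.step_rate)
            if t0 < T:
                induction[i] = t0
                t = t0
                on_state = True
                while t < T:
                    dwell = rng.exponential(params.mean_on if on_state else params.mean_off)
                    end = min(t + dwell, T)
                    (cell_on if on_state else cell_off).append((t, end))
                    t += dwell
                    on_state = not on_state
                for (a, b) in cell_on:
                    state[i, (t_frames >= a) & (t_frames < b)] = True
        ons.append(cell_on)
        offs.append(cell_off)
        noise = rng.normal(0.0, params.background_sd, n_frames)
        bright = params.mean_intensity * _lognormal_factors(rng, params.intensity_cv, n_frames)
        true_int[i] = np.where(state[i], bright, 0.0)
        intensity[i] = true_int[i] + noise

    traces = TraceSet(intensity=intensity, frame_interval=params.frame_interval)
    truth = GroundTruth(
        induction_time=induction,
        on_intervals=ons,
        off_intervals=offs,
        state=state,
        true_intensity=true_int,
        movie_length=T,
    )
    return traces, truth


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

def render_movie(
    traces: TraceSet,
    psf_sigma: float = 1.5,
    cell_size: int = 32,
    cell_radius: int | None = None,
    cell_level: float = 5.0,
    noise_sd: float = 1.0,
    spot_offset: tuple[int, int] = (0, 0),
    seed: int = 0,
):
    """Render traces as a 2D time-lapse movie with one diffraction-limited
    spot per ON cell.

    Cells are disk-shaped regions on a square grid, ``cell_size`` pixels per
    tile; each cell body sits above background (``cell_level``) so that
    Otsu-based segmentation can find it even when the promoter is OFF.  The
    spot is a 2D Gaussian of integrated intensity equal to the trace value,
    at a fixed position (tile center plus ``spot_offset``) inside each cell.

    Returns ``(movie, labels)`` where ``movie`` has shape (t, y, x) and
    ``labels`` is the ground-truth cell label image.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    n_cells, n_frames = traces.intensity.shape
    ncols = int(np.ceil(np.sqrt(n_cells)))
    nrows = int(np.ceil(n_cells / ncols))
    H, W = nrows * cell_size, ncols * cell_size
    if cell_radius is None:
        cell_radius = cell_size // 2 - 2
    oy, ox = spot_offset
    if abs(oy) >= cell_radius or abs(ox) >= cell_radius:
        raise ValueError("spot_offset places the spot outside the cell body")

    yy, xx = np.mgrid[0:H, 0:W]
    labels = np.zeros((H, W), dtype=np.uint16)
    centers = []
    for i in range(n_cells):
        r, c = divmod(i, ncols)
        cy = r * cell_size + cell_size // 2
        cx = c * cell_size + cell_size // 2
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius**2
        if np.any(labels[disk]):
            raise ValueError("overlapping cell regions in layout")
        labels[disk] = i + 1
        centers.append((cy + oy, cx + ox))

    body = (labels > 0).astype(float) * cell_level
    rng = np.random.default_rng(seed)
    movie = np.empty((n_frames, H, W), dtype=np.float32)
    win = int(np.ceil(5 * psf_sigma))
    for t in range(n_frames):
        frame = body.copy()
        for i, (sy, sx) in enumerate(centers):
            amp = traces.intensity[i, t]
            if amp <= 0:
                continue
            y0, y1 = sy - win, sy + win + 1
            x0, x1 = sx - win, sx + win + 1
            gy = np.arange(y0, y1)
            gx = np.arange(x0, x1)
            g = np.exp(
                -((gy[:, None] - sy) ** 2 + (gx[None, :] - sx) ** 2)
                / (2 * psf_sigma**2)
            )
            frame[y0:y1, x0:x1] += amp / (2 * np.pi * psf_sigma**2) * g
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        movie[t] = frame
    return movie, labels


# ---------------------------------------------------------------------------
# smFISH
# ---------------------------------------------------------------------------

def simulate_smfish(
    n_cells: int,
    nascent_counts=None,
    cyto_mean_spots: float = 20.0,
    cyto_intensity_cv: float = 0.15,
    unit_intensity: float = 1000.0,
    dapi_means: tuple[float, float] = (1.0e5, 2.0e5),
    dapi_sds: tuple[float, float] = (5.0e3, 5.0e3),
    dapi_weights: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
):
    """Simulate an smFISH cell table.

    ``nascent_counts`` may be an array of per-cell nascent-RNA counts, a
    callable ``f(rng, n) -> counts``, or None (default: Poisson with mean 8,
    half the cells silenced to 0 so an active fraction of ~0.5 results).

    Returns a dict with ``cells`` (cell_id, dapi_sum, true_component,
    true_nascent) and ``spots`` (cell_id, compartment, intensity) DataFrames.
    Cytoplasmic spot intensities are lognormal with unit median times
    ``unit_intensity``; the single nuclear TS intensity equals
    ``true_nascent * unit_intensity``.
    """
    rng = np.random.default_rng(seed)
    if nascent_counts is None:
        counts = rng.poisson(8.0, n_cells).astype(float)
        counts[rng.random(n_cells) < 0.5] = 0.0
    elif callable(nascent_counts):
        counts = np.asarray(nascent_counts(rng, n_cells), dtype=float)
    else:
        counts = np.broadcast_to(np.asarray(nascent_counts, dtype=float), (n_cells,)).copy()

    if abs(dapi_means[0] - dapi_means[1]) < 1e-9 * max(abs(dapi_means[0]), 1.0):
        warnings.warn("degenerate DAPI mixture: component means are equal")
    comp = (rng.random(n_cells) < dapi_weights[1] / (dapi_weights[0] + dapi_weights[1])).astype(int)
    dapi = rng.normal(np.asarray(dapi_means)[comp], np.asarray(dapi_sds)[comp])

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "dapi_sum": dapi,
            "true_component": comp,
            "true_nascent": counts,
        }
    )

    rows = []
    sigma_ln = np.sqrt(np.log1p(cyto_intensity_cv**2))
    for i in range(n_cells):
        n_cyto = rng.poisson(cyto_mean_spots)
        # lognormal with median 1 => exp(N(0, sigma)); median over cells is the unit
        cyto = unit_intensity * rng.lognormal(0.0, sigma_ln, n_cyto)
        for v in cyto:
            rows.append((i, "cytoplasmic", v))
        if counts[i] > 0:
            rows.append((i, "nuclear", counts[i] * unit_intensity))
    spots = pd.DataFrame(rows, columns=["cell_id", "compartment", "intensity"])
    return {"cells": cells, "spots": spots}


# ---------------------------------------------------------------------------
# MNase fragments
# ---------------------------------------------------------------------------

@dataclass
class NucSimModel:
    """Planted-nucleosome model for MNase fragment simulation.

    ``nucleosomes`` maps condition label -> DataFrame with columns
    (chrom, center, occupancy).  Fragment midpoints are drawn Normal(center,
    ``position_sd``); fragment lengths Normal(``frag_len_mean``,
    ``frag_len_sd``) truncated to [50, 300] bp.  A ``background_frac`` share
    of fragments is uniform over the genome, emulating non-nucleosomal signal.
    """

    chrom_sizes: dict
    nucleosomes: dict
    fragments_per_condition: int = 10000
    frag_len_mean: float = 150.0
    frag_len_sd: float = 15.0
    position_sd: float = 20.0
    background_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, df in self.nucleosomes.items():
            if (df["occupancy"] < 0).any():
                raise ValueError(f"negative occupancy in condition {cond!r}")
            for _, row in df.iterrows():
                if not 0 <= row["center"] <= self.chrom_sizes[row["chrom"]]:
                    raise ValueError("nucleosome center outside chromosome bounds")


def promoter_array_model(
    genes: pd.DataFrame,
    chrom_sizes: dict,
    conditions=("DMSO",),
    spacing: int = 165,
    ndr_width: int = 300,
    plus_one_offset: int = 60,
    array_extent: int = 2200,
    plus_one_shifts: dict | None = None,
    ndr_fill: dict | None = None,
    fragments_per_condition: int = 10000,
    seed: int = 0,
    **model_kwargs,
) -> NucSimModel:
    """Plant a phased nucleosome array with a promoter NDR per gene.

    Yeast chromatin is an essentially continuous nucleosome array broken by
    promoter NDRs, so each gene gets a +1 nucleosome ``plus_one_offset`` bp
    downstream of its TSS (strand-oriented), a -1 nucleosome ``ndr_width``
    bp upstream of the +1, and flanking nucleosomes every ``spacing`` bp out
    to ``array_extent`` — which keeps the promoter trough, not the window
    edge, as each gene's coverage minimum.

    Condition-dependent phenotypes: ``plus_one_shifts[cond]`` moves the +1
    (and its downstream array) by the given strand-oriented bp;
    ``ndr_fill[cond]`` plants an extra nucleosome of the given occupancy in
    the NDR center, emulating remodeler-depletion fill-in.
    """
    plus_one_shifts = plus_one_shifts or {}
    ndr_fill = ndr_fill or {}
    nucleosomes = {}
    for cond in conditions:
        shift = plus_one_shifts.get(cond, 0)
        fill = ndr_fill.get(cond, 0.0)
        rows = []
        for _, g in genes.iterrows():
            sign = 1 if g["strand"] == "+" else -1
            size = chrom_sizes[g["chrom"]]
            p1 = g["tss"] + sign * (plus_one_offset + shift)
            m1 = p1 - sign * (ndr_width + shift)
            n_down = max(int((array_extent - plus_one_offset) // spacing), 1)
            n_up = max(int((array_extent - ndr_width) // spacing), 1)
            centers = [p1 + sign * k * spacing for k in range(n_down + 1)]
            centers += [m1 - sign * k * spacing for k in range(n_up + 1)]
            for c in centers:
                if 0 <= c <= size:
                    rows.append((g["chrom"], float(c), 1.0))
            if fill > 0:
                mid = 0.5 * (p1 + m1)
                rows.append((g["chrom"], float(mid), float(fill)))
        nucleosomes[cond] = pd.DataFrame(rows, columns=["chrom", "center", "occupancy"])
    return NucSimModel(
        chrom_sizes=chrom_sizes,
        nucleosomes=nucleosomes,
        fragments_per_condition=fragments_per_condition,
        seed=seed,
        **model_kwargs,
    )


def simulate_mnase(model: NucSimModel):
    """Draw MNase fragments per condition from planted nucleosomes.

    Returns a dict of condition -> DataFrame(chrom, start, end) with 0-based
    half-open coordinates, deterministic under ``model.seed``.
    """
    out = {}
    conditions = sorted(model.nucleosomes)
    streams = np.random.SeedSequence(model.seed).spawn(len(conditions))
    chroms = sorted(model.chrom_sizes)
    chrom_len = np.array([model.chrom_sizes[c] for c in chroms], dtype=float)
    for cond, ss in zip(conditions, streams):
        rng = np.random.default_rng(ss)
        nucs = model.nucleosomes[cond].reset_index(drop=True)
        occ = nucs["occupancy"].to_numpy(float)
        if occ.sum() <= 0:
            raise ValueError(f"zero total occupancy in condition {cond!r}")
        n = model.fragments_per_condition
        n_bg = rng.binomial(n, model.background_frac)
        n_nuc = n - n_bg

        which = rng.choice(len(nucs), size=n_nuc, p=occ / occ.sum())
        mids = rng.normal(nucs["center"].to_numpy(float)[which], model.position_sd)
        frag_chrom = nucs["chrom"].to_numpy()[which]

        if n_bg:
            ci = rng.choice(len(chroms), size=n_bg, p=chrom_len / chrom_len.sum())
            bg_mids = rng.uniform(0, chrom_len[ci])
            mids = np.concatenate([mids, bg_mids])
            frag_chrom = np.concatenate([frag_chrom, np.array(chroms, dtype=object)[ci]])

        a, b = (50 - model.frag_len_mean) / model.frag_len_sd, (300 - model.frag_len_mean) / model.frag_len_sd
        lengths = stats.truncnorm.rvs(
            a, b, loc=model.frag_len_mean, scale=model.frag_len_sd,
            size=len(mids), random_state=rng,
        )
        start = np.round(mids - lengths / 2.0).astype(int)
        end = start + np.round(lengths).astype(int)
        sizes = np.array([model.chrom_sizes[c] for c in frag_chrom])
        start = np.clip(start, 0, sizes - 1)
        end = np.clip(end, start + 1, sizes)
        df = pd.DataFrame({"chrom": frag_chrom, "start": start, "end": end})
        out[cond] = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return out
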