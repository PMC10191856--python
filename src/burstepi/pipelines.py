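"""End-to-end study runners.

Each function wires the generators to the analysis stages exactly as the
numbered scripts under ``analysis/`` do, and returns plain dicts of the
quantities a study reports.  Problem sizes default to the study conditions
(300-cell live-cell experiments, 1,000-replicate calibrations, 2,000-sample
distribution fits, 10,000 fragments per gene) so that results are directly
comparable across entry points.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pandas as pd

from . import burst_metrics as bm
from . import dist_fits, epistasis, mnase, smfish_quant, stats_boot
from . import synthetic_data as synth

__all__ = [
    "records_from_traces",
    "telegraph_recovery_study",
    "binarization_fidelity_study",
    "bootstrap_calibration_study",
    "fisher_enumeration_check",
    "epistasis_replicate_study",
    "gamma_recovery_study",
    "lognormal_recovery_study",
    "smfish_study",
    "mnase_study",
]


# ---------------------------------------------------------------------------
# live-cell trace processing
# ---------------------------------------------------------------------------

def records_from_traces(traces, bg_width=None, threshold_factor: float = 5.0):
    """Binarize a :class:`TraceSet` and extract per-cell burst records.

    ``bg_width`` is the background width used for thresholding; when None it
    is estimated per condition by the refined whole-trace Lorentzian fit on
    a pooled subsample of frames (noise is homogeneous within a condition).

    Returns ``(records, binaries, bg_width)``.
    """
    if bg_width is None:
        pool = traces.intensity.ravel()
        if pool.size > 20000:
            pool = pool[:: pool.size // 20000 + 1]
        bg_width = bm.estimate_trace_background_width(pool)
    records, binaries = [], []
    for i in range(traces.n_cells):
        b = bm.binarize(
            traces.intensity[i], bg_width,
            frame_interval=traces.frame_interval,
            threshold_factor=threshold_factor,
        )
        binaries.append(b)
        records.append(bm.extract_burst_record(b, traces.intensity[i], cell_id=i))
    return records, binaries, bg_width


def telegraph_recovery_study(
    n_cells: int = 300,
    seed: int = 0,
    n_boot: int = 1000,
    **param_overrides,
) -> dict:
    """Recover telegraph parameters from simulated traces, end to end.

    Returns generative truth, the paper-style uncorrected bootstrap
    summary, and the discretization-corrected estimates (with bootstrap
    s.d.s) for burst duration, time between bursts and induction time.
    """
    params = synth.BurstSimParams(seed=seed, **param_overrides)
    traces, truth = synth.simulate_traces(params, n_cells)
    records, binaries, width = records_from_traces(traces)
    summary = bm.summarize_population(records, condition="sim", n_boot=n_boot, seed=seed)
    corrected = bm.estimate_telegraph_parameters(binaries, n_boot=n_boot, seed=seed)
    return {
        "truth": {
            "mean_on": params.mean_on,
            "mean_off": params.mean_off,
            "induction_time": params.dead_time + params.n_steps / params.step_rate,
        },
        "bg_width": width,
        "summary": summary,
        "corrected": {k: v[0] for k, v in corrected.items()},
        "corrected_sd": {k: v[1] for k, v in corrected.items()},
    }


def binarization_fidelity_study(
    n_cells: int = 100,
    snr: float = 5.0,
    seed: int = 0,
) -> dict:
    """Frame-level ON/OFF agreement with generative truth at a given SNR
    (mean ON intensity over background s.d.)."""
    params = synth.BurstSimParams(mean_intensity=snr, background_sd=1.0, seed=seed)
    traces, truth = synth.simulate_traces(params, n_cells)
    records, binaries, width = records_from_traces(traces)
    agree = [
        float(np.mean(b.state == truth.state[i][: len(b.state)]))
        for i, b in enumerate(binaries)
    ]
    return {"agreement": float(np.mean(agree)), "bg_width": width, "n_cells": n_cells}


# ---------------------------------------------------------------------------
# statistics calibration
# ---------------------------------------------------------------------------

def bootstrap_calibration_study(
    n_replicates: int = 1000,
    n_per_group: int = 100,
    n_boot: int = 1999,
    alpha: float = 0.05,
    seed: int = 0,
    effect: float = 0.0,
) -> dict:
    """Rejection rate of the two-sample bootstrap ASL test.

    With ``effect = 0`` this measures the type-I error (should match
    ``alpha``); with a nonzero mean shift it measures power.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for r in range(n_replicates):
        a = rng.normal(effect, 1.0, n_per_group)
        b = rng.normal(0.0, 1.0, n_per_group)
        res = stats_boot.bootstrap_asl_test(a, b, n_boot=n_boot, seed=int(rng.integers(2**31)))
        rejections += res.asl < alpha
    return {"rejection_rate": rejections / n_replicates, "n_replicates": n_replicates}


def _fisher_two_sided_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by enumerating the hypergeometric support:
    sum of probabilities of all tables (fixed margins) no more likely than
    the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def fisher_enumeration_check(max_margin: int = 12) -> dict:
    """Compare Fisher's exact p against brute-force hypergeometric
    enumeration for every 2x2 table with all margins <= ``max_margin``."""
    worst = 0.0
    n_tables = 0
    for a, b, c, d in product(range(max_margin + 1), repeat=4):
        if a + b > max_margin or c + d > max_margin:
            continue
        if a + c > max_margin or b + d > max_margin:
            continue
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        p = stats_boot.fisher_active(a, b, c, d).asl
        p_ref = _fisher_two_sided_bruteforce(a, b, c, d)
        worst = max(worst, abs(p - p_ref))
        n_tables += 1
    return {"max_abs_diff": worst, "n_tables": n_tables}


# ---------------------------------------------------------------------------
# epistasis replicate studies
# ---------------------------------------------------------------------------

def _condition_summary(mean_off: float, n_cells: int, seed: int, n_boot: int) -> bm.PopulationSummary:
    """Bootstrap summary of one simulated condition, augmented with the
    censoring-corrected telegraph estimates (suffix ``_corrected``)."""
    params = synth.BurstSimParams(mean_off=mean_off, seed=seed)
    traces, _ = synth.simulate_traces(params, n_cells)
    records, binaries, _ = records_from_traces(traces)
    summary = bm.summarize_population(records, n_boot=n_boot, seed=seed)
    corrected = bm.estimate_telegraph_parameters(binaries, n_boot=n_boot, seed=seed)
    alias = {
        "mean_on": "burst_duration_corrected",
        "mean_off": "inter_burst_time_corrected",
        "induction_time": "induction_time_corrected",
    }
    for src, name in alias.items():
        mean, sd = corrected[src]
        summary.params[name] = bm.ParamSummary(boot_mean=mean, boot_sd=sd, n=len(records), values=np.array([]))
    return summary


def epistasis_replicate_study(
    n_studies: int = 100,
    n_cells: int = 200,
    factor_a: float = 2.0,
    factor_b: float = 1.5,
    interaction: float = 1.0,
    baseline_off: float = 8.0,
    parameter: str = "inter_burst_time_corrected",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Replicate dynamic-epistasis studies on simulated perturbations.

    Each study simulates four conditions — baseline, A (mean_off x
    ``factor_a``), B (x ``factor_b``) and the double perturbation
    (x ``factor_a * factor_b * interaction``) — runs the full trace ->
    burst-record -> bootstrap pipeline, and classifies the interaction.
    ``interaction = 1`` plants independence; 2 plants synergy.

    The default parameter is the censoring-corrected time between bursts:
    raw inter-burst means saturate within the 1 h movie for strong
    perturbations (long gaps cannot complete before the movie ends), which
    would masquerade as buffering in the multiplicative comparison.

    Returns the fraction of studies per label.
    """
    rng = np.random.default_rng(seed)
    labels = []
    for s in range(n_studies):
        seeds = rng.integers(2**31, size=4)
        ref = _condition_summary(baseline_off, n_cells, int(seeds[0]), n_boot)
        pa = _condition_summary(baseline_off * factor_a, n_cells, int(seeds[1]), n_boot)
        pb = _condition_summary(baseline_off * factor_b, n_cells, int(seeds[2]), n_boot)
        pab = _condition_summary(
            baseline_off * factor_a * factor_b * interaction, n_cells, int(seeds[3]), n_boot
        )
        ref.condition, pa.condition, pb.condition, pab.condition = "ref", "A", "B", "A&B"
        fa = epistasis.fractional_change(pa, ref, parameter)
        fb = epistasis.fractional_change(pb, ref, parameter)
        fab = epistasis.fractional_change(pab, ref, parameter)
        call = epistasis.classify_interaction(fab, epistasis.expected_double(fa, fb))
        labels.append(call.label)
    labels = np.asarray(labels)
    return {
        "as_expected": float(np.mean(labels == "as-expected")),
        "synergistic": float(np.mean(labels == "synergistic")),
        "buffered": float(np.mean(labels == "buffered")),
        "n_studies": n_studies,
    }


# ---------------------------------------------------------------------------
# distribution-fit recovery
# ---------------------------------------------------------------------------

def gamma_recovery_study(
    n_steps_grid=(1, 2, 4, 6),
    theta: float = 2.0,
    n_samples: int = 2000,
    seed: int = 0,
) -> dict:
    """Fit induction-time histograms drawn from known Gamma step counts."""
    rng = np.random.default_rng(seed)
    fitted = {}
    for k in n_steps_grid:
        times = rng.gamma(k, theta, n_samples)
        fit = dist_fits.fit_gamma_induction(times)
        fitted[k] = {"k": fit.k, "theta": fit.theta, "A": fit.A, "r2": fit.r2}
    # noiseless model histogram: fitting the generating model to exact
    # model densities must give R^2 = 1
    centers = np.arange(0.5, 40.0, 1.0)
    density = dist_fits.amplitude_gamma_pdf(centers, 2.0, 6.0, theta)
    noiseless = dist_fits.fit_gamma_density(centers, density).r2
    return {"fits": fitted, "noiseless_r2": noiseless}


def lognormal_recovery_study(
    mu: float = 5.5,
    sigma: float = 0.6,
    n_samples: int = 2000,
    seed: int = 0,
) -> dict:
    rng = np.random.default_rng(seed)
    fit = dist_fits.fit_lognormal_intensity(rng.lognormal(mu, sigma, n_samples))
    return {"mu": fit.mu, "sigma": fit.sigma, "r2": fit.r2, "truth": (mu, sigma)}


# ---------------------------------------------------------------------------
# smFISH
# ---------------------------------------------------------------------------

def smfish_study(n_cells: int = 2000, seed: int = 0) -> dict:
    """Half-silent / half-active smFISH population plus cell-cycle recovery.

    Nascent counts are 0 for half the cells and 10 for the other half, so
    the true active fraction is the silent/expressing split; DAPI follows
    the default bimodal 1C/2C model.  Stage-call accuracy is measured
    against generative component labels among cells given a G1/G2 call.
    """

    def nascent(rng, n):
        counts = np.full(n, 10.0)
        counts[rng.random(n) < 0.5] = 0.0
        return counts

    sample = synth.simulate_smfish(n_cells, nascent_counts=nascent, seed=seed)
    cells, summary = smfish_quant.quantify_cells(sample["spots"])
    stages, info = smfish_quant.classify_cell_cycle(sample["cells"]["dapi_sum"])
    truth = np.where(sample["cells"]["true_component"] == 0, "G1", "G2")
    called = np.isin(stages, ["G1", "G2"])
    accuracy = float(np.mean(stages[called] == truth[called])) if called.any() else np.nan
    true_active = sample["cells"]["true_nascent"] >= smfish_quant.ACTIVITY_THRESHOLD
    return {
        "active_fraction": summary["active_fraction"],
        "true_active_fraction": float(true_active.mean()),
        "mean_nascent_active": summary["mean_nascent_active"],
        "stage_accuracy": accuracy,
        "stage_called_fraction": float(called.mean()),
        "gmm": info,
        "n_cells": n_cells,
    }


# ---------------------------------------------------------------------------
# MNase
# ---------------------------------------------------------------------------

def demo_genes(n_genes: int = 6, chrom_size: int = 20000) -> tuple:
    """Small two-chromosome gene annotation with both strands and both
    TATA classes, used by the MNase studies."""
    rows = []
    for i in range(n_genes):
        chrom = f"chr{'I' * (i % 2 + 1)}"
        strand = "+" if i % 4 < 2 else "-"
        tss = 5000 + (i // 2) * 5000
        sign = 1 if strand == "+" else -1
        rows.append(
            {
                "name": f"gene{i}",
                "chrom": chrom,
                "strand": strand,
                "tss": tss,
                "tata_start": tss - sign * 90,
                "tata_class": "TATA" if i % 2 == 0 else "TATA-mismatch",
            }
        )
    genes = pd.DataFrame(rows)
    sizes = {"chrI": chrom_size, "chrII": chrom_size}
    return genes, sizes


def mnase_study(
    fragments_per_gene: int = 10000,
    shift_bp: int = 40,
    n_genes: int = 6,
    seed: int = 0,
) -> dict:
    """Planted promoter-architecture recovery and depletion-shift study.

    Plants phased arrays (+1 at +60, NDR 300 bp) for ``n_genes`` genes,
    draws ``fragments_per_gene`` mono-nucleosomal fragments per gene for an
    unperturbed and a depleted condition whose +1 is moved ``shift_bp``
    downstream, and recovers positions and shifts with the calling
    pipeline.
    """
    genes, sizes = demo_genes(n_genes)
    model = synth.promoter_array_model(
        genes, sizes,
        conditions=("DMSO", "depleted"),
        plus_one_shifts={"depleted": shift_bp},
        fragments_per_condition=fragments_per_gene * n_genes,
        seed=seed,
    )
    frags = synth.simulate_mnase(model)
    cov = {c: mnase.make_coverage(mnase.filter_fragments(f), sizes) for c, f in frags.items()}
    calls_ref = mnase.call_plus_one([cov["DMSO"]], genes)
    calls_dep = mnase.call_plus_one([cov["depleted"]], genes)
    shifts, shift_summary = mnase.plus_one_shift(calls_dep, calls_ref, genes)
    inc = calls_ref.loc[~calls_ref["excluded"]]
    profile = mnase.metagene_profile(cov["DMSO"], calls_ref, genes)
    return {
        "plus_one_err": float((inc["plus_one"] - 60).abs().mean()),
        "minus_one_err": float((inc["minus_one"] + 240).abs().mean()),
        "ndr_width_mean": float(inc["ndr_width"].mean()),
        "median_shift": float(shifts["shift"].median()),
        "shift_summary": shift_summary,
        "n_called": int(len(inc)),
        "n_genes": n_genes,
        "metagene_center_peak": float(profile[1000]),
        "coverage_sums": {
            c: {ch: float(t.norm[ch].sum()) for ch in t.norm} for c, t in cov.items()
        },
    }
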