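"""MNase-seq coverage, promoter nucleosome calling, and depletion comparisons.

Paired-end fragments are length-filtered (95-225 bp inclusive, the
mono-nucleosomal range), converted to base-resolution coverage by counting
every base covered by the full fragment span, and normalized chromosome by
chromosome to total coverage 1.

Promoter nucleosomes are called per gene on the raw (pre-normalization)
coverage of a 4,000 bp TSS-centered window, strand-flipped for Crick genes,
summed over the pooled unperturbed reference datasets and smoothed with a
40 bp Gaussian window.  The -1 nucleosome is the last coverage peak before
the smoothed minimum, the +1 nucleosome the first peak after it; the NDR
width is their distance.  Genes with fewer than two peaks, or whose -1/+1
call lands more than 1,000 bp from the TSS, are excluded.

Downstream comparisons: +1-centered metagene averages, NDR-width-sorted
log2 fold-change heatmaps of depletion vs control, per-gene +1 shifts
summarized by TATA class, and coverage over the 8 bp TATA window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "CoverageTrack",
    "filter_fragments",
    "read_fragments_bed",
    "read_fragments_bam",
    "make_coverage",
    "call_plus_one",
    "metagene_profile",
    "log2fc_matrix",
    "plus_one_shift",
    "tata_window_coverage",
    "write_bedgraph",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class CoverageTrack:
    """Base-resolution coverage per chromosome: raw counts and the
    per-chromosome normalized twin (each chromosome sums to 1)."""

    raw: dict   # chrom -> np.ndarray of fragment-span counts
    norm: dict  # chrom -> np.ndarray summing to 1

    @classmethod
    def from_raw(cls, raw: dict) -> "CoverageTrack":
        norm = {}
        for chrom, arr in raw.items():
            total = arr.sum()
            norm[chrom] = arr / total if total > 0 else arr.astype(float)
        return cls(raw=raw, norm=norm)


# ---------------------------------------------------------------------------
# fragments and coverage
# ---------------------------------------------------------------------------

def filter_fragments(fragments: pd.DataFrame, min_len: int = 95, max_len: int = 225) -> pd.DataFrame:
    """Retain mono-nucleosome-sized fragments, bounds inclusive."""
    length = fragments["end"] - fragments["start"]
    return fragments.loc[(length >= min_len) & (length <= max_len)].reset_index(drop=True)


def read_fragments_bed(path) -> pd.DataFrame:
    """BED3(+) fragment intervals (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def read_fragments_bam(path) -> pd.DataFrame:
    """Fragment spans from name-paired alignments (one span per pair)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(path) as bam:
        for read in bam:
            if not read.is_proper_pair or read.is_reverse or read.template_length <= 0:
                continue
            rows.append((read.reference_name, read.reference_start,
                         read.reference_start + read.template_length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def make_coverage(fragments: pd.DataFrame, chrom_sizes: dict) -> CoverageTrack:
    """Fragment-span coverage per chromosome, normalized to sum 1.

    Every base in [start, end) of each fragment is incremented once (one
    count per read pair).  Fragments extending beyond the chromosome are
    clipped with a warning.
    """
    raw = {c: np.zeros(int(n)) for c, n in chrom_sizes.items()}
    clipped = 0
    for chrom, grp in fragments.groupby("chrom"):
        if chrom not in raw:
            raise KeyError(f"fragment on unknown chromosome {chrom!r}")
        size = len(raw[chrom])
        start = grp["start"].to_numpy(int)
        end = grp["end"].to_numpy(int)
        bad = (start < 0) | (end > size)
        clipped += int(bad.sum())
        start = np.clip(start, 0, size)
        end = np.clip(end, 0, size)
        delta = np.zeros(size + 1)
        np.add.at(delta, start, 1.0)
        np.add.at(delta, end, -1.0)
        raw[chrom] += np.cumsum(delta[:-1])
    if clipped:
        warnings.warn(f"{clipped} fragments extended beyond a chromosome and were clipped")
    return CoverageTrack.from_raw(raw)


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def _extract_window(cov: dict, gene, half: int):
    """TSS-oriented coverage window of length 2*half.

    Index i maps to position (i - half) downstream of the TSS regardless of
    strand; windows are mirrored around the TSS for Crick genes so that
    mirror-image genes give identical oriented profiles.  Out-of-chromosome
    parts are zero-padded and flagged truncated.
    """
    arr = cov[gene["chrom"]]
    tss = int(gene["tss"])
    if gene["strand"] == "+":
        lo, hi = tss - half, tss + half
    else:
        lo, hi = tss - half + 1, tss + half + 1
    out = np.zeros(2 * half)
    a, b = max(lo, 0), min(hi, len(arr))
    truncated = (a != lo) or (b != hi)
    if b > a:
        out[a - lo : b - lo] = arr[a:b]
    if gene["strand"] != "+":
        out = out[::-1]
    return out, truncated


def _oriented_to_genomic(gene, rel: float) -> float:
    """Convert a TSS-oriented offset (downstream positive) to genomic bp."""
    return gene["tss"] + rel if gene["strand"] == "+" else gene["tss"] - rel


# ---------------------------------------------------------------------------
# nucleosome calling
# ---------------------------------------------------------------------------

def smoothing_sigma(window: float = 40.0, mode: str = "fwhm") -> float:
    """Gaussian sigma for a '40 bp window': FWHM = window by default, or the
    raw sigma when mode='sigma' (both interpretations shipped)."""
    if mode == "fwhm":
        return window / FWHM_TO_SIGMA
    if mode == "sigma":
        return float(window)
    raise ValueError(f"unknown smoothing mode {mode!r}")


def call_plus_one(
    coverage_sets,
    genes: pd.DataFrame,
    window: int = 4000,
    smooth_window: float = 40.0,
    smooth_mode: str = "fwhm",
    prominence_frac: float = 0.05,
    min_separation: int = 100,
    max_tss_distance: int = 1000,
) -> pd.DataFrame:
    """Call -1/+1 promoter nucleosomes per gene from pooled raw coverage.

    ``coverage_sets`` is a list of :class:`CoverageTrack` (the unperturbed
    reference pool; pass a single-element list for per-dataset calling).
    Positions are reported TSS-oriented (downstream positive).  Exclusion
    reasons: 'no-data', 'fewer-than-two-peaks', 'peak-beyond-1000bp'.
    """
    half = window // 2
    sigma = smoothing_sigma(smooth_window, smooth_mode)
    rows = []
    for _, gene in genes.iterrows():
        pooled = np.zeros(window)
        truncated = False
        for track in coverage_sets:
            w, t = _extract_window(track.raw, gene, half)
            pooled += w
            truncated |= t
        base = {"gene": gene["name"], "truncated": truncated,
                "minus_one": np.nan, "plus_one": np.nan, "ndr_width": np.nan}
        if pooled.sum() == 0:
            rows.append({**base, "excluded": True, "reason": "no-data"})
            continue
        smoothed = gaussian_filter1d(pooled, sigma, mode="nearest")
        minimum = int(np.argmin(smoothed))
        peaks, _ = find_peaks(
            smoothed,
            prominence=prominence_frac * smoothed.max(),
            distance=min_separation,
        )
        before = peaks[peaks < minimum]
        after = peaks[peaks > minimum]
        if len(peaks) < 2 or len(before) == 0 or len(after) == 0:
            rows.append({**base, "excluded": True, "reason": "fewer-than-two-peaks"})
            continue
        minus_one = float(before[-1] - half)
        plus_one = float(after[0] - half)
        if abs(minus_one) > max_tss_distance or abs(plus_one) > max_tss_distance:
            rows.append({**base, "excluded": True, "reason": "peak-beyond-1000bp"})
            continue
        rows.append(
            {
                **base,
                "minus_one": minus_one,
                "plus_one": plus_one,
                "ndr_width": plus_one - minus_one,
                "excluded": False,
                "reason": "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metagene / comparisons
# ---------------------------------------------------------------------------

def _included(calls: pd.DataFrame) -> pd.DataFrame:
    return calls.loc[~calls["excluded"]]


def _plus_one_window(cov: dict, gene, plus_one_rel: float, half: int):
    """Oriented window centered on the gene's reference +1 nucleosome."""
    centered = dict(gene)
    centered["tss"] = int(round(_oriented_to_genomic(gene, plus_one_rel)))
    return _extract_window(cov, centered, half)


def metagene_profile(
    coverage: CoverageTrack,
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 2000,
) -> np.ndarray:
    """Mean normalized coverage over +1-centered, strand-oriented windows.

    Each included gene contributes its 2,000 bp window centered at that
    gene's +1 nucleosome position in the unperturbed reference; the profile
    is the element-wise mean.
    """
    inc = _included(calls)
    if len(inc) == 0:
        raise ValueError("no included genes for metagene profile")
    half = window // 2
    gene_by_name = {g["name"]: g for _, g in genes.iterrows()}
    acc = np.zeros(window)
    for _, call in inc.iterrows():
        gene = gene_by_name[call["gene"]]
        w, _ = _plus_one_window(coverage.norm, gene, call["plus_one"], half)
        acc += w
    return acc / len(inc)


def log2fc_matrix(
    depleted: CoverageTrack,
    control_replicates,
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 2000,
    eps: float | None = None,
) -> pd.DataFrame:
    """Gene x position log2 fold-change of depletion vs mean control.

    Windows are +1-centered and strand-oriented; rows are ordered by
    ascending NDR width.  ``eps`` guards zero coverage; by default it is 1%
    of the mean control coverage per base over all windows, small enough not
    to damp genuine fold-changes.
    """
    inc = _included(calls).sort_values("ndr_width")
    half = window // 2
    gene_by_name = {g["name"]: g for _, g in genes.iterrows()}
    dep_rows, ctl_rows, names = [], [], []
    dep_cov = depleted.norm if isinstance(depleted, CoverageTrack) else depleted
    for _, call in inc.iterrows():
        gene = gene_by_name[call["gene"]]
        d, _ = _plus_one_window(dep_cov, gene, call["plus_one"], half)
        ctl = np.zeros(window)
        for track in control_replicates:
            cov = track.norm if isinstance(track, CoverageTrack) else track
            w, _ = _plus_one_window(cov, gene, call["plus_one"], half)
            ctl += w
        ctl /= max(len(control_replicates), 1)
        dep_rows.append(d)
        ctl_rows.append(ctl)
        names.append(call["gene"])
    dep_mat = np.asarray(dep_rows)
    ctl_mat = np.asarray(ctl_rows)
    if eps is None:
        mean_ctl = ctl_mat.mean()
        eps = 0.01 * mean_ctl if mean_ctl > 0 else 1e-12
    mat = np.log2((dep_mat + eps) / (ctl_mat + eps))
    cols = np.arange(-half, half)
    return pd.DataFrame(mat, index=names, columns=cols)


def plus_one_shift(
    depleted_calls: pd.DataFrame,
    reference_calls: pd.DataFrame,
    gene_classes: pd.DataFrame | None = None,
):
    """Per-gene +1 nucleosome shift: depleted minus reference, in
    TSS-oriented coordinates (negative = toward the NDR / TSS).

    Genes excluded in either condition are dropped.  Returns
    ``(shifts, summary)``: per-gene shifts (with TATA class when
    ``gene_classes`` provides columns name/tata_class) and per-class
    medians with counts.
    """
    dep = _included(depleted_calls)[["gene", "plus_one"]]
    ref = _included(reference_calls)[["gene", "plus_one"]]
    merged = dep.merge(ref, on="gene", suffixes=("_dep", "_ref"))
    merged["shift"] = merged["plus_one_dep"] - merged["plus_one_ref"]
    if gene_classes is not None and "tata_class" in gene_classes.columns:
        merged = merged.merge(
            gene_classes[["name", "tata_class"]].rename(columns={"name": "gene"}),
            on="gene", how="left",
        )
    else:
        merged["tata_class"] = "unknown"
    summary = (
        merged.groupby("tata_class")["shift"]
        .agg(median="median", n="count")
        .reset_index()
    )
    return merged[["gene", "shift", "tata_class"]], summary


def tata_window_coverage(coverage: CoverageTrack, genes: pd.DataFrame) -> pd.DataFrame:
    """Sum of normalized coverage over the 8 bp TATA / TATA-mismatch window.

    Genes without an annotated window (NaN ``tata_start``) are skipped.
    """
    rows = []
    for _, gene in genes.iterrows():
        if "tata_start" not in gene or pd.isna(gene["tata_start"]):
            continue
        start = int(gene["tata_start"])
        arr = coverage.norm[gene["chrom"]]
        lo, hi = max(start, 0), min(start + 8, len(arr))
        rows.append({"name": gene["name"], "tata_coverage": float(arr[lo:hi].sum())})
    return pd.DataFrame(rows)


def write_bedgraph(track: CoverageTrack, path, normalized: bool = True) -> None:
    """Write coverage as bedGraph (0-based half-open runs of equal value)."""
    cov = track.norm if normalized else track.raw
    with open(path, "w") as fh:
        for chrom in sorted(cov):
            arr = cov[chrom]
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")
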