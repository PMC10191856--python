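"""Fragment filtering, coverage, nucleosome calling and comparisons."""

import numpy as np
import pandas as pd
import pytest

from burstepi.mnase import (
    CoverageTrack,
    call_plus_one,
    filter_fragments,
    log2fc_matrix,
    make_coverage,
    metagene_profile,
    plus_one_shift,
    smoothing_sigma,
    tata_window_coverage,
)

HALF = 2000


def _frag(chrom, start, end):
    return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})


def _gene(name="g", chrom="chrI", strand="+", tss=5000, **extra):
    return pd.DataFrame([{"name": name, "chrom": chrom, "strand": strand, "tss": tss, **extra}])


def _array_coverage(size, tss, strand, peaks_rel, amp=100.0, width=30.0):
    """Nucleosome-array-like coverage with Gaussian bumps at TSS-oriented
    offsets (downstream positive)."""
    g = np.arange(size, dtype=float)
    cov = np.zeros(size)
    sign = 1 if strand == "+" else -1
    for rel in peaks_rel:
        center = tss + sign * rel
        cov += amp * np.exp(-((g - center) ** 2) / (2 * width**2))
    return cov


def _standard_peaks():
    # -1 at -180, +1 at +120, flanking array every 165 bp out past the window
    up = [-180 - 165 * k for k in range(12)]
    down = [120 + 165 * k for k in range(12)]
    return up + down


class TestFilterFragments:
    def test_inclusive_bounds(self):
        frags = pd.DataFrame(
            {
                "chrom": ["c"] * 5,
                "start": [0] * 5,
                "end": [94, 95, 150, 225, 226],
            }
        )
        kept = filter_fragments(frags)
        assert sorted(kept["end"]) == [95, 150, 225]

    def test_empty_input(self):
        assert len(filter_fragments(pd.DataFrame(columns=["chrom", "start", "end"]))) == 0


class TestMakeCoverage:
    def test_single_fragment_normalization(self):
        cov = make_coverage(_frag("chrI", 10, 25), {"chrI": 100})
        np.testing.assert_allclose(cov.norm["chrI"][10:25], 1 / 15)
        assert cov.norm["chrI"][:10].sum() == 0
        assert cov.norm["chrI"][25:].sum() == 0

    def test_duplicate_fragments_same_normalized_track(self):
        one = make_coverage(_frag("chrI", 10, 25), {"chrI": 100})
        two = make_coverage(
            pd.concat([_frag("chrI", 10, 25)] * 2, ignore_index=True), {"chrI": 100}
        )
        np.testing.assert_allclose(one.norm["chrI"], two.norm["chrI"])

    def test_per_chromosome_sums_to_one(self):
        frags = pd.concat(
            [_frag("chrI", 0, 50), _frag("chrI", 60, 90), _frag("chrII", 10, 40)],
            ignore_index=True,
        )
        cov = make_coverage(frags, {"chrI": 100, "chrII": 100})
        assert cov.norm["chrI"].sum() == pytest.approx(1.0, abs=1e-9)
        assert cov.norm["chrII"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_bounds_fragment_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            cov = make_coverage(_frag("chrI", 90, 120), {"chrI": 100})
        assert cov.raw["chrI"][90:].sum() == 10


class TestSmoothing:
    def test_fwhm_interpretation_default(self):
        assert smoothing_sigma(40.0) == pytest.approx(40.0 / (2 * np.sqrt(2 * np.log(2))))
        assert smoothing_sigma(40.0, mode="sigma") == 40.0


class TestCallPlusOne:
    def test_planted_geometry_recovered(self):
        cov = CoverageTrack.from_raw(
            {"chrI": _array_coverage(10000, 5000, "+", _standard_peaks())}
        )
        calls = call_plus_one([cov], _gene())
        row = calls.iloc[0]
        assert not row["excluded"]
        assert row["minus_one"] == pytest.approx(-180, abs=10)
        assert row["plus_one"] == pytest.approx(120, abs=10)
        assert row["ndr_width"] == pytest.approx(300, abs=15)

    def test_strand_symmetry(self):
        peaks = _standard_peaks()
        cov_w = CoverageTrack.from_raw({"chrI": _array_coverage(10000, 5000, "+", peaks)})
        cov_c = CoverageTrack.from_raw({"chrI": _array_coverage(10000, 5000, "-", peaks)})
        call_w = call_plus_one([cov_w], _gene(strand="+")).iloc[0]
        call_c = call_plus_one([cov_c], _gene(strand="-")).iloc[0]
        assert call_w["plus_one"] == pytest.approx(call_c["plus_one"], abs=1)
        assert call_w["minus_one"] == pytest.approx(call_c["minus_one"], abs=1)

    def test_single_peak_excluded(self):
        cov = CoverageTrack.from_raw({"chrI": _array_coverage(10000, 5000, "+", [50])})
        row = call_plus_one([cov], _gene()).iloc[0]
        assert row["excluded"] and row["reason"] == "fewer-than-two-peaks"

    def test_distant_peak_excluded(self):
        # upstream array then nothing until +1200: +1 lands beyond 1,000 bp
        peaks = [-200 - 165 * k for k in range(10)] + [1200, 1365, 1530]
        cov = CoverageTrack.from_raw({"chrI": _array_coverage(10000, 5000, "+", peaks)})
        row = call_plus_one([cov], _gene()).iloc[0]
        assert row["excluded"] and row["reason"] == "peak-beyond-1000bp"

    def test_gene_without_coverage_excluded(self):
        cov = CoverageTrack.from_raw({"chrI": np.zeros(10000)})
        row = call_plus_one([cov], _gene()).iloc[0]
        assert row["excluded"] and row["reason"] == "no-data"


class TestMetagene:
    def _setup(self):
        cov = CoverageTrack.from_raw(
            {"chrI": _array_coverage(10000, 5000, "+", _standard_peaks())}
        )
        calls = call_plus_one([cov], _gene())
        return cov, calls

    def test_single_gene_profile_equals_window(self):
        cov, calls = self._setup()
        prof = metagene_profile(cov, calls, _gene())
        assert prof.shape == (2000,)
        # peak of the +1 nucleosome sits at the window center
        center_region = prof[1000 - 20 : 1000 + 20]
        assert center_region.max() == prof[980:1020].max()
        assert prof[1000] > 0.8 * prof.max()

    def test_excluded_genes_contribute_nothing(self):
        cov, calls = self._setup()
        calls2 = pd.concat(
            [calls, pd.DataFrame([{"gene": "gx", "truncated": False, "minus_one": np.nan,
                                   "plus_one": np.nan, "ndr_width": np.nan,
                                   "excluded": True, "reason": "no-data"}])],
            ignore_index=True,
        )
        prof1 = metagene_profile(cov, calls, _gene())
        prof2 = metagene_profile(cov, calls2, _gene())
        np.testing.assert_allclose(prof1, prof2)

    def test_no_included_genes_rejected(self):
        cov, calls = self._setup()
        calls["excluded"] = True
        with pytest.raises(ValueError):
            metagene_profile(cov, calls, _gene())


class TestLog2FC:
    def _calls(self):
        cov = CoverageTrack.from_raw(
            {"chrI": _array_coverage(10000, 5000, "+", _standard_peaks())}
        )
        return call_plus_one([cov], _gene())

    def test_equal_conditions_zero_matrix(self):
        calls = self._calls()
        track = {"chrI": np.full(10000, 3.0)}
        mat = log2fc_matrix(track, [track], calls, _gene())
        np.testing.assert_allclose(mat.to_numpy(), 0.0, atol=1e-9)

    def test_doubled_coverage_log2_one(self):
        calls = self._calls()
        ctl = {"chrI": np.full(10000, 3.0)}
        dep = {"chrI": np.full(10000, 6.0)}
        mat = log2fc_matrix(dep, [ctl], calls, _gene())
        np.testing.assert_allclose(mat.to_numpy(), 1.0, atol=0.05)

    def test_rows_sorted_by_ndr_width(self):
        peaks_narrow = [-120 - 165 * k for k in range(12)] + [120 + 165 * k for k in range(12)]
        cov = CoverageTrack.from_raw(
            {
                "chrI": _array_coverage(20000, 5000, "+", _standard_peaks())
                + _array_coverage(20000, 15000, "+", peaks_narrow)
            }
        )
        genes = pd.concat([_gene("wide", tss=5000), _gene("narrow", tss=15000)], ignore_index=True)
        calls = call_plus_one([cov], genes)
        mat = log2fc_matrix(cov, [cov], calls, genes)
        assert list(mat.index) == ["narrow", "wide"]


class TestPlusOneShift:
    def test_identical_conditions_zero_shift(self):
        cov = CoverageTrack.from_raw(
            {"chrI": _array_coverage(10000, 5000, "+", _standard_peaks())}
        )
        calls = call_plus_one([cov], _gene())
        shifts, summary = plus_one_shift(calls, calls, None)
        assert shifts["shift"].tolist() == [0.0]
        assert summary["median"].tolist() == [0.0]

    def test_gene_excluded_in_depletion_dropped(self):
        cov = CoverageTrack.from_raw(
            {"chrI": _array_coverage(10000, 5000, "+", _standard_peaks())}
        )
        calls = call_plus_one([cov], _gene())
        dep = calls.copy()
        dep["excluded"] = True
        shifts, _ = plus_one_shift(dep, calls, None)
        assert len(shifts) == 0

    def test_planted_class_specific_shift(self):
        peaks_shifted = [-180 - 165 * k for k in range(12)] + [160 + 165 * k for k in range(12)]
        base = _array_coverage(20000, 5000, "+", _standard_peaks()) + _array_coverage(
            20000, 15000, "+", _standard_peaks()
        )
        dep = _array_coverage(20000, 5000, "+", peaks_shifted) + _array_coverage(
            20000, 15000, "+", _standard_peaks()
        )
        genes = pd.concat(
            [_gene("a", tss=5000, tata_class="TATA-mismatch"),
             _gene("b", tss=15000, tata_class="TATA")],
            ignore_index=True,
        )
        ref_calls = call_plus_one([CoverageTrack.from_raw({"chrI": base})], genes)
        dep_calls = call_plus_one([CoverageTrack.from_raw({"chrI": dep})], genes)
        shifts, summary = plus_one_shift(dep_calls, ref_calls, genes)
        med = summary.set_index("tata_class")["median"]
        assert med["TATA-mismatch"] == pytest.approx(40, abs=10)
        assert med["TATA"] == pytest.approx(0, abs=5)


class TestTataWindow:
    def test_uniform_coverage_sums_eight_bases(self):
        cov = CoverageTrack.from_raw({"chrI": np.ones(1000)})
        genes = _gene(tata_start=100, tss=200)
        out = tata_window_coverage(cov, genes)
        assert out["tata_coverage"].iloc[0] == pytest.approx(8 / 1000)

    def test_zero_coverage_window(self):
        raw = np.ones(1000)
        raw[100:108] = 0.0
        cov = CoverageTrack.from_raw({"chrI": raw})
        out = tata_window_coverage(cov, _gene(tata_start=100, tss=200))
        assert out["tata_coverage"].iloc[0] == 0.0

    def test_gene_without_window_skipped(self):
        cov = CoverageTrack.from_raw({"chrI": np.ones(1000)})
        genes = pd.concat(
            [_gene("a", tata_start=100, tss=200), _gene("b", tata_start=np.nan, tss=300)],
            ignore_index=True,
        )
        out = tata_window_coverage(cov, genes)
        assert out["name"].tolist() == ["a"]
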