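"""Coverage I/O, normalization, decay-profile extraction, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from parbcage import (
    BindingProfile,
    CoverageTrack,
    F_PLASMID,
    ParSSite,
    correlate,
    detect_dips,
    estimate_background,
    make_decay_profile,
    nc_density,
    normalize_input,
    read_bedgraph,
    read_profile_tsv,
    rescale_overlap,
    write_bedgraph,
    write_profile_tsv,
)
from parbcage.profile_io import BedGraphError


class TestBedGraph:
    def test_record_expansion(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t3\t5.0\n")
        track = read_bedgraph(p)
        assert track.counts.tolist() == [5.0, 5.0, 5.0]
        assert (track.start_bp, track.end_bp) == (0, 3)

    def test_adjacent_records_concatenate(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t2\t1\nchr1\t2\t5\t7\n")
        track = read_bedgraph(p)
        # brute-force per-bp fill oracle
        expect = np.zeros(5)
        for s, e, v in [(0, 2, 1.0), (2, 5, 7.0)]:
            expect[s:e] = v
        assert track.counts.tolist() == expect.tolist()

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("")
        assert len(read_bedgraph(p)) == 0

    @pytest.mark.parametrize(
        "content,msg",
        [
            ("chr1\t0\t3\n", "4 fields"),
            ("chr1\t-1\t3\t2\n", "negative"),
            ("chr1\t5\t3\t2\n", "inverted"),
            ("chr1\t0\t3\t2\nchr1\t2\t4\t1\n", "overlap"),
        ],
    )
    def test_malformed_input_reports_line(self, tmp_path, content, msg):
        p = tmp_path / "a.bedgraph"
        p.write_text(content)
        with pytest.raises(BedGraphError, match=msg):
            read_bedgraph(p)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=200))
    def test_roundtrip_lossless_for_integer_counts(self, counts):
        import tempfile, os

        track = CoverageTrack("c", 10, 10 + len(counts), np.array(counts, dtype=float))
        fd, path = tempfile.mkstemp(suffix=".bedgraph")
        os.close(fd)
        try:
            write_bedgraph(track, path)
            back = read_bedgraph(path)
            assert back.counts.tolist() == track.counts.tolist()
            assert (back.start_bp, back.end_bp) == (track.start_bp, track.end_bp)
        finally:
            os.unlink(path)


class TestNormalizeInput:
    def _tracks(self, ip_counts, in_counts):
        ip = CoverageTrack("c", 0, len(ip_counts), np.array(ip_counts, float))
        inp = CoverageTrack("c", 0, len(in_counts), np.array(in_counts, float))
        return ip, inp

    def test_equal_totals_unchanged(self):
        ip, inp = self._tracks([1, 2, 3], [2, 2, 2])
        assert normalize_input(ip, inp).counts.tolist() == [2, 2, 2]

    def test_double_total_halved(self):
        ip, inp = self._tracks([1, 2, 3], [4, 4, 4])
        assert normalize_input(ip, inp).counts.tolist() == [2, 2, 2]

    def test_scale_factor_arithmetic(self):
        ip, inp = self._tracks([500, 500], [300, 100])
        out = normalize_input(ip, inp)
        assert out.counts.tolist() == [750.0, 250.0]  # scale 1000/400 = 2.5

    def test_zero_input_total_rejected(self):
        ip, inp = self._tracks([1, 1], [0, 0])
        with pytest.raises(ValueError):
            normalize_input(ip, inp)


class TestEstimateBackground:
    def test_flat_track(self):
        track = CoverageTrack("c", 0, 60_000, np.full(60_000, 7.0))
        site = ParSSite(29_990, 30_010, 30_000)
        assert estimate_background(track, site, 10_000) == 7.0

    def test_peak_inside_exclusion_ignored(self):
        counts = np.full(60_000, 10.0)
        counts[29_000:31_000] = 500.0
        track = CoverageTrack("c", 0, 60_000, counts)
        site = ParSSite(29_990, 30_010, 30_000)
        assert estimate_background(track, site, 10_000) == 10.0

    def test_mixed_flanks_use_pooled_median(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, 60_000).astype(float)
        track = CoverageTrack("c", 0, 60_000, counts)
        site = ParSSite(29_990, 30_010, 30_000)
        pos = np.arange(60_000)
        flanks = counts[np.abs(pos - 30_000) > 10_000]
        assert estimate_background(track, site, 10_000) == np.median(flanks)

    def test_no_flank_rejected(self):
        track = CoverageTrack("c", 0, 100, np.ones(100))
        with pytest.raises(ValueError):
            estimate_background(track, ParSSite(40, 60, 50), 25_000)


class TestMakeDecayProfile:
    SITE = ParSSite(900, 1_000, 950)

    def test_single_spike_above_background(self):
        counts = np.full(2_000, 4.0)
        counts[1_000] = 10.0  # the anchor bp
        track = CoverageTrack("c", 0, 2_000, counts)
        prof = make_decay_profile(track, self.SITE, 4.0, side="right")
        assert prof.anchor_bp == 1_000
        assert prof.density[0] == 1.0
        assert np.all(prof.density[1:] == 0.0)

    def test_recovers_generating_decay(self, f_params):
        depth, bg = 1_000.0, 5.0
        pos = np.arange(0, 20_000)
        signal = np.where(
            pos >= 1_000, nc_density(np.abs(pos - 1_000), f_params), f_params.kappa
        )
        track = CoverageTrack("c", 0, 20_000, depth * signal + bg)
        prof = make_decay_profile(track, self.SITE, bg, side="right")
        expect = nc_density(prof.offsets_bp, f_params) / f_params.kappa
        assert prof.density == pytest.approx(expect, rel=1e-9)

    def test_left_and_right_sides_differ_for_asymmetric_repeats(self):
        counts = np.arange(2_000, dtype=float)
        track = CoverageTrack("c", 0, 2_000, counts)
        right = make_decay_profile(track, self.SITE, 0.0, side="right")
        left = make_decay_profile(track, self.SITE, 0.0, side="left")
        assert right.anchor_bp == 1_000 and left.anchor_bp == 899
        assert right.density[1] != left.density[1]
        # left offsets increase away from parS (toward lower coordinates)
        assert left.density[1] == pytest.approx(898.0 / 899.0)

    def test_anchor_conventions_differ_by_one_bp(self):
        counts = np.arange(2_000, dtype=float)
        track = CoverageTrack("c", 0, 2_000, counts)
        a = make_decay_profile(track, self.SITE, 0.0, anchor_convention="downstream")
        b = make_decay_profile(track, self.SITE, 0.0, anchor_convention="last_repeat_bp")
        assert a.anchor_bp - b.anchor_bp == 1

    def test_anchor_at_background_rejected(self):
        track = CoverageTrack("c", 0, 2_000, np.full(2_000, 3.0))
        with pytest.raises(ValueError, match="anchor"):
            make_decay_profile(track, self.SITE, 3.0)


class TestRescaleOverlap:
    def _profile(self, dens):
        return BindingProfile(np.arange(len(dens), dtype=float), np.asarray(dens))

    def test_tenfold_attenuation(self):
        ref = self._profile(np.linspace(1, 0.1, 100))
        target = self._profile(ref.density / 10.0)
        assert rescale_overlap(target, ref, (0, 99)) == pytest.approx(10.0)

    def test_identity(self):
        ref = self._profile(np.linspace(1, 0.1, 100))
        assert rescale_overlap(ref, ref, (0, 99)) == pytest.approx(1.0)

    def test_noisy_attenuation_close_to_closed_form(self):
        rng = np.random.default_rng(1)
        ref = self._profile(np.linspace(1, 0.1, 500))
        t = ref.density / 10.0 + rng.normal(0, 1e-3, 500)
        target = self._profile(np.abs(t))
        c = rescale_overlap(target, ref, (0, 499))
        assert c == pytest.approx(10.0, rel=0.05)

    def test_zero_target_rejected(self):
        ref = self._profile(np.linspace(1, 0.1, 100))
        target = self._profile(np.zeros(100))
        with pytest.raises(ValueError):
            rescale_overlap(target, ref, (0, 99))


class TestCorrelate:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert correlate(x, x) == pytest.approx(1.0)
        assert correlate(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert correlate([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-5)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_symmetric_and_affine_invariant(self, xs, a, b):
        rng = np.random.default_rng(0)
        x = np.asarray(xs)
        y = rng.normal(size=x.size)
        if np.ptp(x) < 1e-6:
            return
        assert correlate(x, y) == pytest.approx(correlate(y, x), rel=1e-9, abs=1e-12)
        assert correlate(a * x + b, y) == pytest.approx(correlate(x, y), rel=1e-9, abs=1e-9)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert correlate(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDetectDips:
    def _model_profile(self, f_params, modifier=None):
        s = np.arange(0.0, 12_000.0)
        dens = nc_density(s, f_params) / f_params.kappa
        if modifier is not None:
            dens = modifier(s, dens)
        return BindingProfile(s, dens, normalized=True)

    def test_model_profile_has_no_dips(self, f_params):
        prof = self._model_profile(f_params)
        assert detect_dips(prof, f_params) == []

    def test_suppressed_region_detected(self, f_params):
        def suppress(s, d):
            return np.where((s >= 5_000) & (s < 5_300), d * 0.2, d)

        prof = self._model_profile(f_params, suppress)
        dips = detect_dips(prof, f_params)
        assert len(dips) == 1
        lo, hi = dips[0]
        assert lo < 5_300 and hi > 5_000  # overlaps the suppressed region

    def test_zero_threshold_finds_nothing(self, f_params):
        def suppress(s, d):
            return np.where((s >= 5_000) & (s < 5_300), d * 0.2, d)

        prof = self._model_profile(f_params, suppress)
        assert detect_dips(prof, f_params, depth_threshold=0.0) == []


class TestProfileTsv:
    def test_roundtrip(self, tmp_path, mc_profile_small):
        path = tmp_path / "p.tsv"
        write_profile_tsv(mc_profile_small, path)
        back = read_profile_tsv(path)
        assert back.offsets_bp == pytest.approx(mc_profile_small.offsets_bp)
        assert back.density == pytest.approx(mc_profile_small.density, rel=1e-7)
        assert back.anchor_bp == mc_profile_small.anchor_bp
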