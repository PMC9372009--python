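"""Run data model, centroiding and EIC construction."""

import numpy as np
import pytest

import gcscreen as g
from gcscreen.errors import ParseError, ValidationError
from gcscreen.msdata import centroid_run


def profile(rt, pts):
    mz, inten = zip(*pts)
    return g.ProfileSpectrum(rt=rt, mz=np.array(mz), intensity=np.array(inten))


def centroid(rt, pts):
    mz, inten = zip(*pts)
    return g.CentroidSpectrum(rt=rt, mz=np.array(mz), intensity=np.array(inten))


class TestSpectrumInvariants:
    def test_profile_requires_increasing_mz(self):
        with pytest.raises(ValidationError):
            profile(0.0, [(100.0, 1.0), (100.0, 2.0)])

    def test_centroid_requires_positive_intensity(self):
        with pytest.raises(ValidationError):
            centroid(0.0, [(100.0, 0.0)])

    def test_run_requires_increasing_rts(self):
        s = centroid(5.0, [(100.0, 1.0)])
        with pytest.raises(ValidationError):
            g.Run(scans=[s, s])

    def test_run_scan_period_is_median_interval(self):
        scans = [centroid(t, [(100.0, 1.0)]) for t in (0.0, 0.2, 0.4, 0.62)]
        assert g.Run(scans=scans).scan_period == pytest.approx(0.2)


class TestCentroidProfile:
    def test_asymmetric_peak_weighted_mean(self):
        # hand-computed: (99.99*10 + 100.00*100 + 100.01*30) / 140 = 100.00142857
        spec = profile(1.0, [(99.99, 10.0), (100.00, 100.0), (100.01, 30.0)])
        cs = g.centroid_profile(spec, min_points=2)
        assert cs.mz == pytest.approx([100.00142857142858], abs=1e-9)
        assert cs.intensity == pytest.approx([100.0])

    def test_symmetric_triangle_centroids_at_apex(self):
        spec = profile(1.0, [(149.999, 50.0), (150.0, 100.0), (150.001, 50.0)])
        cs = g.centroid_profile(spec)
        assert cs.mz == pytest.approx([150.0], abs=1e-6)

    def test_two_separated_peaks_give_two_centroids(self):
        pts = [(100.000, 10.0), (100.002, 100.0), (100.004, 10.0),
               (200.000, 20.0), (200.002, 80.0), (200.004, 20.0)]
        cs = g.centroid_profile(profile(0.0, pts))
        assert len(cs) == 2

    def test_min_points_suppresses_narrow_regions(self):
        pts = [(100.0, 5.0), (150.0, 50.0), (150.001, 60.0), (150.002, 40.0)]
        cs = g.centroid_profile(profile(0.0, pts), min_points=2)
        assert len(cs) == 1 and cs.mz[0] == pytest.approx(150.001, abs=1e-3)

    def test_snr_floor_excludes_low_points(self):
        pts = [(99.998, 2.0), (100.0, 100.0), (100.002, 90.0), (100.004, 2.0)]
        with_floor = g.centroid_profile(profile(0.0, pts), snr_floor=10.0)
        assert with_floor.mz[0] == pytest.approx((100.0 * 100 + 100.002 * 90) / 190, abs=1e-9)

    def test_empty_input_gives_empty_output(self):
        cs = g.centroid_profile(profile(0.0, []) if False else
                                g.ProfileSpectrum(rt=0.0, mz=np.empty(0), intensity=np.empty(0)))
        assert len(cs) == 0

    def test_valley_splitting_within_contiguous_region(self):
        pts = [(100.000, 10.0), (100.002, 100.0), (100.004, 20.0),
               (100.006, 90.0), (100.008, 10.0)]
        cs = g.centroid_profile(profile(0.0, pts))
        assert len(cs) == 2

    def test_noiseless_simulated_profile_recovers_known_centroid(self):
        # recovery within half a profile sampling step
        from gcscreen.simdata import SimConfig, _render_profile

        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(0)
        for true_mz in (68.0, 150.0468, 388.1444, 502.0):
            mz, inten = _render_profile(np.array([true_mz]), np.array([1e5]), cfg, rng)
            cs = g.centroid_profile(g.ProfileSpectrum(rt=0, mz=mz, intensity=inten))
            step = cfg.profile_fwhm(true_mz) * cfg.profile_spacing
            assert len(cs) == 1
            assert abs(cs.mz[0] - true_mz) < step / 2


class TestExtractEics:
    def run_of(self, scan_peaks):
        scans = [centroid(0.2 * i, pk) for i, pk in enumerate(scan_peaks)]
        return g.Run(scans=scans)

    def test_single_mass_gives_single_trace(self):
        run = self.run_of([[(100.0, 10.0)], [(100.0, 20.0)], [(100.0, 15.0)]])
        eics = g.extract_eics(run, mz_delta=0.05)
        assert len(eics) == 1
        assert eics[0].target_mz == pytest.approx(100.0)
        assert eics[0].intensities == pytest.approx([10.0, 20.0, 15.0])

    def test_separation_beyond_window_gives_two_traces(self):
        run = self.run_of([[(100.0, 10.0)], [(100.2, 10.0)], [(100.0, 10.0)], [(100.2, 10.0)]])
        assert len(g.extract_eics(run, mz_delta=0.05)) == 2

    def test_slow_drift_stays_one_trace(self):
        # 10 scans drifting 100.000 -> 100.004, full window 0.05
        drift = [[(100.0 + 0.0004 * i, 50.0 + i)] for i in range(10)]
        eics = g.extract_eics(self.run_of(drift), mz_delta=0.05)
        assert len(eics) == 1
        mzs = [p[0][0] for p in drift]
        ints = [p[0][1] for p in drift]
        expected = np.average(mzs, weights=ints)
        assert eics[0].target_mz == pytest.approx(expected, abs=1e-9)

    def test_tic_conserved(self):
        rng = np.random.default_rng(5)
        scan_peaks = []
        for _ in range(20):
            n = rng.integers(1, 8)
            mz = np.sort(rng.uniform(50, 500, n))
            inten = rng.uniform(1, 1000, n)
            scan_peaks.append(list(zip(mz, inten)))
        run = self.run_of(scan_peaks)
        eics = g.extract_eics(run, mz_delta=0.05)
        for si, pk in enumerate(scan_peaks):
            tic = sum(i for _, i in pk)
            assert sum(e.intensities[si] for e in eics) == pytest.approx(tic, rel=1e-9)

    def test_profile_run_rejected(self):
        run = g.Run(scans=[profile(0.0, [(100.0, 1.0), (100.01, 2.0)])])
        with pytest.raises(TypeError, match="centroid"):
            g.extract_eics(run)


class TestRoundTrips:
    @pytest.fixture()
    def sim_run(self):
        from gcscreen.simdata import PlantedCompound, SimConfig, simulate_run

        p = PlantedCompound(
            name="x", rt=100.0, mz=np.array([100.0423, 250.1201]),
            rel=np.array([999.0, 400.0]), base_area=5e4,
        )
        run, _ = simulate_run([p], SimConfig(seed=1))
        return run

    @pytest.mark.parametrize("fmt,suffix", [("internal", "run.txt"), ("mzml", "mzml")])
    def test_write_read_roundtrip(self, sim_run, tmp_path, fmt, suffix):
        path = tmp_path / f"a.{suffix}"
        g.write_run(sim_run, path, format=fmt)
        back = g.read_run(path, format=fmt)
        assert len(back) == len(sim_run)
        assert back.is_profile
        for a, b in zip(sim_run.scans, back.scans):
            assert b.rt == pytest.approx(a.rt, abs=1e-9)
            np.testing.assert_allclose(b.mz, a.mz, rtol=1e-6)
            np.testing.assert_allclose(b.intensity, a.intensity, rtol=1e-6)

    def test_centroided_roundtrip_preserves_mode(self, sim_run, tmp_path):
        crun = centroid_run(sim_run)
        path = tmp_path / "c.mzml"
        g.write_run(crun, path)
        assert not g.read_run(path).is_profile

    @pytest.mark.parametrize("fmt", ["internal", "mzml"])
    def test_empty_run_roundtrip(self, tmp_path, fmt):
        run = g.Run(scans=[])
        path = tmp_path / ("e.run.txt" if fmt == "internal" else "e.mzml")
        g.write_run(run, path, format=fmt)
        assert len(g.read_run(path, format=fmt)) == 0

    def test_duplicate_rt_file_rejected(self, tmp_path):
        path = tmp_path / "dup.run.txt"
        path.write_text(
            "#gcscreen-run 1\n#mode centroid\n"
            "S 1.0 1\n100.0 5.0\nS 1.0 1\n100.0 6.0\n"
        )
        with pytest.raises(ValidationError):
            g.read_run(path)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            g.read_run(tmp_path / "nope.mzml")

    def test_garbage_internal_file_is_parse_error(self, tmp_path):
        path = tmp_path / "x.run.txt"
        path.write_text("not a run\n")
        with pytest.raises(ParseError):
            g.read_run(path)
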