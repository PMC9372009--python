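"""MSP library I/O, entry building from standards, RT-library migration."""

import numpy as np
import pytest

import gcscreen as g
from gcscreen.errors import AmbiguityError, NotFoundError, ParseError, ValidationError
from gcscreen.rical import ri_to_rt, rt_to_ri
from gcscreen.simdata import PlantedCompound, SimConfig, simulate_run


class TestMspIO:
    def test_small_fixture_parses(self, tmp_path):
        p = tmp_path / "lib.msp"
        p.write_text(
            "Name: Benzothiazole\nCASNO: 95-16-9\nRI: 1221.1\n"
            "Comments: class=industrial\nNum Peaks: 2\n135.0139 999\n108.0369 400\n\n"
            "Name: 2-Ethylhexyl salicylate, TMS\nRI: 1811\n"
            "Comments: derivatized=TMS\nNum Peaks: 1\n73.0468 999\n"
        )
        lib = g.read_msp(p)
        assert len(lib) == 2
        assert lib.get("Benzothiazole").ri == pytest.approx(1221.1)
        assert lib.get("2-Ethylhexyl salicylate, TMS").derivatized

    def test_roundtrip_on_simulated_library(self, tmp_path):
        lib = g.simulate_library(100, seed=9)
        path = tmp_path / "lib.msp"
        g.write_msp(lib, path)
        assert g.read_msp(path).entries == lib.entries

    def test_zero_peaks_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.msp"
        p.write_text("Name: X\nNum Peaks: 0\n")
        with pytest.raises(ParseError):
            g.read_msp(p)

    def test_count_mismatch_reports_line(self, tmp_path):
        p = tmp_path / "bad.msp"
        p.write_text("Name: X\nNum Peaks: 3\n100.0 999\n101.0 5\n")
        with pytest.raises(ParseError, match="line"):
            g.read_msp(p)

    def test_missing_num_peaks_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.msp"
        p.write_text("Name: X\n100.0 999\n")
        with pytest.raises(ParseError):
            g.read_msp(p)

    def test_base_peak_formatting_contract(self, tmp_path):
        e = g.LibraryEntry(name="Y", mz=np.array([150.0468]),
                           rel_intensity=np.array([999.0]), ri=1500.0)
        path = tmp_path / "one.msp"
        g.write_msp(g.SpectralLibrary(entries=[e]), path)
        assert "150.0468 999" in path.read_text()

    def test_duplicate_names_rejected(self):
        e = g.LibraryEntry(name="Y", mz=np.array([100.0]),
                           rel_intensity=np.array([999.0]), ri=1.0)
        with pytest.raises(ValidationError):
            g.SpectralLibrary(entries=[e, e])

    def test_entry_requires_normalized_base(self):
        with pytest.raises(ValidationError):
            g.LibraryEntry(name="Z", mz=np.array([100.0]),
                           rel_intensity=np.array([500.0]))

    def test_normalize_spectrum_helper(self):
        mz, rel = g.speclib.normalize_spectrum([200.0, 100.0], [10.0, 40.0])
        assert list(mz) == [100.0, 200.0]
        assert rel == pytest.approx([999.0, 249.75])

    def test_empty_library_roundtrip(self, tmp_path):
        path = tmp_path / "empty.msp"
        g.write_msp(g.SpectralLibrary(entries=[]), path)
        assert len(g.read_msp(path)) == 0


@pytest.fixture(scope="module")
def standard_run(full_calib):
    entry_mz = np.array([91.0542, 120.0575, 165.0699, 180.0934])
    entry_rel = np.array([999.0, 550.0, 300.0, 120.0])
    rt = float(ri_to_rt(1500.0, full_calib))
    planted = PlantedCompound(name="std", rt=rt, mz=entry_mz, rel=entry_rel,
                              base_area=1e6)
    run, _ = simulate_run([planted], SimConfig(seed=21))
    return run, rt, entry_mz, entry_rel


class TestBuildEntry:
    def test_entry_recovers_spectrum_and_ri(self, standard_run, full_calib):
        run, rt, mz, rel = standard_run
        entry = g.build_entry_from_run(run, expected_rt=rt, calib=full_calib,
                                       name="My standard")
        assert entry.name == "My standard"
        assert entry.ri == pytest.approx(1500.0, abs=2.0)
        # cosine vs the planted spectrum
        assert entry.mz == pytest.approx(mz, abs=0.01)
        a = entry.rel_intensity / np.linalg.norm(entry.rel_intensity)
        b = rel / np.linalg.norm(rel)
        assert float(a @ b) >= 0.99

    def test_no_component_near_rt_raises(self, standard_run, full_calib):
        run, rt, *_ = standard_run
        with pytest.raises(NotFoundError):
            g.build_entry_from_run(run, expected_rt=rt + 200.0, calib=full_calib,
                                   name="nothing here")

    def test_ambiguous_region_raises(self, full_calib):
        mz = np.array([91.0542, 120.0575, 165.0699])
        rel = np.array([999.0, 500.0, 300.0])
        p1 = PlantedCompound(name="a", rt=600.0, mz=mz, rel=rel, base_area=1e6)
        p2 = PlantedCompound(name="b", rt=610.0, mz=mz + 30.0, rel=rel, base_area=9e5)
        run, _ = simulate_run([p1, p2], SimConfig(seed=22))
        with pytest.raises(AmbiguityError):
            g.build_entry_from_run(run, expected_rt=605.0, calib=full_calib, name="which")

    def test_alkane_standard_gets_exact_hundreds(self, full_calib):
        from gcscreen.simdata import simulate_alkane_run

        run, calib, _ = simulate_alkane_run((14, 18), config=SimConfig(seed=23))
        rt16 = float(calib.rt[list(calib.carbon).index(16)])
        entry = g.build_entry_from_run(run, expected_rt=rt16, calib=calib, name="C16",
                                       rt_tolerance=10.0)
        assert entry.ri == pytest.approx(1600.0, abs=1.0)


class TestMigration:
    def make_rt_lib(self, n=15, seed=2):
        rng = np.random.default_rng(seed)
        entries = []
        for k in range(n):
            mz = np.sort(rng.uniform(50, 400, 5).round(4))
            rel = np.append(rng.uniform(50, 900, 4), 999.0)
            entries.append(g.LibraryEntry(
                name=f"P{k}", mz=mz, rel_intensity=np.sort(rel),
                rt=200.0 + 60.0 * k,
            ))
        return g.SpectralLibrary(entries=entries, source="rtlib")

    def test_exact_affine_recovery(self, full_calib):
        lib = self.make_rt_lib()
        a_true, b_true = 0.98, 6.0
        anchors = [(e.name, e.rt, a_true * e.rt + b_true) for e in lib.entries[:12]]
        migrated, fit = g.migrate_rt_library(lib, anchors, full_calib)
        assert fit.a == pytest.approx(a_true, abs=1e-9)
        assert fit.b == pytest.approx(b_true, abs=1e-9)
        assert np.max(np.abs(fit.residuals)) < 1e-9
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        e = migrated.entries[3]
        assert e.ri == pytest.approx(rt_to_ri(a_true * lib.entries[3].rt + b_true,
                                              full_calib), abs=1e-9)

    def test_identity_anchors_keep_ri_of_original_rt(self, full_calib):
        lib = self.make_rt_lib()
        anchors = [(e.name, e.rt, e.rt) for e in lib.entries[:5]]
        migrated, fit = g.migrate_rt_library(lib, anchors, full_calib)
        for orig, new in zip(lib.entries, migrated.entries):
            assert new.ri == pytest.approx(rt_to_ri(orig.rt, full_calib), abs=1e-9)

    def test_noisy_anchors_match_closed_form_ols_oracle(self, full_calib):
        lib = self.make_rt_lib()
        rng = np.random.default_rng(77)
        a_true, b_true = 1.02, -4.0
        chosen = lib.entries[:12]
        x = np.array([e.rt for e in chosen])
        y = a_true * x + b_true + rng.normal(0, 0.5, x.size)
        anchors = [(e.name, float(xi), float(yi)) for e, xi, yi in zip(chosen, x, y)]
        _, fit = g.migrate_rt_library(lib, anchors, full_calib)
        # closed-form least squares oracle
        xm, ym = x.mean(), y.mean()
        a_hat = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
        b_hat = float(ym - a_hat * xm)
        assert fit.a == pytest.approx(a_hat, abs=1e-9)
        assert fit.b == pytest.approx(b_hat, abs=1e-9)
        assert abs(fit.a - a_true) <= 3 * fit.se_a
        assert abs(fit.b - b_true) <= 3 * fit.se_b

    def test_too_few_anchors_rejected(self, full_calib):
        lib = self.make_rt_lib()
        with pytest.raises(ValidationError):
            g.migrate_rt_library(lib, [("P0", 200.0, 205.0)], full_calib)

    def test_unknown_anchor_named_in_error(self, full_calib):
        lib = self.make_rt_lib()
        with pytest.raises(ValidationError, match="Ghost"):
            g.migrate_rt_library(
                lib, [("P0", 200.0, 205.0), ("Ghost", 300.0, 305.0)], full_calib
            )
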