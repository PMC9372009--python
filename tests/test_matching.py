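"""Ion pairing, weighted forward/reverse match factors, RT penalty, hit selection."""

import math

import numpy as np
import pytest

import gcscreen as g
from gcscreen.errors import ConfigurationError
from gcscreen.matching import forward_reverse_scores
from gcscreen.rical import ri_to_rt

MP = g.MatchParams


def spec(pairs, rt=0.0):
    mz, inten = zip(*sorted(pairs))
    return g.CentroidSpectrum(rt=rt, mz=np.array(mz), intensity=np.array(inten))


def entry(pairs, name="E", **kw):
    mz, rel = zip(*sorted(pairs))
    return g.LibraryEntry(name=name, mz=np.array(mz), rel_intensity=np.array(rel), **kw)


def brute_force_weighted_cosine(q_pairs, l_pairs, mode):
    """Independent oracle: align by exact m/z, weight I^0.5 * mz^1.3."""
    q = dict(q_pairs)
    l = dict(l_pairs)
    keys = sorted(set(l) | set(q)) if mode == "forward" else sorted(l)
    num = qq = ll = 0.0
    for m in keys:
        a = math.sqrt(q.get(m, 0.0)) * m**1.3
        b = math.sqrt(l.get(m, 0.0)) * m**1.3
        num += a * b
        qq += a * a
        ll += b * b
    return num / math.sqrt(qq * ll) if qq > 0 and ll > 0 else 0.0


class TestMatchIons:
    def test_pair_within_tolerance(self):
        p = g.match_ions(spec([(100.0005, 10.0)]), entry([(100.0000, 999.0)]),
                         amt_ppm=50)
        assert len(p.pairs) == 1
        assert p.pairs[0][2] == pytest.approx(5.0, abs=1e-6)

    def test_beyond_tolerance_unmatched(self):
        p = g.match_ions(spec([(100.0100, 10.0)]), entry([(100.0000, 999.0)]),
                         amt_ppm=50)
        assert p.pairs == []
        assert p.unmatched_library == [0]

    def test_min_mz_excludes_low_ions_both_sides(self):
        q = spec([(29.0027, 100.0), (100.0, 50.0)])
        e = entry([(29.0027, 999.0), (100.0, 400.0)])
        p = g.match_ions(q, e, amt_ppm=50, min_mz=30.0)
        assert p.query_mz.tolist() == [100.0]
        assert p.lib_mz.tolist() == [100.0]
        assert len(p.pairs) == 1

    def test_one_to_one_conflict_resolved_by_smaller_ppm(self):
        q = spec([(99.9990, 10.0), (100.0002, 80.0)])
        e = entry([(100.0000, 999.0)])
        p = g.match_ions(q, e, amt_ppm=50)
        assert len(p.pairs) == 1
        qi, li, ppm = p.pairs[0]
        assert p.query_mz[qi] == pytest.approx(100.0002)


class TestMatchFactor:
    def test_identical_spectra_score_100_for_any_pwf(self):
        pairs = [(70.0, 300.0), (100.0, 999.0), (230.1, 120.0)]
        q, e = spec(pairs), entry(pairs)
        for pwf in (0.0, 0.1, 0.5, 1.0):
            assert g.match_factor(q, e, pwf=pwf) == pytest.approx(100.0, abs=1e-9)

    def test_reverse_ignores_extra_query_ions(self):
        lib_pairs = [(70.0, 300.0), (100.0, 999.0), (230.1, 120.0)]
        extra = [(55.5, 80.0), (81.2, 40.0), (120.8, 60.0), (150.6, 90.0), (310.9, 30.0)]
        q, e = spec(lib_pairs + extra), entry(lib_pairs)
        assert g.match_factor(q, e, pwf=0.0) == pytest.approx(100.0, abs=1e-9)

    def test_forward_equals_brute_force_cosine(self):
        lib_pairs = [(70.0, 300.0), (100.0, 999.0), (230.1, 120.0)]
        extra = [(55.5, 80.0), (81.2, 40.0), (120.8, 60.0), (150.6, 90.0), (310.9, 30.0)]
        q, e = spec(lib_pairs + extra), entry(lib_pairs)
        f_oracle = brute_force_weighted_cosine(lib_pairs + extra, lib_pairs, "forward")
        got = g.match_factor(q, e, pwf=1.0)
        assert got == pytest.approx(100.0 * f_oracle, abs=1e-9)
        assert got < 100.0

    def test_affine_in_pwf(self):
        lib_pairs = [(70.0, 300.0), (100.0, 999.0), (230.1, 120.0)]
        extra = [(55.5, 80.0), (150.6, 90.0)]
        q, e = spec(lib_pairs + extra), entry(lib_pairs)
        s0 = g.match_factor(q, e, pwf=0.0)
        s1 = g.match_factor(q, e, pwf=1.0)
        for pwf in (0.1, 0.25, 0.5, 0.75, 0.9):
            expect = pwf * s1 + (1 - pwf) * s0
            assert g.match_factor(q, e, pwf=pwf) == pytest.approx(expect, abs=1e-9)

    def test_reverse_at_least_forward_for_superset_query(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_lib = int(rng.integers(2, 8))
            lib_mz = np.sort(rng.uniform(40, 400, n_lib).round(3))
            lib_i = rng.uniform(10, 999, n_lib)
            lib_i[rng.integers(0, n_lib)] = 999.0
            extra_mz = np.sort(rng.uniform(401, 600, 3).round(3))
            q = spec(list(zip(lib_mz, lib_i)) + list(zip(extra_mz, rng.uniform(5, 500, 3))))
            e = entry(list(zip(lib_mz, lib_i)))
            p = g.match_ions(q, e)
            f, r = forward_reverse_scores(p)
            assert r >= f - 1e-12

    def test_scale_invariance(self):
        lib_pairs = [(70.0, 300.0), (100.0, 999.0), (230.1, 120.0)]
        q1 = spec([(m, i * 0.37) for m, i in lib_pairs] + [(55.5, 29.6)])
        q2 = spec([(m, i * 7100.0) for m, i in lib_pairs] + [(55.5, 568000.0)])
        e = entry(lib_pairs)
        for pwf in (0.0, 0.5, 1.0):
            assert g.match_factor(q1, e, pwf=pwf) == pytest.approx(
                g.match_factor(q2, e, pwf=pwf), abs=1e-9
            )

    def test_disjoint_spectra_score_zero(self):
        q = spec([(100.0, 999.0)])
        e = entry([(200.0, 999.0)])
        assert g.match_factor(q, e, pwf=0.5) == 0.0


class TestRtPenalty:
    def test_within_free_window_no_penalty(self):
        assert g.rt_penalty(10.0, MP(penalty_free_s=20, rt_range_s=20)) == 1.0

    def test_beyond_range_rejected(self):
        assert g.rt_penalty(25.0, MP(penalty_free_s=20, rt_range_s=20)) is None

    def test_linear_ramp(self):
        # (20-10)/(30-10) * 20 = 10 penalty points -> multiplier 0.90
        p = MP(penalty_free_s=10, rt_range_s=30, max_rt_penalty=20)
        assert g.rt_penalty(20.0, p) == pytest.approx(0.90, abs=1e-12)
        assert g.rt_penalty(-20.0, p) == pytest.approx(0.90, abs=1e-12)
        assert g.rt_penalty(30.0, p) == pytest.approx(0.80, abs=1e-12)

    def test_soft_mode_applies_max_penalty(self):
        p = MP(penalty_free_s=10, rt_range_s=30, max_rt_penalty=20, hard_reject=False)
        assert g.rt_penalty(100.0, p) == pytest.approx(0.80)

    def test_invalid_window_combination_rejected(self):
        with pytest.raises(Exception):
            MP(penalty_free_s=30, rt_range_s=20)


class TestIdentify:
    def comp(self, pairs, rt):
        return g.Component(apex_rt=rt, ions=list(pairs),
                           base_area=max(i for _, i in pairs),
                           model_shape=np.ones(5))

    def lib_of(self, *entries):
        return g.SpectralLibrary(entries=list(entries), source="test")

    def test_exact_match_at_expected_ri(self, full_calib):
        pairs = [(70.0, 300.0), (100.0, 999.0), (230.1, 120.0)]
        e = entry(pairs, name="target", ri=1500.0)
        c = self.comp(pairs, rt=float(ri_to_rt(1500.0, full_calib)))
        ids = g.identify([c], self.lib_of(e), full_calib, MP())
        assert len(ids) == 1
        assert ids[0].final_score == pytest.approx(100.0, abs=1e-9)
        assert ids[0].penalty_multiplier == 1.0

    def test_subthreshold_hit_dropped(self, full_calib):
        e = entry([(70.0, 999.0), (100.0, 800.0), (230.1, 700.0), (300.2, 600.0)],
                  name="target", ri=1500.0)
        c = self.comp([(70.0, 999.0)], rt=float(ri_to_rt(1500.0, full_calib)))
        ids = g.identify([c], self.lib_of(e), full_calib, MP(min_match_factor=75))
        assert ids == []

    def test_max_hits_keeps_best(self, full_calib):
        pairs = [(70.0, 300.0), (100.0, 999.0)]
        e1 = entry(pairs, name="right", ri=1500.0)
        e2 = entry([(70.0, 300.0), (100.0, 999.0), (150.0, 500.0)], name="partial",
                   ri=1500.0)
        c = self.comp(pairs, rt=float(ri_to_rt(1500.0, full_calib)))
        ids = g.identify([c], self.lib_of(e1, e2), full_calib, MP(max_hits=1))
        assert [h.entry_name for h in ids] == ["right"]

    def test_isomers_resolved_by_ri(self):
        # identical spectra, RIs 41 units apart; 72 s per 100 RI makes the
        # wrong isomer 29.5 s away -> beyond the 20 s search range -> rejected
        calib = g.AlkaneCalibration(
            carbon=np.arange(7, 41), rt=100.0 + 72.0 * (np.arange(7, 41) - 7)
        )
        pairs = [(149.0233, 999.0), (205.0859, 300.0), (223.0965, 150.0)]
        iso1 = entry(pairs, name="di-iso", ri=1546.0)
        iso2 = entry(pairs, name="di-n", ri=1587.0)
        lib = self.lib_of(iso1, iso2)
        for ri, expect in ((1546.0, "di-iso"), (1587.0, "di-n")):
            c = self.comp(pairs, rt=float(ri_to_rt(ri, calib)))
            ids = g.identify([c], lib, calib, MP())
            assert [h.entry_name for h in ids] == [expect]
            assert ids[0].penalty_multiplier == 1.0

    def test_final_score_non_increasing_in_delta_rt(self, full_calib):
        pairs = [(70.0, 300.0), (100.0, 999.0), (230.1, 120.0)]
        e = entry(pairs, name="t", ri=1500.0)
        base_rt = float(ri_to_rt(1500.0, full_calib))
        params = MP(penalty_free_s=5, rt_range_s=25, max_rt_penalty=20,
                    min_match_factor=0)
        scores = []
        for d in (0.0, 3.0, 8.0, 15.0, 24.0):
            ids = g.identify([self.comp(pairs, rt=base_rt + d)],
                             self.lib_of(e), full_calib, params)
            scores.append(ids[0].final_score)
        assert scores == sorted(scores, reverse=True)
        assert scores[0] == pytest.approx(scores[1])  # inside free window

    def test_entry_without_retention_is_flagged(self):
        pairs = [(70.0, 300.0), (100.0, 999.0)]
        e = entry(pairs, name="no-rt")
        c = self.comp(pairs, rt=500.0)
        ids = g.identify([c], self.lib_of(e), calib=None, params=MP())
        assert len(ids) == 1
        assert not ids[0].rt_evidence
        assert ids[0].penalty_multiplier == 1.0

    def test_ri_library_without_calibration_is_configuration_error(self):
        e = entry([(100.0, 999.0)], name="ri-only", ri=1400.0)
        c = self.comp([(100.0, 999.0)], rt=500.0)
        with pytest.raises(ConfigurationError):
            g.identify([c], self.lib_of(e), calib=None, params=MP())

    def test_two_libraries_merge_with_provenance(self, full_calib):
        pairs = [(70.0, 300.0), (100.0, 999.0)]
        e1 = entry(pairs, name="in-house hit", ri=1500.0)
        e2 = entry([(300.0, 999.0)], name="pesticide miss", ri=1500.0)
        lib1 = g.SpectralLibrary(entries=[e1], source="inhouse")
        lib2 = g.SpectralLibrary(entries=[e2], source="pesticides")
        c = self.comp(pairs, rt=float(ri_to_rt(1500.0, full_calib)))
        ids = g.identify([c], [(lib1, MP()), (lib2, MP(rt_range_s=30,
                                                      penalty_free_s=30,
                                                      max_rt_penalty=30))],
                         full_calib)
        assert [h.library for h in ids] == ["inhouse"]
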