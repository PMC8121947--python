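import numpy as np
import pytest

from ribostall import (
    PipelineConfig,
    build_ratio_table,
    gene_scores,
    pause_ratios,
    pause_scores,
)

from conftest import make_orf, rpm_track


@pytest.fixture
def orf300():
    return make_orf("g", "A" * 300)


class TestGeneScores:
    def test_rpkm_from_rpm_sum(self, orf300):
        rpm = np.zeros(300)
        rpm[:30] = 1.0  # 30 rpm total over a 0.3 kb gene
        [g] = gene_scores(rpm_track({"g": rpm}), [orf300])
        assert g.rpkm == pytest.approx(100.0)
        assert g.active

    def test_zero_coverage_gene_inactive(self, orf300):
        [g] = gene_scores(rpm_track({"g": np.zeros(300)}), [orf300])
        assert g.rpkm == 0.0 and not g.active

    def test_rpkm_depth_invariance(self, orf300):
        rpm = np.random.default_rng(0).random(300)
        a = gene_scores(rpm_track({"g": rpm}), [orf300])[0].rpkm
        b = gene_scores(rpm_track({"g": rpm.copy()}, total=2_000_000), [orf300])[0].rpkm
        assert a == pytest.approx(b)  # rpm is already depth-normalized


class TestPauseScores:
    def test_uniform_coverage_scores_one(self, orf300):
        prof = pause_scores(rpm_track({"g": np.full(300, 2.5)}), orf300)
        np.testing.assert_allclose(prof.nt_scores, 1.0)
        np.testing.assert_allclose(prof.codon_scores, 1.0)

    def test_single_spike_scores(self):
        orf = make_orf("g", "A" * 30)
        rpm = np.zeros(30)
        rpm[0] = 30.0
        # gene mean rpm = 1, so the spike scores 30 and its codon 30/3 = 10
        prof = pause_scores(rpm_track({"g": rpm}), orf)
        assert prof.nt_scores[0] == pytest.approx(30.0)
        assert prof.nt_scores[1:].sum() == 0
        assert prof.codon_scores[0] == pytest.approx(10.0)

    def test_codon_score_is_nucleotide_mean(self):
        orf = make_orf("g", "A" * 6)
        prof = pause_scores(rpm_track({"g": [1.0, 2.0, 3.0, 2.0, 2.0, 2.0]}), orf)
        # mean rpm = 2 -> nt scores (0.5,1,1.5,...) -> codon 0 mean 1.0
        assert prof.codon_scores[0] == pytest.approx(1.0)

    def test_mean_score_conservation(self):
        rng = np.random.default_rng(1)
        orf = make_orf("g", "A" * 90)
        prof = pause_scores(rpm_track({"g": rng.random(90) * 10}), orf)
        assert prof.nt_scores.mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_gene_has_no_profile(self, orf300):
        assert pause_scores(rpm_track({"g": np.zeros(300)}), orf300) is None


class TestPauseRatios:
    def make_profiles(self, t_rpm, c_rpm, config=None):
        config = config or PipelineConfig()
        orf = make_orf("g", "A" * len(t_rpm))
        tp = pause_scores(rpm_track(t_rpm_dict := {"g": t_rpm}, condition="treated"), orf, config)
        cp = pause_scores(rpm_track({"g": c_rpm}, condition="control"), orf, config)
        return tp, cp

    def test_simple_ratio(self):
        t = np.full(30, 2.0)
        c = np.full(30, 2.0)
        t[:3] = 10.0  # codon 0 stands out in treated
        tp, cp = self.make_profiles(t, c)
        ratios = pause_ratios(tp, cp)
        # treated mean = 2.8 -> codon0 score 10/2.8; control codon0 score 1
        assert ratios[0] == pytest.approx((10.0 / 2.8) / 1.0)

    def test_identical_tracks_give_unit_ratios(self):
        rng = np.random.default_rng(2)
        x = rng.random(60) * 5 + 1
        tp, cp = self.make_profiles(x, x.copy())
        ratios = pause_ratios(tp, cp)
        assert ratios  # non-empty
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_reciprocity(self):
        rng = np.random.default_rng(3)
        a = rng.random(60) * 5 + 1
        b = rng.random(60) * 5 + 1
        tp, cp = self.make_profiles(a, b)
        fwd = pause_ratios(tp, cp)
        rev = pause_ratios(cp, tp)
        for j, r in fwd.items():
            assert r * rev[j] == pytest.approx(1.0)

    def test_inclusion_threshold_drops_codons(self):
        t = np.full(30, 5.0)
        c = np.full(30, 5.0)
        c[3:6] = 0.2  # codon 1 below 0.5 rpm in control at every nt
        tp, cp = self.make_profiles(t, c)
        assert 1 not in pause_ratios(tp, cp)

    def test_one_covered_nucleotide_keeps_codon(self):
        t = np.full(30, 5.0)
        c = np.full(30, 5.0)
        c[3:5] = 0.0  # codon 1 retains one nt above threshold
        tp, cp = self.make_profiles(t, c)
        assert 1 in pause_ratios(tp, cp)

    def test_stop_codon_never_a_site(self):
        t = np.full(30, 5.0)
        tp, cp = self.make_profiles(t, t.copy())
        assert 9 not in pause_ratios(tp, cp)  # last codon of a 10-codon ORF

    def test_depth_rescaling_leaves_ratios_unchanged(self):
        rng = np.random.default_rng(4)
        a = rng.random(60) * 5 + 1
        b = rng.random(60) * 5 + 1
        tp, cp = self.make_profiles(a, b)
        tp2, cp2 = self.make_profiles(a * 3, b * 3)
        r1, r2 = pause_ratios(tp, cp), pause_ratios(tp2, cp2)
        assert set(r1) == set(r2)
        for j in r1:
            assert r1[j] == pytest.approx(r2[j])


class TestBruteForceOracle:
    def test_all_quantities_by_direct_summation(self):
        """Pause scores, codon scores and ratios recomputed independently."""
        rng = np.random.default_rng(7)
        cfg = PipelineConfig()
        orfs = [make_orf(f"g{i}", "A" * int(n)) for i, n in enumerate([30, 60, 90])]
        for orf in orfs:
            t = rng.integers(0, 40, len(orf.nt_seq)).astype(float)
            c = rng.integers(0, 40, len(orf.nt_seq)).astype(float)
            if t.mean() == 0 or c.mean() == 0:
                continue
            tp = pause_scores(rpm_track({orf.orf_id: t}), orf, cfg)
            cp = pause_scores(rpm_track({orf.orf_id: c}), orf, cfg)
            got = pause_ratios(tp, cp, cfg)
            n_codons = len(orf.nt_seq) // 3
            for j in range(n_codons - 1):
                t_sc = sum(t[3 * j + k] / t.mean() for k in range(3)) / 3
                c_sc = sum(c[3 * j + k] / c.mean() for k in range(3)) / 3
                included = any(
                    t[3 * j + k] >= 0.5 and c[3 * j + k] >= 0.5 for k in range(3)
                )
                if included and c_sc > 0:
                    assert got[j] == pytest.approx(t_sc / c_sc, abs=1e-9)
                else:
                    assert j not in got


class TestRatioTable:
    def test_identical_conditions_all_unit(self):
        rng = np.random.default_rng(8)
        orf = make_orf("g", "A" * 150)
        x = rng.random(150) * 8 + 1
        tracks = {
            "t1": rpm_track({"g": x}, "t1", "treated", 1, total=10**6),
            "t2": rpm_track({"g": x}, "t2", "treated", 2, total=10**6),
            "c1": rpm_track({"g": x}, "c1", "control", 1, total=10**6),
            "c2": rpm_track({"g": x}, "c2", "control", 2, total=10**6),
        }
        cfg = PipelineConfig(min_gene_rpkm=1.0)
        table = build_ratio_table(tracks, [orf], cfg)
        assert len(table) == 49  # 50 codons minus the stop
        np.testing.assert_allclose(table.ratio_rep1, 1.0)
        np.testing.assert_allclose(table.ratio_rep2, 1.0)

    def test_inactive_gene_excluded(self):
        orf = make_orf("g", "A" * 150)
        low = np.full(150, 0.001)
        tracks = {
            "t1": rpm_track({"g": low}, "t1", "treated", 1),
            "c1": rpm_track({"g": low}, "c1", "control", 1),
        }
        table = build_ratio_table(tracks, [orf], PipelineConfig(min_gene_rpkm=5.0))
        assert table.empty

    def test_requires_both_conditions(self):
        orf = make_orf("g", "A" * 30)
        tracks = {"t1": rpm_track({"g": np.ones(30)}, "t1", "treated", 1)}
        with pytest.raises(ValueError, match="control"):
            build_ratio_table(tracks, [orf])
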