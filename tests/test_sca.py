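import numpy as np
import pandas as pd
import pytest

from bemut.sca import (
    CLASS_CN,
    arm_sca_load,
    classify_segment,
    focal_amp_prevalence_test,
    genome_doubling_flag,
    segment_and_call,
    synthetic_track,
    true_class_per_base,
)


class TestClassifySegment:
    @pytest.mark.parametrize(
        "total,minor,length,expected",
        [
            (0, 0, 5e6, "HD"),
            (1, 0, 5e6, "loss"),
            (2, 0, 5e6, "cnLOH"),
            (2, 1, 5e6, "diploid"),
            (3, 1, 5e6, "allele_gain"),
            (4, 2, 5e6, "balanced_gain"),
            (4, 1, 5e6, "allele_gain"),
            (6, 1, 1.5e6, "focal_amp"),
            (6, 1, 5e6, "allele_gain"),  # too long for focal
            (8, 1, 1.5e6, "focal_amp"),
            (8, 4, 5e6, "balanced_gain"),
        ],
    )
    def test_definitional_table(self, total, minor, length, expected):
        assert classify_segment(total, minor, length) == expected

    def test_ploidy_four_recalibration(self):
        assert classify_segment(4, 2, 5e6, ploidy=4) == "diploid"
        assert classify_segment(4, 0, 5e6, ploidy=4) == "cnLOH"
        assert classify_segment(2, 1, 5e6, ploidy=4) == "loss"

    def test_minor_bound_enforced(self):
        with pytest.raises(ValueError, match="minor"):
            classify_segment(2, 2, 5e6)

    def test_every_lattice_point_gets_exactly_one_class(self):
        classes = {"HD", "loss", "cnLOH", "balanced_gain", "allele_gain",
                   "focal_amp", "diploid"}
        for total in range(0, 9):
            for minor in range(0, total // 2 + 1):
                for length in (1e6, 5e6):
                    assert classify_segment(total, minor, length) in classes


class TestSegmentAndCall:
    def test_noise_free_deletion_exact(self):
        tr = synthetic_track([(40_000_000, 50_000_000, 1, 0)],
                             span=(0, 100_000_000), spacing=20_000)
        segs = segment_and_call(tr, "P")
        assert len(segs) == 3
        mid = segs.iloc[1]
        assert (mid["total_cn"], mid["minor_cn"], mid["class"]) == (1, 0, "loss")
        # breakpoints exact to within one probe spacing
        assert abs(mid["start"] - 40_000_000) <= 20_000
        assert abs(mid["end"] - 50_000_000) <= 20_120

    def test_noise_free_cnloh(self):
        tr = synthetic_track([(20_000_000, 40_000_000, 2, 0)],
                             span=(0, 100_000_000), spacing=20_000)
        segs = segment_and_call(tr, "P")
        assert list(segs["class"]) == ["diploid", "cnLOH", "diploid"]

    def test_noisy_track_base_accuracy(self):
        truth = [
            (10_000_000, 14_000_000, 1, 0),
            (30_000_000, 35_000_000, 2, 0),
            (50_000_000, 53_000_000, 3, 1),
            (70_000_000, 74_000_000, 4, 2),
            (90_000_000, 91_500_000, 8, 1),
        ]
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            tr = synthetic_track(truth, span=(0, 100_000_000), spacing=20_000,
                                 lr_sigma=0.25, baf_sigma=0.03, rng=rng)
            segs = segment_and_call(tr, "P")
            grid = np.arange(0, 100_000_000, 10_000)
            want = np.empty(len(grid), dtype=object)
            for a, b, c in true_class_per_base(truth, (0, 100_000_000)):
                want[(grid >= a) & (grid < b)] = c
            got = np.full(len(grid), "diploid", dtype=object)
            for _, r in segs.iterrows():
                got[(grid >= r["start"]) & (grid < r["end"])] = r["class"]
            accs.append((got == want).mean())
        assert min(accs) >= 0.95

    def test_short_chromosome_skipped(self):
        tr = synthetic_track([], span=(0, 500_000), spacing=20_000)
        segs = segment_and_call(tr, "P")
        assert len(segs) == 0  # < 50 probes

    def test_finite_log_ratio_required(self):
        tr = synthetic_track([], span=(0, 10_000_000), spacing=20_000)
        tr.loc[0, "log_ratio"] = np.inf
        with pytest.raises(ValueError, match="finite"):
            segment_and_call(tr, "P")


class TestArmLoads:
    @staticmethod
    def _arms():
        df = pd.DataFrame(
            {"chrom": ["1", "1"], "arm": ["p", "q"],
             "start": [0, 60_000_000], "end": [50_000_000, 110_000_000]}
        )
        df["length_mb"] = (df["end"] - df["start"]) / 1e6
        return df

    @staticmethod
    def _seg(pid, start, end, cls):
        total, minor = CLASS_CN[cls]
        return {
            "patient_id": pid, "chrom": "1", "start": start, "end": end,
            "n_probes": np.nan, "log_ratio": np.nan,
            "total_cn": total, "minor_cn": minor, "class": cls,
        }

    def test_simple_load(self):
        segs = pd.DataFrame([self._seg("P", 10_000_000, 20_000_000, "loss")])
        out = arm_sca_load(segs, self._arms()).set_index(["patient_id", "arm", "class"])
        row = out.loc[("P", "1p", "loss")]
        assert row["mb"] == pytest.approx(10.0)
        assert row["n_per_mb"] == pytest.approx(1 / 50)

    def test_diploid_genome_empty(self):
        segs = pd.DataFrame([self._seg("P", 0, 50_000_000, "loss")]).iloc[:0]
        assert len(arm_sca_load(segs, self._arms())) == 0

    def test_boundary_crossing_split_and_mb_conserved(self):
        segs = pd.DataFrame([self._seg("P", 40_000_000, 80_000_000, "cnLOH")])
        out = arm_sca_load(segs, self._arms())
        # 10 Mb on 1p, 20 Mb on 1q (centromeric 10 Mb gap uncounted)
        by_arm = out.set_index("arm")["mb"]
        assert by_arm["1p"] == pytest.approx(10.0)
        assert by_arm["1q"] == pytest.approx(20.0)

    def test_additive_under_segment_splitting(self):
        whole = pd.DataFrame([self._seg("P", 10_000_000, 30_000_000, "loss")])
        split = pd.DataFrame([
            self._seg("P", 10_000_000, 18_000_000, "loss"),
            self._seg("P", 18_000_000, 30_000_000, "loss"),
        ])
        a = arm_sca_load(whole, self._arms())
        b = arm_sca_load(split, self._arms())
        assert a["mb"].sum() == pytest.approx(b["mb"].sum())

    def test_cohort_mb_matches_bruteforce_overlap(self, small_cohort, arm_table):
        segs = small_cohort["segments"]
        out = arm_sca_load(segs, arm_table)
        # brute force: sum of per-(segment, arm) overlaps
        expected = 0.0
        for s in segs.itertuples(index=False):
            for a in arm_table.itertuples(index=False):
                if str(a.chrom) == str(s.chrom):
                    expected += max(0, min(s.end, a.end) - max(s.start, a.start))
        assert out["mb"].sum() == pytest.approx(expected / 1e6)


class TestGenomeDoubling:
    def _segs(self, fraction, arm_table, total=4, minor=2):
        rows = []
        need = fraction * (arm_table["end"] - arm_table["start"]).sum()
        got = 0.0
        for a in arm_table.itertuples(index=False):
            if got >= need:
                break
            take = min(a.end - a.start, need - got)
            rows.append({
                "patient_id": "P", "chrom": a.chrom, "start": a.start,
                "end": int(a.start + take), "n_probes": np.nan, "log_ratio": np.nan,
                "total_cn": total, "minor_cn": minor, "class": "balanced_gain",
            })
            got += take
        return pd.DataFrame(rows)

    def test_fully_diploid_false(self, arm_table):
        empty = self._segs(0.0, arm_table)
        assert genome_doubling_flag(empty, arm_table) is False

    def test_whole_genome_doubled_true(self, arm_table):
        assert genome_doubling_flag(self._segs(1.0, arm_table), arm_table) is True

    def test_sixty_percent_major_two_true(self, arm_table):
        assert genome_doubling_flag(self._segs(0.6, arm_table), arm_table) is True
        assert genome_doubling_flag(self._segs(0.4, arm_table), arm_table) is False

    def test_unknown_when_minor_unassessable(self, arm_table):
        segs = self._segs(0.6, arm_table)
        segs["minor_cn"] = np.nan
        assert genome_doubling_flag(segs, arm_table) is None


class TestFocalAmpPrevalence:
    def test_0_of_41_vs_8_of_41(self):
        meta = pd.DataFrame(
            {
                "patient_id": [f"U{i}" for i in range(41)] + [f"N{i}" for i in range(41)],
                "nsaid_user": [True] * 41 + [False] * 41,
            }
        )
        rows = [
            {
                "patient_id": f"N{i}", "chrom": "1", "start": 1_000_000,
                "end": 2_000_000, "n_probes": np.nan, "log_ratio": np.nan,
                "total_cn": 8, "minor_cn": 1, "class": "focal_amp",
            }
            for i in range(8)
        ]
        res = focal_amp_prevalence_test(pd.DataFrame(rows), meta)
        assert res.p_value == pytest.approx(5.3616e-3, rel=1e-3)
        assert res.detail["users_with_amp"] == 0
        assert res.detail["nonusers_with_amp"] == 8

    def test_no_amps_anywhere_p_one(self):
        meta = pd.DataFrame(
            {"patient_id": ["a", "b"], "nsaid_user": [True, False]}
        )
        empty = pd.DataFrame(columns=["patient_id", "class"])
        assert focal_amp_prevalence_test(empty, meta).p_value == 1.0
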