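import numpy as np
import pandas as pd
import pytest

from cardiomr.sumstats import (LDTable, SummaryStats, define_loci,
                               genomic_control_correct, ivw_meta, meta_subtract,
                               neff_filter, prune_independent, replication_flags)

from conftest import make_sumstats


class TestIVWMeta:
    def test_equal_weight_symmetry(self):
        a = make_sumstats([dict(BETA=1.0, SE=1.0)])
        b = make_sumstats([dict(BETA=3.0, SE=1.0)])
        m = ivw_meta([a, b]).table.iloc[0]
        assert m["BETA"] == pytest.approx(2.0)
        assert m["SE"] == pytest.approx(1 / np.sqrt(2))

    def test_single_study_passthrough(self):
        a = make_sumstats([dict(BETA=0.2, SE=0.05), dict(BETA=-0.1, SE=0.02)])
        m = ivw_meta([a])
        pd.testing.assert_frame_equal(m.table, a.table)

    def test_matches_closed_form_weights(self):
        # three studies at one variant vs the explicit weight formula
        studies = [make_sumstats([dict(BETA=b, SE=s)])
                   for b, s in [(0.1, 0.01), (0.2, 0.02), (0.0, 0.05)]]
        m = ivw_meta(studies).table.iloc[0]
        w = np.array([1 / 0.01**2, 1 / 0.02**2, 1 / 0.05**2])
        b = np.array([0.1, 0.2, 0.0])
        assert m["BETA"] == pytest.approx((w * b).sum() / w.sum(), rel=1e-12)
        assert m["SE"] == pytest.approx(1 / np.sqrt(w.sum()), rel=1e-12)
        assert m["N"] == pytest.approx(30_000)

    def test_pooled_se_never_above_min_input(self, rng):
        studies = []
        for _ in range(3):
            ses = rng.uniform(0.01, 0.1, 5)
            studies.append(make_sumstats(
                [dict(BETA=rng.normal(), SE=s) for s in ses]))
        m = ivw_meta(studies)
        for i, row in m.table.iterrows():
            min_se = min(s.table.iloc[i]["SE"] for s in studies)
            assert row["SE"] <= min_se + 1e-12

    def test_k_identical_studies_shrink_se_by_sqrt_k(self):
        a = make_sumstats([dict(BETA=0.3, SE=0.04)])
        for k in (2, 4):
            m = ivw_meta([a] * k).table.iloc[0]
            assert m["BETA"] == pytest.approx(0.3)
            assert m["SE"] == pytest.approx(0.04 / np.sqrt(k))

    def test_allele_swap_aligned(self):
        a = make_sumstats([dict(BETA=0.1, SE=0.01, EA="A", OA="G", EAF=0.3)])
        b = make_sumstats([dict(BETA=-0.1, SE=0.01, EA="G", OA="A", EAF=0.7)])
        m = ivw_meta([a, b]).table.iloc[0]
        assert m["BETA"] == pytest.approx(0.1)

    def test_variant_in_one_study_flagged(self):
        a = make_sumstats([dict(SNP="rs1"), dict(SNP="rs2")])
        b = make_sumstats([dict(SNP="rs1")])
        m = ivw_meta([a, b])
        flags = m.table.set_index("SNP")["SINGLE_STUDY"]
        assert not flags["rs1"] and flags["rs2"]


class TestGenomicControl:
    def test_identity_intercept(self):
        a = make_sumstats([dict(BETA=0.1, SE=0.01)])
        out = genomic_control_correct(a, 1.0)
        assert out.table.iloc[0]["SE"] == pytest.approx(0.01)
        assert out.gc_intercept_applied == 1.0

    def test_ukb_intercept_value(self):
        # SE 0.01 under the 1.132 LD-score intercept
        a = make_sumstats([dict(BETA=0.1, SE=0.01)])
        out = genomic_control_correct(a, 1.132)
        assert out.table.iloc[0]["SE"] == pytest.approx(0.010640, abs=1e-6)

    def test_p_monotone_when_inflating(self, rng):
        a = make_sumstats([dict(BETA=rng.normal(), SE=rng.uniform(0.01, 0.1))
                           for _ in range(20)])
        out = genomic_control_correct(a, 1.3)
        assert (out.table["P"].to_numpy() >= a.table["P"].to_numpy() - 1e-15).all()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            genomic_control_correct(make_sumstats([{}]), 0.0)


class TestNeffFilter:
    @pytest.mark.parametrize(
        "n, info, eaf, kept",
        [
            (1000, 0.5, 0.05, True),   # N_eff = 47.5
            (1000, 0.25, 0.5, False),  # Info below 0.3 regardless of N_eff
            (1000, 0.3, 0.01, False),  # N_eff = 5.94
        ],
    )
    def test_rule_table(self, n, info, eaf, kept):
        s = make_sumstats([dict(N=float(n), INFO=info, EAF=eaf)])
        assert (len(neff_filter(s)) == 1) is kept

    def test_idempotent(self, rng):
        s = make_sumstats([dict(N=float(rng.integers(20, 5000)),
                                INFO=float(rng.uniform(0.1, 1.0)),
                                EAF=float(rng.uniform(0.01, 0.99)))
                           for _ in range(50)])
        once = neff_filter(s)
        twice = neff_filter(once)
        pd.testing.assert_frame_equal(once.table, twice.table)


class TestPruning:
    def _stats3(self):
        return make_sumstats([
            dict(SNP="a", POS=1_000_000, BETA=0.10, SE=0.01),
            dict(SNP="b", POS=2_000_000, BETA=0.09, SE=0.01),
            dict(SNP="c", POS=8_000_000, BETA=0.08, SE=0.01),
        ])

    def test_single_significant_variant(self):
        s = make_sumstats([dict(SNP="a", BETA=0.1, SE=0.01),
                           dict(SNP="b", BETA=0.001, SE=0.01)])
        assert prune_independent(s, LDTable(pd.DataFrame(columns=["SNP_A", "SNP_B", "R2"]))) == ["a"]

    def test_correlated_pair_in_window_keeps_lower_p(self):
        s = self._stats3()
        ld = LDTable(pd.DataFrame([("a", "b", 0.9)], columns=["SNP_A", "SNP_B", "R2"]))
        out = prune_independent(s, ld)
        assert "a" in out and "b" not in out

    def test_correlated_pair_outside_window_both_kept(self):
        # 7 Mb apart: correlation no longer disqualifies
        s = make_sumstats([
            dict(SNP="a", POS=1_000_000, BETA=0.10, SE=0.01),
            dict(SNP="b", POS=8_000_000, BETA=0.09, SE=0.01),
        ])
        ld = LDTable(pd.DataFrame([("a", "b", 0.9)], columns=["SNP_A", "SNP_B", "R2"]))
        assert sorted(prune_independent(s, ld)) == ["a", "b"]

    def test_output_mutually_valid(self, rng):
        # exhaustive pairwise re-check of the (r2, window) rule
        n = 30
        recs = [dict(SNP=f"v{i}", POS=int(p), BETA=float(b), SE=0.01)
                for i, (p, b) in enumerate(zip(rng.integers(1, 3e7, n),
                                               rng.normal(0.08, 0.02, n)))]
        s = make_sumstats(recs)
        pairs = []
        ids = [r["SNP"] for r in recs]
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    pairs.append((ids[i], ids[j], float(rng.random())))
        ld = LDTable(pd.DataFrame(pairs, columns=["SNP_A", "SNP_B", "R2"]))
        out = prune_independent(s, ld)
        pos = s.indexed()["POS"]
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                violates = abs(pos[a] - pos[b]) <= 5e6 and ld.r2(a, b) >= 0.005
                assert not violates


class TestLoci:
    def test_isolated_variant_flanks(self):
        s = make_sumstats([dict(SNP="a", POS=10_000_000)])
        loc = define_loci(["a"], s).iloc[0]
        assert (loc["START"], loc["END"]) == (9e6, 11e6)

    def test_overlapping_spans_merge_keeping_best(self):
        s = make_sumstats([
            dict(SNP="a", POS=10_000_000, BETA=0.10, SE=0.01),
            dict(SNP="b", POS=11_500_000, BETA=0.12, SE=0.01),
        ])
        loci = define_loci(["a", "b"], s)
        assert len(loci) == 1
        assert loci.iloc[0]["TOP_SNP"] == "b"

    def test_zero_flank_degenerates_to_position(self):
        s = make_sumstats([dict(SNP="a", POS=5_000_000)])
        loc = define_loci(["a"], s, flank_bp=0).iloc[0]
        assert loc["START"] == loc["END"] == 5_000_000


class TestReplication:
    def _triplet(self, p_meta=5e-10, p_a=1e-3, p_b=1e-3, beta_b=0.1):
        meta = make_sumstats([dict(SNP="rs1", BETA=0.1, SE=0.1 / abs(_z(p_meta)))])
        a = make_sumstats([dict(SNP="rs1", BETA=0.1, SE=0.1 / abs(_z(p_a)))])
        b = make_sumstats([dict(SNP="rs1", BETA=beta_b, SE=abs(beta_b) / abs(_z(p_b)))])
        return meta, a, b

    def test_all_criteria_met(self):
        flags = replication_flags(*self._triplet()).iloc[0]
        assert flags["replicated"]

    def test_opposite_signs_fail(self):
        flags = replication_flags(*self._triplet(beta_b=-0.1)).iloc[0]
        assert not flags["concordant_direction"] and not flags["replicated"]

    def test_support_threshold_is_strict(self):
        flags = replication_flags(*self._triplet(p_b=0.02)).iloc[0]
        assert not flags["support_cohort_b"] and not flags["replicated"]

    def test_novelty_by_distance(self):
        meta, a, b = self._triplet()
        near = pd.DataFrame([dict(CHR="1", START=500_000, END=1_200_000)])
        far = pd.DataFrame([dict(CHR="1", START=20_000_000, END=21_000_000)])
        assert not replication_flags(meta, a, b, known_loci=near).iloc[0]["novel"]
        assert replication_flags(meta, a, b, known_loci=far).iloc[0]["novel"]


class TestMetaSubtract:
    def test_round_trip_recovers_cohort(self, rng):
        a = make_sumstats([dict(BETA=float(b), SE=float(s), N=10_000.0)
                           for b, s in zip(rng.normal(0, 0.1, 10),
                                           rng.uniform(0.01, 0.05, 10))])
        b = make_sumstats([dict(BETA=float(b), SE=float(s), N=20_000.0)
                           for b, s in zip(rng.normal(0, 0.1, 10),
                                           rng.uniform(0.01, 0.05, 10))])
        m = ivw_meta([a, b])
        back = meta_subtract(m, a)
        np.testing.assert_allclose(back.table["BETA"], b.table["BETA"], rtol=1e-10)
        np.testing.assert_allclose(back.table["SE"], b.table["SE"], rtol=1e-10)
        np.testing.assert_allclose(back.table["N"], b.table["N"], rtol=1e-10)

    def test_subtracting_self_drops_everything(self):
        m = make_sumstats([{}])
        with pytest.raises(ValueError):
            meta_subtract(m, m)

    def test_three_cohort_associativity(self, rng):
        studies = [make_sumstats([dict(BETA=float(rng.normal(0, 0.1)),
                                       SE=float(rng.uniform(0.01, 0.05)))])
                   for _ in range(3)]
        full = ivw_meta(studies)
        left = meta_subtract(full, studies[0]).table.iloc[0]
        other_two = ivw_meta(studies[1:]).table.iloc[0]
        assert left["BETA"] == pytest.approx(other_two["BETA"], rel=1e-10)
        assert left["SE"] == pytest.approx(other_two["SE"], rel=1e-10)


class TestIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        s = make_sumstats([dict(BETA=float(rng.normal(0, 0.05)),
                                SE=float(rng.uniform(0.005, 0.05)))
                           for _ in range(5)])
        path = tmp_path / "stats.tsv"
        s.write_tsv(path)
        back = SummaryStats.read_tsv(path)
        np.testing.assert_allclose(back.table["BETA"], s.table["BETA"], rtol=1e-5)
        assert list(back.table["SNP"]) == list(s.table["SNP"])

    def test_inconsistent_p_rejected(self, tmp_path):
        s = make_sumstats([dict(BETA=0.1, SE=0.01)])
        s.table.loc[0, "P"] = 0.5  # wildly off |beta/se| ~ 10
        path = tmp_path / "bad.tsv"
        s.table.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="inconsistent"):
            SummaryStats.read_tsv(path)


def _z(p):
    from cardiomr.statsutil import z_from_p

    return z_from_p(p)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
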