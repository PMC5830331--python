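import numpy as np
import pandas as pd
import pytest

from bemut.catalog import PathwayDB
from bemut.pathways import (
    assign_mutations_to_pathways,
    diversity_group_test,
    diversity_table,
    gene_burden_test,
    pathway_burden_test,
    percent_reduction,
    shannon_pathway_diversity,
)
from bemut.stats import kruskal_wallis


@pytest.fixture()
def tiny_gene_intervals():
    return pd.DataFrame(
        {
            "gene": ["GA", "GB", "GC"],
            "chrom": ["1", "1", "2"],
            "start": [10_000, 50_000, 10_000],
            "end": [20_000, 60_000, 20_000],
        }
    )


@pytest.fixture()
def tiny_pathdb():
    return PathwayDB({"W1": {"GA", "GB"}, "W2": {"GA", "GC"}})


def _mut(pid, chrom, pos, category="exon-non-synonymous"):
    return {
        "patient_id": pid, "chrom": chrom, "pos": pos,
        "ref": "C", "alt": "T", "mut_type": "SNV", "context3": "ACG",
        "vaf": 0.3, "genes": "", "category": category,
    }


class TestAssignment:
    def test_within_1kb_assigned_outside_not(self, tiny_pathdb, tiny_gene_intervals):
        cat = pd.DataFrame([
            _mut("P1", "1", 9_300),   # 800 bp upstream of GA: assigned
            _mut("P1", "1", 8_400),   # 1,500 bp upstream: not assigned
        ])
        b = assign_mutations_to_pathways(cat, tiny_pathdb, tiny_gene_intervals)
        assert b.functional.loc["P1", "W1"] == 1

    def test_gene_in_two_pathways_double_counts(self, tiny_pathdb, tiny_gene_intervals):
        cat = pd.DataFrame([_mut("P1", "1", 15_000)])  # inside GA
        b = assign_mutations_to_pathways(cat, tiny_pathdb, tiny_gene_intervals)
        assert b.functional.loc["P1", "W1"] == 1
        assert b.functional.loc["P1", "W2"] == 1

    def test_nonfunctional_tracked_separately(self, tiny_pathdb, tiny_gene_intervals):
        cat = pd.DataFrame([_mut("P1", "1", 15_000, category="intron-coding-gene")])
        b = assign_mutations_to_pathways(cat, tiny_pathdb, tiny_gene_intervals)
        assert b.functional.loc["P1", "W1"] == 0
        assert b.nonfunctional.loc["P1", "W1"] == 1

    def test_missing_interval_warns(self, tiny_gene_intervals):
        db = PathwayDB({"W": {"GA", "NO_SUCH"}})
        cat = pd.DataFrame([_mut("P1", "1", 15_000)])
        with pytest.warns(UserWarning, match="lack intervals"):
            assign_mutations_to_pathways(cat, db, tiny_gene_intervals)

    def test_catalog_genes_column_fallback(self, tiny_pathdb):
        cat = pd.DataFrame([_mut("P1", "1", 15_000)])
        cat.loc[0, "genes"] = "GA"
        b = assign_mutations_to_pathways(cat, tiny_pathdb)
        assert b.functional.loc["P1", "W1"] == 1

    def test_burden_conservation(self, small_cohort, pathway_db):
        """Sum over pathways >= number of pathway-assigned mutations
        (equality only when pathways are disjoint)."""
        cat, meta = small_cohort["catalog"], small_cohort["meta"]
        b = assign_mutations_to_pathways(cat, pathway_db, meta=meta)
        all_genes = pathway_db.all_genes()
        assigned = cat[cat["genes"].isin(all_genes)]
        total_burden = b.functional.to_numpy().sum() + b.nonfunctional.to_numpy().sum()
        assert total_burden >= len(assigned)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "u,n,expected", [(1.0, 2.0, 50.0), (0.83, 1.71, 51.46), (3.3, 3.3, 0.0)]
    )
    def test_values(self, u, n, expected):
        assert percent_reduction(u, n) == pytest.approx(expected, abs=0.005)

    def test_zero_nonuser_undefined(self):
        assert np.isnan(percent_reduction(1.0, 0.0))


class TestShannon:
    def test_uniform_nine_pathways(self):
        counts = pd.Series(3.0, index=[f"p{i}" for i in range(9)])
        genes = pd.Series(10, index=counts.index)
        assert shannon_pathway_diversity(counts, genes) == pytest.approx(np.log(9))

    def test_point_mass_zero(self):
        counts = pd.Series([7, 0, 0], index=list("abc"))
        genes = pd.Series([5, 5, 5], index=list("abc"))
        assert shannon_pathway_diversity(counts, genes) == 0.0

    def test_hand_value_with_gene_normalization(self):
        counts = pd.Series([2, 2], index=["a", "b"])
        genes = pd.Series([10, 20], index=["a", "b"])
        assert shannon_pathway_diversity(counts, genes) == pytest.approx(0.6365, abs=1e-4)

    def test_scale_invariance_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(2, 12))
            counts = pd.Series(rng.integers(0, 30, k).astype(float))
            genes = pd.Series(rng.integers(5, 200, k))
            si = shannon_pathway_diversity(counts, genes)
            assert 0 <= si <= np.log(k) + 1e-12
            assert shannon_pathway_diversity(counts * 7, genes) == pytest.approx(si)

    def test_all_zero_patient_gets_zero(self):
        counts = pd.Series([0, 0], index=["a", "b"])
        genes = pd.Series([5, 5], index=["a", "b"])
        assert shannon_pathway_diversity(counts, genes) == 0.0

    def test_empty_subset_rejected(self):
        counts = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError, match="non-empty"):
            shannon_pathway_diversity(counts, pd.Series([5], index=["a"]), [])


class TestDiversityGroupTest:
    def test_equals_kruskal_composition(self, small_cohort, pathway_db):
        from bemut.simulate import AFFECTED_PATHWAYS

        cat, meta = small_cohort["catalog"], small_cohort["meta"]
        b = assign_mutations_to_pathways(cat, pathway_db, meta=meta)
        si = diversity_table(b, list(AFFECTED_PATHWAYS))
        res = diversity_group_test(si, meta)
        users = meta.loc[meta["nsaid_user"], "patient_id"]
        nonusers = meta.loc[~meta["nsaid_user"], "patient_id"]
        direct = kruskal_wallis(si[users], si[nonusers])
        assert res.p_value == pytest.approx(direct.p_value)

    def test_identical_groups_nonsignificant(self):
        si = pd.Series(np.tile([1.0, 1.5, 2.0], 6), index=[f"P{i}" for i in range(18)])
        meta = pd.DataFrame(
            {"patient_id": si.index, "nsaid_user": [True, False] * 9}
        )
        assert diversity_group_test(si, meta).p_value > 0.9


class TestGeneBurden:
    @staticmethod
    def _catalog(carrier_ids, gene="HOT"):
        rows = [_mut(p, "1", 15_000) for p in carrier_ids]
        df = pd.DataFrame(rows)
        df["genes"] = gene
        return df

    @staticmethod
    def _meta(n=10):
        return pd.DataFrame(
            {
                "patient_id": [f"U{i}" for i in range(n)] + [f"N{i}" for i in range(n)],
                "nsaid_user": [True] * n + [False] * n,
                "ever_smoker": False, "tp53_mutant": False, "target_mb": 96.0,
            }
        )

    def test_four_and_four_carriers_not_tested(self):
        meta = self._meta()
        cat = self._catalog([f"U{i}" for i in range(4)] + [f"N{i}" for i in range(4)])
        out = gene_burden_test(cat, meta, min_carriers=5)
        assert len(out) == 0

    def test_five_user_carriers_tested(self):
        meta = self._meta()
        cat = self._catalog([f"U{i}" for i in range(5)])
        out = gene_burden_test(cat, meta, min_carriers=5)
        assert list(out["gene"]) == ["HOT"]

    def test_depleted_gene_flagged_on_synthetic_truth(
        self, reference, gene_model, pathway_db, arm_table
    ):
        from bemut import simulate

        hot = gene_model["gene"].iloc[100]
        t = simulate.null_truth(
            load_mean=290.93, load_sd=209.69, seed=13,
            gene_effects={hot: 0.9}, gene_weights={hot: 40.0},
        )
        cat, meta, _, _ = simulate.generate_cohort(t, pathway_db, reference, gene_model, arm_table)
        out = gene_burden_test(cat, meta, min_carriers=5, fdr=0.1)
        row = out[out["gene"] == hot]
        assert len(row) == 1
        assert row["significant"].iloc[0]


class TestPathwayBurdenTest:
    def test_identical_groups_high_p(self):
        patients = [f"P{i}" for i in range(20)]
        meta = pd.DataFrame({"patient_id": patients, "nsaid_user": [True, False] * 10})
        from bemut.pathways import PathwayBurden

        func = pd.DataFrame({"W1": np.tile([2, 2], 10), "W2": 0}, index=patients)
        b = PathwayBurden(
            functional=func,
            nonfunctional=func * 0,
            genes_per_pathway=pd.Series({"W1": 10, "W2": 5}),
        )
        out = pathway_burden_test(b, meta).set_index("pathway")
        assert out.loc["W1", "p"] > 0.9  # constant counts
        assert out.loc["W2", "p"] == 1.0  # all-zero pathway


class TestShannonProperties:
    def test_hypothesis_scale_invariance_and_bounds(self):
        from hypothesis import given, settings, strategies as st

        @settings(deadline=None, derandomize=True, max_examples=50)
        @given(
            st.lists(st.integers(0, 50), min_size=2, max_size=12),
            st.integers(2, 9),
        )
        def run(counts, scale):
            genes = pd.Series(np.arange(5, 5 + len(counts)) * 3)
            c = pd.Series(np.asarray(counts, dtype=float))
            si = shannon_pathway_diversity(c, genes)
            assert 0.0 <= si <= np.log(len(counts)) + 1e-9
            assert shannon_pathway_diversity(c * scale, genes) == pytest.approx(si)

        run()
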