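import numpy as np
import pandas as pd
import pytest

from coexbench import normalization as norm
from coexbench.benchstats import (
    WorkflowSpec,
    bin_datasets,
    enumerate_workflows,
    method_impact,
    pairwise_compare,
    read_count_diversity,
    resample_design,
    run_workflow,
    sample_similarity,
)
from coexbench.corpus_io import Corpus, Dataset
from coexbench.netbuild import correlation_network

from _oracles import oracle_bh_adjust, oracle_signed_rank_tail


class TestWorkflowSpec:
    def test_name_convention(self):
        assert WorkflowSpec().name == "Counts"
        assert WorkflowSpec("none", "ctf", "clr").name == "CTF_CLR"
        assert WorkflowSpec("tpm", "qnt", "wto").name == "TPM_QNT_WTO"

    @pytest.mark.parametrize("between", ["tmm", "uq", "ctf", "cuf"])
    def test_within_sample_norm_cannot_precede_count_factors(self, between):
        with pytest.raises(ValueError, match="raw counts"):
            WorkflowSpec("cpm", between, "none")

    def test_unknown_methods_rejected(self):
        with pytest.raises(ValueError):
            WorkflowSpec("vst", "none", "none")


class TestEnumeration:
    def test_all_combinations_respecting_compatibility(self):
        specs = enumerate_workflows()
        assert len(specs) == 36
        assert len(set(specs)) == 36
        # combinatorial identity: (1*6 + 3*2) compatible pairs x 3 transforms
        n_pairs = 1 * 6 + 3 * 2
        assert len(specs) == n_pairs * 3

    def test_reduced_benchmark_after_dropping_worst_methods(self):
        assert len(enumerate_workflows({"rpkm", "qnt", "wto"})) == 14

    def test_excluding_everything_leaves_the_counts_workflow(self):
        only = enumerate_workflows(
            {"cpm", "rpkm", "tpm", "qnt", "tmm", "uq", "ctf", "cuf", "clr", "wto"}
        )
        assert [s.name for s in only] == ["Counts"]

    def test_deterministic_canonical_order(self):
        assert enumerate_workflows() == enumerate_workflows()

    def test_unknown_exclusion_is_an_error(self):
        with pytest.raises(ValueError, match="unknown"):
            enumerate_workflows({"vst"})


@pytest.fixture
def workflow_counts(rng):
    counts = pd.DataFrame(
        rng.poisson(60, size=(12, 8)).astype(float) + 1.0,
        index=[f"G{i}" for i in range(12)],
        columns=[f"S{j}" for j in range(8)],
    )
    lengths = pd.Series(rng.integers(300, 4000, size=12), index=counts.index)
    return counts, lengths


class TestRunWorkflow:
    def test_counts_workflow_is_correlation_of_asinh_counts(self, workflow_counts):
        counts, lengths = workflow_counts
        net = run_workflow(counts, lengths, WorkflowSpec())
        direct = correlation_network(norm.asinh_transform(counts))
        np.testing.assert_allclose(net.weights, direct.weights, atol=1e-12)

    def test_ctf_workflow_equals_manual_composition(self, workflow_counts):
        counts, lengths = workflow_counts
        net = run_workflow(counts, lengths, WorkflowSpec("none", "ctf", "none"))
        manual = correlation_network(
            norm.asinh_transform(
                norm.apply_count_adjustment(counts, norm.tmm_factors(counts))
            )
        )
        np.testing.assert_allclose(net.weights, manual.weights, atol=1e-12)

    def test_sample_permutation_leaves_network_unchanged(self, workflow_counts):
        counts, lengths = workflow_counts
        spec = WorkflowSpec("tpm", "qnt", "clr")
        net = run_workflow(counts, lengths, spec)
        permuted = counts[list(reversed(counts.columns))]
        net2 = run_workflow(permuted, lengths, spec)
        np.testing.assert_allclose(net.weights, net2.weights, atol=1e-9)

    def test_tmm_and_ctf_networks_differ(self, workflow_counts):
        """Library-size division before asinh changes correlations — the
        distinction between TMM and CTF is real, not cosmetic."""
        counts, lengths = workflow_counts
        tmm = run_workflow(counts, lengths, WorkflowSpec("none", "tmm", "none"))
        ctf = run_workflow(counts, lengths, WorkflowSpec("none", "ctf", "none"))
        assert not np.allclose(tmm.weights, ctf.weights)

    def test_stage_errors_carry_workflow_and_stage(self, workflow_counts):
        counts, _ = workflow_counts
        with pytest.raises(ValueError, match="TPM.*within-sample"):
            run_workflow(counts, None, WorkflowSpec("tpm", "none", "none"))


class TestPairwiseCompare:
    def test_identical_scores_tie_everywhere(self, rng):
        s = pd.Series(rng.normal(size=10), index=[f"d{i}" for i in range(10)])
        scores = pd.DataFrame({"A": s, "B": s})
        comp = pairwise_compare(scores)
        row = comp.table.iloc[0]
        assert row.win_proportion == 0.5
        assert row.p_value == 1.0
        assert not comp.table.significant.any()

    def test_uniform_shift_gives_exact_signed_rank_tail(self, rng):
        b = pd.Series(rng.normal(size=20), index=[f"d{i}" for i in range(20)])
        scores = pd.DataFrame({"A": b + 1.0, "B": b})
        comp = pairwise_compare(scores)
        row = comp.table.set_index(["workflow_a", "workflow_b"]).loc[("A", "B")]
        assert row.win_proportion == 1.0
        w_max = 20 * 21 // 2
        assert row.p_value == pytest.approx(oracle_signed_rank_tail(20, w_max),
                                            rel=1e-9)
        assert comp.outperform_counts["A"] == 1
        assert comp.outperform_counts["B"] == 0

    def test_exact_tail_matches_scipy_on_continuous_differences(self, rng):
        from scipy.stats import wilcoxon

        from coexbench.benchstats import _signed_rank_p

        d = rng.normal(size=15)
        expected = wilcoxon(d, alternative="greater", method="exact").pvalue
        assert _signed_rank_p(d) == pytest.approx(expected, rel=1e-12)

    def test_bh_adjustment_matches_step_up_oracle(self, rng):
        # 4 workflows -> 12 ordered pairs; check the BH column directly
        scores = pd.DataFrame(
            rng.normal(size=(15, 4)), columns=list("ABCD"),
            index=[f"d{i}" for i in range(15)],
        )
        comp = pairwise_compare(scores)
        expected = oracle_bh_adjust(comp.table["p_value"].tolist())
        np.testing.assert_allclose(comp.table["p_adjusted"], expected, rtol=1e-12)

    def test_win_proportions_are_antisymmetric(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(12, 3)), columns=list("ABC"),
            index=[f"d{i}" for i in range(12)],
        )
        comp = pairwise_compare(scores)
        t = comp.table.set_index(["workflow_a", "workflow_b"])
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert (
                t.loc[(a, b)].win_proportion + t.loc[(b, a)].win_proportion
                == pytest.approx(1.0)
            )

    def test_detection_power_grows_with_shift_and_sample_size(self):
        rng = np.random.default_rng(99)
        base = rng.normal(size=40)

        def pval(shift, n):
            b = pd.Series(base[:n], index=[f"d{i}" for i in range(n)])
            noise = rng.normal(scale=0.5, size=n)
            scores = pd.DataFrame({"A": b + shift + noise, "B": b})
            comp = pairwise_compare(scores)
            t = comp.table.set_index(["workflow_a", "workflow_b"])
            return t.loc[("A", "B")].p_value

        assert pval(2.0, 30) < pval(0.3, 30)
        assert pval(0.5, 40) < pval(0.5, 8)


class TestMethodImpact:
    def make_result(self, order):
        """Scores in which workflows win strictly according to ``order``."""
        rng = np.random.default_rng(5)
        n = 30
        base = rng.normal(size=n)
        scores = pd.DataFrame(
            {name: base + rank for rank, name in enumerate(reversed(order))},
            index=[f"d{i}" for i in range(n)],
        )
        return pairwise_compare(scores)

    def test_dominant_method_scores_one_and_dominated_zero(self):
        specs = {
            "Counts": WorkflowSpec(),
            "CTF": WorkflowSpec("none", "ctf", "none"),
            "CTF_CLR": WorkflowSpec("none", "ctf", "clr"),
            "CLR": WorkflowSpec("none", "none", "clr"),
        }
        comp = self.make_result(["CTF", "CTF_CLR", "Counts", "CLR"])
        impact = method_impact(comp, specs, methods=("ctf", "no-between"))
        # every (with-CTF, without-CTF) comparison is a significant win
        assert impact["ctf"] == 1.0
        assert impact["no-between"] == 0.0

    def test_within_sample_assessment_excludes_count_factor_workflows(self):
        specs = {
            "Counts": WorkflowSpec(),
            "TPM": WorkflowSpec("tpm", "none", "none"),
            "CTF": WorkflowSpec("none", "ctf", "none"),
        }
        comp = self.make_result(["CTF", "TPM", "Counts"])
        impact = method_impact(comp, specs, methods=("tpm", "no-within"))
        # CTF rows are excluded from the within-sample family, so TPM is
        # judged only against Counts (a significant win)
        assert impact["tpm"] == 1.0
        assert impact["no-within"] == 0.0

    def test_toy_table_matches_exhaustive_enumeration(self):
        specs = {s.name: s for s in enumerate_workflows({"rpkm", "qnt", "wto"})}
        names = list(specs)
        rng = np.random.default_rng(11)
        scores = pd.DataFrame(
            rng.normal(size=(20, len(names))) + np.arange(len(names)) * 0.5,
            columns=names, index=[f"d{i}" for i in range(20)],
        )
        comp = pairwise_compare(scores)
        impact = method_impact(comp, specs, methods=("ctf", "clr"))
        table = comp.table.set_index(["workflow_a", "workflow_b"])
        for m in ("ctf", "clr"):
            wins = total = 0
            for a in names:
                for b in names:
                    if a == b:
                        continue
                    sa, sb = specs[a], specs[b]
                    if m == "ctf" and (sa.within != "none" or sb.within != "none"):
                        continue
                    if m in sa.methods and m not in sb.methods:
                        total += 1
                        wins += bool(table.loc[(a, b)].significant)
            assert impact[m] == pytest.approx(wins / total)


class TestExperimentalFactors:
    def test_duplicated_samples_have_similarity_one(self, rng):
        col = rng.poisson(50, size=20).astype(float)
        counts = pd.DataFrame({"S1": col, "S2": col, "S3": col},
                              index=[f"G{i}" for i in range(20)])
        assert sample_similarity(counts) == pytest.approx(1.0)

    def test_reversed_ranks_have_similarity_minus_one(self):
        a = np.arange(1.0, 11.0)
        counts = pd.DataFrame({"S1": a, "S2": a[::-1]},
                              index=[f"G{i}" for i in range(10)])
        assert sample_similarity(counts, variable_fraction=1.0) == pytest.approx(-1.0)

    def test_four_sample_fixture_matches_loop_oracle(self, rng):
        from scipy.stats import spearmanr

        counts = pd.DataFrame(rng.poisson(40, size=(16, 4)).astype(float),
                              index=[f"G{i}" for i in range(16)],
                              columns=list("WXYZ"))
        got = sample_similarity(counts, 0.5)
        var = counts.var(axis=1, ddof=1)
        top = sorted(counts.index, key=lambda g: (-var[g], g))[:8]
        sub = counts.loc[top]
        rhos = []
        for i in range(4):
            for j in range(i + 1, 4):
                rhos.append(spearmanr(sub.iloc[:, i], sub.iloc[:, j]).statistic)
        assert got == pytest.approx(float(np.median(rhos)))

    def test_read_count_diversity_examples(self):
        equal = pd.DataFrame([[50.0, 50.0], [50.0, 50.0]], index=["G1", "G2"])
        assert read_count_diversity(equal) == 0.0
        two = pd.DataFrame([[100.0, 200.0]], index=["G1"])
        assert read_count_diversity(two) == pytest.approx(70.7107, abs=1e-4)
        three = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"])
        assert read_count_diversity(three) == pytest.approx(1.0)


class TestBinning:
    def test_even_split(self):
        values = {f"d{i}": float(i) for i in range(10)}
        bins = bin_datasets(values, 5)
        assert [len(b) for b in bins] == [2, 2, 2, 2, 2]
        assert bins[0] == ["d0", "d1"]

    def test_remainder_goes_to_lowest_bins(self):
        values = {f"d{i:02d}": float(i) for i in range(11)}
        bins = bin_datasets(values, 5)
        assert [len(b) for b in bins] == [3, 2, 2, 2, 2]

    def test_ties_broken_by_id_deterministically(self):
        values = {"b": 1.0, "a": 1.0, "c": 1.0, "d": 1.0}
        assert bin_datasets(values, 2) == [["a", "b"], ["c", "d"]]


def make_source(rng, dataset_id, n_samples):
    counts = pd.DataFrame(
        rng.poisson(10, size=(4, n_samples)).astype(float),
        index=[f"G{i}" for i in range(4)],
        columns=[f"{dataset_id}.s{j}" for j in range(n_samples)],
    )
    return Dataset(dataset_id, counts)


class TestResampleDesign:
    def test_small_sources_are_ineligible(self, rng):
        corpus = Corpus({
            "big": make_source(rng, "big", 80),
            "small": make_source(rng, "small", 60),
        })
        specs = resample_design(corpus, sizes=(5, 10), replicates=2, seed=3)
        assert {s.source for s in specs} == {"big"}
        assert len(specs) == 2 * 2

    def test_design_is_reproducible_and_without_replacement(self, rng):
        corpus = Corpus({"big": make_source(rng, "big", 75)})
        a = resample_design(corpus, sizes=(5, 40), replicates=3, seed=17)
        b = resample_design(corpus, sizes=(5, 40), replicates=3, seed=17)
        assert a == b
        for spec in a:
            assert len(set(spec.sample_ids)) == spec.size
        c = resample_design(corpus, sizes=(5, 40), replicates=3, seed=18)
        assert a != c

    def test_oversized_request_skipped_with_warning(self, rng):
        corpus = Corpus({"d": make_source(rng, "d", 72)})
        with pytest.warns(UserWarning, match="exceeds"):
            specs = resample_design(corpus, sizes=(100,), replicates=2, seed=0)
        assert specs == []
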