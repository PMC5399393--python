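import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comorbidnet.io_model import ExpressionDataset
from comorbidnet.expression_validation import (
    collapse_probes,
    log2_quantile_normalize,
    qvalues,
    two_sided_p,
    validate_candidates,
    welch_t,
)
from comorbidnet.overlap_enrichment import fdr_adjust


def make_dataset(matrix, groups, probe_map=None, dataset_id="ds"):
    return ExpressionDataset(dataset_id, matrix, groups, probe_map)


@pytest.fixture
def four_sample_groups():
    return {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}


class TestQuantileNormalization:
    def test_identical_columns_unchanged(self, four_sample_groups):
        col = [1.0, 5.0, 3.0]
        m = pd.DataFrame({s: col for s in four_sample_groups}, index=["g1", "g2", "g3"])
        ds = log2_quantile_normalize(make_dataset(m, four_sample_groups), log2=False)
        assert np.allclose(ds.matrix.to_numpy(), m.to_numpy())

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(1, 10, size=(20, 4)), columns=["s1", "s2", "s3", "s4"])
        groups = {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
        ds = log2_quantile_normalize(make_dataset(m, groups), log2=False)
        out = ds.matrix.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_two_by_two_rank_means(self, four_sample_groups):
        # columns (1, 2) and (3, 4): order-statistic means are (1+3)/2 and (2+4)/2
        m = pd.DataFrame(
            {"s1": [1.0, 3.0], "s2": [2.0, 4.0], "s3": [1.0, 3.0], "s4": [2.0, 4.0]},
            index=["g1", "g2"],
        )
        ds = log2_quantile_normalize(make_dataset(m, four_sample_groups), log2=False)
        assert np.allclose(ds.matrix["s1"], [1.5, 3.5])
        assert np.allclose(ds.matrix["s2"], [1.5, 3.5])

    def test_nonpositive_values_block_log_transform(self, four_sample_groups):
        m = pd.DataFrame(
            {s: [1.0, 0.0] for s in four_sample_groups}, index=["g1", "g2"]
        )
        with pytest.raises(ValueError, match="nonpositive"):
            log2_quantile_normalize(make_dataset(m, four_sample_groups), log2=True)


class TestCollapseProbes:
    def test_identity_without_probe_map(self, four_sample_groups):
        m = pd.DataFrame(np.ones((2, 4)), index=["g1", "g2"], columns=list(four_sample_groups))
        ds = make_dataset(m, four_sample_groups)
        assert collapse_probes(ds) is ds

    def test_keeps_highest_mean_probe(self, four_sample_groups):
        m = pd.DataFrame(
            {"s1": [5.0, 7.0], "s2": [5.0, 7.0], "s3": [5.0, 7.0], "s4": [5.0, 7.0]},
            index=["p_low", "p_high"],
        )
        ds = make_dataset(m, four_sample_groups, probe_map={"p_low": "G", "p_high": "G"})
        out = collapse_probes(ds)
        assert list(out.matrix.index) == ["G"]
        assert np.allclose(out.matrix.loc["G"], 7.0)

    def test_tie_breaks_by_probe_id(self, four_sample_groups):
        m = pd.DataFrame(np.full((2, 4), 3.0), index=["pB", "pA"], columns=list(four_sample_groups))
        ds = make_dataset(m, four_sample_groups, probe_map={"pB": "G", "pA": "G"})
        out = collapse_probes(ds)
        # equal means: lexicographically smallest probe id (pA) retained
        assert out.matrix.loc["G"].tolist() == ds.matrix.loc["pA"].tolist()

    def test_unmapped_probes_dropped(self, four_sample_groups):
        m = pd.DataFrame(np.ones((2, 4)), index=["p1", "p2"], columns=list(four_sample_groups))
        ds = make_dataset(m, four_sample_groups, probe_map={"p1": "G"})
        out = collapse_probes(ds)
        assert list(out.matrix.index) == ["G"]


class TestWelch:
    def test_identical_samples_give_zero(self):
        t, df = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0

    def test_antisymmetry(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        t1, df1 = welch_t(x, y)
        t2, df2 = welch_t(y, x)
        assert t1 == -t2
        assert df1 == df2

    def test_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0])
        sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
        se2 = sx2 / 3 + sy2 / 3
        t_ref = (x.mean() - y.mean()) / np.sqrt(se2)
        df_ref = se2**2 / ((sx2 / 3) ** 2 / 2 + (sy2 / 3) ** 2 / 2)
        t, df = welch_t(x, y)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert df == pytest.approx(df_ref, abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])

    def test_group_size_minimum(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_two_sided_p_properties(self):
        assert two_sided_p(0.0, 5.0) == 1.0
        assert two_sided_p(2.0, 5.0) == two_sided_p(-2.0, 5.0)
        assert two_sided_p(3.0, 5.0) < two_sided_p(2.0, 5.0)


class TestQvalues:
    def test_bh_mode_equals_fdr_adjust(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        assert np.array_equal(qvalues(p, method="bh"), np.minimum(fdr_adjust(p), 1.0))

    def test_single_p_with_pi0_one(self):
        assert qvalues([0.37], method="bh") == pytest.approx([0.37])

    def test_uniform_null_pi0_near_one(self):
        from comorbidnet.expression_validation import _storey_pi0

        rng_seeds = range(20)
        for seed in rng_seeds:
            p = np.random.default_rng(seed).uniform(size=2000)
            pi0 = _storey_pi0(p)
            assert 0.85 <= pi0 <= 1.0

    def test_small_sample_fallback(self):
        p = np.linspace(0.01, 0.99, 50)
        q = qvalues(p, method="storey")
        assert (q >= 0).all() and (q <= 1).all()

    def test_qvalues_monotone_in_p(self):
        p = np.random.default_rng(3).uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])


class TestValidateCandidates:
    @pytest.fixture
    def dataset(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(150)]
        n_case, n_ctrl = 10, 8
        data = rng.normal(8.0, 0.5, size=(150, n_case + n_ctrl))
        data[:10, :n_case] += 2.0  # first ten genes are shifted in cases
        samples = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_ctrl)]
        groups = {s: ("case" if s.startswith("c") else "control") for s in samples}
        return ExpressionDataset("toy", pd.DataFrame(data, index=genes, columns=samples), groups)

    def test_shifted_genes_found(self, dataset):
        result = validate_candidates(dataset, frozenset(dataset.matrix.index))
        assert {f"G{i}" for i in range(10)} <= result.significant

    def test_alpha_zero_nothing_significant(self, dataset):
        result = validate_candidates(dataset, frozenset(dataset.matrix.index), alpha=0.0)
        assert result.significant == frozenset()

    def test_absent_candidates_reported_untested(self, dataset):
        result = validate_candidates(dataset, frozenset({"G0", "G1", "MISSING"}))
        assert "MISSING" in result.untested
        assert "MISSING" not in result.table.index
        assert result.n_hypotheses == 2

    def test_hypothesis_universe_restricted_to_candidates(self, dataset):
        small = validate_candidates(dataset, frozenset({"G0", "G1", "G2"}))
        assert small.n_hypotheses == 3

    def test_no_candidate_on_array_is_error(self, dataset):
        with pytest.raises(ValueError):
            validate_candidates(dataset, frozenset({"NOPE"}))

    def test_invariant_to_sample_and_gene_order(self, dataset):
        shuffled = ExpressionDataset(
            "toy2",
            dataset.matrix.iloc[::-1, ::-1],
            dict(dataset.groups),
        )
        r1 = validate_candidates(dataset, frozenset(dataset.matrix.index))
        r2 = validate_candidates(shuffled, frozenset(dataset.matrix.index))
        assert np.allclose(
            r1.table.sort_index()["t"].to_numpy(), r2.table.sort_index()["t"].to_numpy()
        )
        assert r1.significant == r2.significant

    def test_rows_with_missing_values_excluded(self, dataset):
        m = dataset.matrix.copy()
        m.iloc[0, 0] = np.nan
        ds = ExpressionDataset("toy3", m, dict(dataset.groups))
        result = validate_candidates(ds, frozenset(m.index))
        assert "G0" in result.untested
        assert result.n_hypotheses == len(m) - 1
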