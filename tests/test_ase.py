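import numpy as np
import pandas as pd
import pytest

from poebias import ase
from poebias.errors import UndefinedBiasError
from poebias.simulate import SimulationConfig, simulate_counts


def table_from_pooled(bxc, cxb, gene="g", n_split=2):
    """Build a replicate table whose pooled per-cross counts are as given."""
    rows = []
    for cross, (pat, mat) in (("BxC", bxc), ("CxB", cxb)):
        for i in range(n_split):
            rows.append(
                {
                    "gene_id": gene,
                    "replicate": f"{cross}_r{i}",
                    "cross": cross,
                    "maternal_reads": mat // n_split,
                    "paternal_reads": pat // n_split,
                    "length": 1000,
                }
            )
    return pd.DataFrame(rows)


class TestTpm:
    def test_rate_normalisation(self):
        out = ase.tpm([10, 10], [1000, 2000])
        assert out == pytest.approx([666666.67, 333333.33], abs=0.01)

    def test_single_gene_is_one_million(self):
        assert ase.tpm([37], [1234]) == pytest.approx([1e6])

    def test_zero_count_gene(self):
        assert ase.tpm([0, 5], [100, 100]) == pytest.approx([0.0, 1e6])

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert ase.tpm([0, 0], [10, 10]) == pytest.approx([0.0, 0.0])

    def test_sums_to_one_million(self, rng):
        counts = rng.integers(1, 1000, size=30)
        lengths = rng.integers(200, 5000, size=30)
        assert ase.tpm(counts, lengths).sum() == pytest.approx(1e6)


class TestGeneAse:
    def test_pure_parental_effect(self):
        res = ase.gene_ase(table_from_pooled(bxc=(600, 400), cxb=(600, 400)))
        assert res.parental_pct == pytest.approx(60.0)
        assert res.strain_pct == pytest.approx(50.0)

    def test_pure_strain_effect(self):
        res = ase.gene_ase(table_from_pooled(bxc=(600, 400), cxb=(400, 600)))
        assert res.parental_pct == pytest.approx(50.0)
        assert res.strain_pct == pytest.approx(60.0)

    def test_zero_reads_in_cross_rejected(self):
        with pytest.raises(UndefinedBiasError):
            ase.gene_ase(table_from_pooled(bxc=(0, 0), cxb=(100, 100)))

    def test_binomial_recovery_within_one_point(self):
        cfg = SimulationConfig(n_genes=1, parental_effect=0.6, depth=100_000, n_replicates=8)
        counts = simulate_counts(cfg, seed=7)
        res = ase.gene_ase(counts)
        assert res.parental_pct == pytest.approx(60.0, abs=1.0)


class TestLowCountFilter:
    @pytest.mark.parametrize(
        "bxc,cxb,thresh,keep",
        [((500, 500), (500, 500), 50, True),
         ((20, 10), (500, 500), 50, False),
         ((1, 0), (0, 1), 1, True)],
    )
    def test_threshold(self, bxc, cxb, thresh, keep):
        t = table_from_pooled(bxc=bxc, cxb=cxb, n_split=1)
        assert ase.low_count_filter(t, min_reads_per_cross=thresh) is keep


class TestPermutationTest:
    def test_perfectly_balanced_gives_p_one(self):
        t = table_from_pooled(bxc=(500, 500), cxb=(500, 500), n_split=4)
        assert ase.permutation_parent_test(t, n_perm=199, seed=1) == pytest.approx(1.0)

    def test_strong_effect_detected(self):
        cfg = SimulationConfig(n_genes=1, parental_effect=0.9, depth=10_000, n_replicates=6)
        counts = simulate_counts(cfg, seed=11)
        assert ase.permutation_parent_test(counts, n_perm=999, seed=3) <= 0.01

    def test_seed_reproducible(self):
        cfg = SimulationConfig(n_genes=1, parental_effect=0.55, depth=1000, n_replicates=4)
        counts = simulate_counts(cfg, seed=5)
        p1 = ase.permutation_parent_test(counts, n_perm=499, seed=42)
        p2 = ase.permutation_parent_test(counts, n_perm=499, seed=42)
        assert p1 == p2

    def test_type_one_error_calibrated(self):
        """Under a pure null (p=0.5, no strain effect) the rejection rate at
        alpha=0.05 stays near nominal across 1000 simulated genes."""
        cfg = SimulationConfig(n_genes=1000, parental_effect=0.5, depth=1000, n_replicates=4)
        counts = simulate_counts(cfg, seed=2023)
        rng = np.random.default_rng(99)
        pvals = [
            ase.permutation_parent_test(sub, n_perm=199, seed=rng)
            for _, sub in counts.groupby("gene_id", sort=True)
        ]
        rate = float(np.mean(np.asarray(pvals) <= 0.05))
        assert 0.03 <= rate <= 0.07

    def test_coarse_n_perm_warns(self):
        t = table_from_pooled(bxc=(60, 40), cxb=(55, 45), n_split=2)
        with pytest.warns(UserWarning, match="granularity"):
            ase.permutation_parent_test(t, n_perm=20, seed=0)


class TestDecomposeTable:
    def test_estimator_unbiased_over_many_genes(self):
        """Mean(estimate - truth) within +/-0.3 points over 500 genes at
        depth 1e4 under the additive binomial model."""
        rng = np.random.default_rng(77)
        effects = pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in range(500)],
                "parental_effect": rng.uniform(0.35, 0.65, size=500),
                "strain_effect": rng.uniform(-0.05, 0.05, size=500),
            }
        )
        cfg = SimulationConfig(depth=10_000, n_replicates=6)
        counts = simulate_counts(cfg, seed=13, gene_effects=effects)
        res = ase.decompose_table(counts).set_index("gene_id")
        truth = 100 * effects.set_index("gene_id")["parental_effect"]
        err = (res["parental_pct"] - truth).dropna()
        assert len(err) == 500
        assert abs(err.mean()) <= 0.3

    def test_low_count_genes_dropped_and_recorded(self):
        t = pd.concat(
            [table_from_pooled((500, 500), (500, 500), gene="hi"),
             table_from_pooled((4, 4), (4, 4), gene="lo")]
        )
        res = ase.decompose_table(t, min_reads_per_cross=20)
        assert list(res["gene_id"]) == ["hi"]
        assert res.attrs["dropped_low_count"] == ["lo"]

    def test_mean_tpm_reflects_relative_expression(self):
        rows = []
        for gene, depth in (("big", 900), ("small", 100)):
            rows.append(table_from_pooled((depth, depth), (depth, depth), gene=gene, n_split=1))
        res = ase.decompose_table(pd.concat(rows), min_reads_per_cross=1).set_index("gene_id")
        assert res.loc["big", "mean_tpm"] == pytest.approx(9e5)
        assert res.loc["small", "mean_tpm"] == pytest.approx(1e5)
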