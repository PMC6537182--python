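"""On-disk formats, quality filtering and VIF-based LD pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whogem.containers import GenotypeMatrix, QMatrix
from whogem.genotype_io import (
    ld_prune,
    quality_filter,
    read_dosage_tsv,
    read_genotypes,
    read_q_matrix,
    write_dosage_tsv,
    write_q_matrix,
    write_vcf,
)

VCF_TOY = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
1\t100\tv1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\tv2\tA\tT\t.\tPASS\t.\tGT\t./.\t1|1\t0/1
"""


class TestVcf:
    def test_gt_to_dosage(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TOY)
        G = read_genotypes(path)
        assert G.sample_ids == ["A", "B", "C"]
        assert np.array_equal(G.dosage[:, 0], [0, 1, 2])
        assert np.isnan(G.dosage[0, 1])          # ./. is missing
        assert G.dosage[1, 1] == 2 and G.dosage[2, 1] == 1
        assert G.pos is not None and list(G.pos) == [100, 200]

    def test_non_diploid_names_sample(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(VCF_TOY.replace("0/0\t0/1\t1/1", "0\t0/1\t1/1"))
        with pytest.raises(ValueError, match="A"):
            read_genotypes(path)

    def test_write_read_round_trip(self, tmp_path, random_genotypes):
        G = random_genotypes
        G.dosage[0, 0] = np.nan
        path = tmp_path / "rt.vcf"
        write_vcf(G, path)
        back = read_genotypes(path)
        assert np.array_equal(G.dosage, back.dosage, equal_nan=True)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 12), m=st.integers(2, 15))
def test_dosage_tsv_round_trip(tmp_path_factory, seed, n, m):
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, (n, m)).astype(float)
    dosage[rng.random((n, m)) < 0.1] = np.nan
    G = GenotypeMatrix([f"s{i}" for i in range(n)], [f"v{j}" for j in range(m)], dosage)
    path = tmp_path_factory.mktemp("tsv") / "g.tsv"
    write_dosage_tsv(G, path)
    back = read_dosage_tsv(path)
    assert back.sample_ids == G.sample_ids
    assert back.variant_ids == G.variant_ids
    assert np.array_equal(back.dosage, G.dosage, equal_nan=True)


class TestQualityFilter:
    def test_toy_survivors_match_hand_count(self):
        nan = np.nan
        # v0: clean common; v1: 2/10 missing; v2: monomorphic;
        # v3: maf 0.05; v4: singleton maf 0.05 at n=10
        dosage = np.array([
            [1, 1, 0, 0, 0],
            [0, nan, 0, 0, 0],
            [1, nan, 0, 0, 0],
            [2, 1, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [1, 1, 0, 0, 0],
            [2, 0, 0, 0, 0],
            [0, 1, 0, 1, 0],
            [1, 0, 0, 0, 0],
            [0, 2, 0, 0, 1],
        ], dtype=float)
        G = GenotypeMatrix([f"s{i}" for i in range(10)], [f"v{j}" for j in range(5)], dosage)
        # hand count: missingness (0, .2, 0, 0, 0); maf (.4, .375, 0, .05, .05)
        out = quality_filter(G, max_missing=0.05, min_maf=0.01)
        assert out.variant_ids == ["v0", "v3", "v4"]
        out2 = quality_filter(G, max_missing=0.25, min_maf=0.06)
        assert out2.variant_ids == ["v0", "v1"]

    def test_all_removed_warns(self, rng):
        G = GenotypeMatrix(["a", "b"], ["v0"], np.array([[0.0], [0.0]]))
        with pytest.warns(UserWarning):
            out = quality_filter(G)
        assert out.n_variants == 0


def _vif(X, j):
    """Independent VIF oracle: 1 / (1 - R^2) of column j on the others."""
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(X)), others])
    beta, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
    resid = X[:, j] - A @ beta
    ss_tot = ((X[:, j] - X[:, j].mean()) ** 2).sum()
    return 1.0 / max(resid @ resid / ss_tot, 1e-12)


class TestLdPrune:
    def test_independent_variants_untouched(self, rng):
        # sample size well above the window so chance multicollinearity
        # cannot inflate the VIFs
        X = rng.binomial(2, rng.uniform(0.2, 0.8, 60), (300, 60)).astype(float)
        G = GenotypeMatrix([f"s{i}" for i in range(300)],
                           [f"v{j}" for j in range(60)], X)
        out = ld_prune(G, window=10, step=4, vif_threshold=1.3)
        assert out.n_variants >= 58

    def test_duplicate_column_loses_exactly_one(self, rng):
        X = rng.binomial(2, 0.5, (80, 6)).astype(float)
        X[:, 3] = X[:, 1]
        G = GenotypeMatrix([f"s{i}" for i in range(80)],
                           [f"v{j}" for j in range(6)], X)
        out = ld_prune(G, window=6, step=2)
        assert "v1" in out.variant_ids and "v3" not in out.variant_ids
        assert out.n_variants == 5

    def test_vif_threshold_decides_removal(self, rng):
        # one strongly correlated pair, one weakly correlated pair;
        # the oracle VIF computed directly decides what must happen
        n = 400
        base = rng.binomial(2, 0.5, n).astype(float)
        noisy = np.where(rng.random(n) < 0.25, rng.binomial(2, 0.5, n), base)
        weak = np.where(rng.random(n) < 0.75, rng.binomial(2, 0.5, n), base)
        X = np.column_stack([base, noisy, rng.binomial(2, 0.5, n), weak]).astype(float)
        G = GenotypeMatrix([f"s{i}" for i in range(n)], list("abcd"), X)
        vif_strong = _vif(X[:, [0, 1]], 0)
        vif_weak = _vif(X[:, [0, 3]], 0)
        assert vif_strong > 1.3 > vif_weak  # construction sanity
        out = ld_prune(G, window=4, step=2, vif_threshold=1.3)
        # strong pair loses one member, weak pair both kept
        assert ("a" in out.variant_ids) != ("b" in out.variant_ids) or \
            len({"a", "b"} & set(out.variant_ids)) == 1
        assert "d" in out.variant_ids and "c" in out.variant_ids

    def test_idempotent_and_posthoc_bound(self, rng):
        n, m = 150, 40
        X = rng.binomial(2, 0.5, (n, m)).astype(float)
        # plant correlated blocks
        for j in range(0, m, 5):
            mask = rng.random(n) < 0.8
            X[mask, j + 1] = X[mask, j]
        G = GenotypeMatrix([f"s{i}" for i in range(n)], [f"v{j}" for j in range(m)], X)
        once = ld_prune(G, window=10, step=4, vif_threshold=1.5)
        twice = ld_prune(once, window=10, step=4, vif_threshold=1.5)
        assert twice.variant_ids == once.variant_ids
        # post-hoc: every window of the survivors satisfies the bound
        Y = once.imputed()
        for start in range(0, once.n_variants, 4):
            win = list(range(start, min(start + 10, once.n_variants)))
            if len(win) < 2:
                continue
            for j in range(len(win)):
                assert _vif(Y[:, win], j) < 1.5 + 1e-6

    def test_parameter_validation(self, random_genotypes):
        with pytest.raises(ValueError):
            ld_prune(random_genotypes, window=1)
        with pytest.raises(ValueError):
            ld_prune(random_genotypes, window=10, step=0)
        with pytest.raises(ValueError):
            ld_prune(random_genotypes, vif_threshold=1.0)


class TestQMatrixIO:
    def test_parse_simple(self, tmp_path):
        path = tmp_path / "x.Q"
        path.write_text("0.5 0.5\n0.25 0.75\n")
        Q = read_q_matrix(path)
        assert np.allclose(Q.theta, [[0.5, 0.5], [0.25, 0.75]])

    def test_bad_row_sum_names_row(self, tmp_path):
        path = tmp_path / "bad.Q"
        path.write_text("0.5 0.5\n0.7 0.4\n")
        with pytest.raises(ValueError, match="row 2"):
            read_q_matrix(path)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), k=st.integers(2, 8), n=st.integers(1, 20))
    def test_round_trip_six_decimals(self, tmp_path_factory, seed, k, n):
        rng = np.random.default_rng(seed)
        Q = QMatrix([f"s{i}" for i in range(n)], rng.dirichlet(np.ones(k), n))
        path = tmp_path_factory.mktemp("q") / "x.Q"
        write_q_matrix(Q, path)
        back = read_q_matrix(path)
        assert back.sample_ids == Q.sample_ids
        assert np.abs(back.theta - Q.theta).max() < 5e-6
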