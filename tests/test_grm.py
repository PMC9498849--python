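"""Kinship construction across the VanRaden / GCTA / alpha / LDAK family."""

import numpy as np
import pytest

from enrichsim import (
    GRMSpec,
    SubsetDefinition,
    apply_qc,
    build_grm,
    compute_weights,
    grm_pca,
    read_grm,
    simulate_panel,
    write_grm,
)
from enrichsim.grm import ALPHA_GRID, GRM

from conftest import make_panel_from_dosages


class TestSpecValidation:
    def test_fixed_alpha_models(self):
        assert GRMSpec(model="vanraden").alpha == 0.0
        assert GRMSpec(model="gcta").alpha == -1.0
        assert GRMSpec(model="ldak", weights=_unit_weights(10)).alpha == -0.25
        with pytest.raises(ValueError):
            GRMSpec(model="vanraden", alpha=-1.0)
        with pytest.raises(ValueError):
            GRMSpec(model="ldak")  # weights required
        with pytest.raises(ValueError):
            GRMSpec(model="gcta", weights=_unit_weights(10))

    def test_alpha_grid_spans_study_values(self):
        assert ALPHA_GRID == (-1.25, -1.0, -0.75, -0.5, -0.25, 0.0, 0.25)


def _unit_weights(m):
    from enrichsim.ldweights import LDWeights

    return LDWeights(
        raw=np.ones(m), normalized=np.ones(m), window_kb=100.0,
        window_assignment=np.zeros(m, dtype=int), m=m,
    )


class TestBuildGRM:
    def test_vanraden_two_individuals_hand_arithmetic(self):
        # one SNP, p = 0.5, dosages (0, 2): M = (-1, 1)^T, denominator
        # 2 p q = 0.5, G = M M^T / 0.5 = [[2, -2], [-2, 2]]
        panel = make_panel_from_dosages(np.array([[0], [2]], dtype=np.int8))
        g = build_grm(panel, GRMSpec(model="vanraden"))
        np.testing.assert_allclose(g.matrix, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-14)

    def test_alpha_zero_is_vanraden_bitwise(self, small_panel):
        gv = build_grm(small_panel, GRMSpec(model="vanraden"))
        ga = build_grm(small_panel, GRMSpec(model="alpha", alpha=0.0))
        assert np.array_equal(gv.matrix, ga.matrix)

    def test_alpha_minus_one_is_standardized_kinship(self, small_panel):
        """alpha=-1 equals Z Z^T / m with z = (x - 2p)/sqrt(2pq), independently built."""
        g = build_grm(small_panel, GRMSpec(model="gcta"))
        X = small_panel.dosages.astype(float)
        p = small_panel.freq
        Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
        np.testing.assert_allclose(g.matrix, Z @ Z.T / small_panel.m, atol=1e-12)

    def test_ldak_with_unit_weights_equals_alpha_model(self, small_panel):
        """The cli-level equivalence: ldak with w=1 is the alpha=-0.25 kinship."""
        g_l = build_grm(
            small_panel, GRMSpec(model="ldak", weights=_unit_weights(small_panel.m))
        )
        g_a = build_grm(small_panel, GRMSpec(model="alpha", alpha=-0.25))
        np.testing.assert_allclose(g_l.matrix, g_a.matrix, atol=1e-12)

    def test_mean_diagonal_near_one(self):
        panel, _ = apply_qc(simulate_panel(300, 5000, 50_000_000, seed=44))
        for model, alpha in [("vanraden", None), ("gcta", None), ("alpha", -0.5)]:
            g = build_grm(panel, GRMSpec(model=model, alpha=alpha))
            assert 0.95 <= np.mean(np.diag(g.matrix)) <= 1.05
        w = compute_weights(panel, 100.0)
        g = build_grm(panel, GRMSpec(model="ldak", weights=w))
        assert 0.95 <= np.mean(np.diag(g.matrix)) <= 1.05

    def test_normalize_diag_exact(self, small_panel):
        g = build_grm(small_panel, GRMSpec(model="gcta"), normalize_diag=True)
        assert np.mean(np.diag(g.matrix)) == pytest.approx(1.0, rel=1e-12)

    def test_subset_and_complement_partition(self, small_panel, functional_subset):
        rest = functional_subset.complement(small_panel.m)
        assert functional_subset.size + rest.size == small_panel.m
        assert len(np.intersect1d(functional_subset.indices, rest.indices)) == 0
        g_f = build_grm(small_panel, GRMSpec(model="gcta", subset=functional_subset))
        g_r = build_grm(small_panel, GRMSpec(model="gcta", subset=rest))
        g_all = build_grm(small_panel, GRMSpec(model="gcta"))
        # unnormalized gcta kinships add: m_f G_f + m_r G_r = m G_all
        combined = (
            functional_subset.size * g_f.matrix + rest.size * g_r.matrix
        ) / small_panel.m
        np.testing.assert_allclose(combined, g_all.matrix, atol=1e-10)

    def test_symmetric_and_psd(self, small_panel):
        g = build_grm(small_panel, GRMSpec(model="vanraden"))
        np.testing.assert_allclose(g.matrix, g.matrix.T, atol=1e-12)
        assert np.linalg.eigvalsh(g.matrix).min() > -1e-8

    def test_individual_permutation_equivariance(self, small_panel):
        g = build_grm(small_panel, GRMSpec(model="gcta"))
        perm = np.random.default_rng(0).permutation(small_panel.n)
        permuted = make_panel_from_dosages(
            small_panel.dosages[perm], pos=small_panel.pos, chrom=small_panel.chrom
        )
        gp = build_grm(permuted, GRMSpec(model="gcta"))
        np.testing.assert_allclose(gp.matrix, g.matrix[np.ix_(perm, perm)], atol=1e-12)

    def test_as_printed_gcta_differs_from_per_snp(self, small_panel):
        a = build_grm(small_panel, GRMSpec(model="gcta"))
        b = build_grm(small_panel, GRMSpec(model="gcta", scaling="as_printed"))
        assert not np.allclose(a.matrix, b.matrix)
        # at alpha = 0 both conventions coincide
        av = build_grm(small_panel, GRMSpec(model="vanraden"))
        bv = build_grm(small_panel, GRMSpec(model="vanraden", scaling="as_printed"))
        np.testing.assert_allclose(av.matrix, bv.matrix, atol=1e-12)


class TestPCA:
    def test_spectral_reconstruction(self, small_panel):
        g = build_grm(small_panel.take_variants(np.arange(200)), GRMSpec(model="vanraden"))
        k = g.n - 1
        cov = grm_pca(g, k=k)
        recon = cov.matrix @ np.diag(cov.eigenvalues) @ cov.matrix.T
        resid = g.matrix - recon
        # only the smallest eigenvalue's direction is missing
        assert np.abs(resid).max() <= np.abs(np.linalg.eigvalsh(g.matrix)).min() + 1e-8

    def test_columns_orthonormal_and_sorted(self, small_panel):
        g = build_grm(small_panel, GRMSpec(model="vanraden"))
        cov = grm_pca(g, k=10)
        np.testing.assert_allclose(cov.matrix.T @ cov.matrix, np.eye(10), atol=1e-10)
        assert np.all(np.diff(cov.eigenvalues) <= 1e-10)

    def test_pc1_separates_planted_populations(self):
        """Two panels from different frequency landscapes: PC1 splits them."""
        a = simulate_panel(60, 400, 10_000_000, seed=1)
        b = simulate_panel(60, 400, 10_000_000, seed=2)
        merged = make_panel_from_dosages(
            np.vstack([a.dosages, b.dosages]), pos=a.pos, chrom=a.chrom
        )
        g = build_grm(merged, GRMSpec(model="vanraden"))
        pc1 = grm_pca(g, k=2).matrix[:, 0]
        labels = np.array([0] * 60 + [1] * 60)
        # silhouette-style check: within-group spread below between-group gap
        gap = abs(pc1[labels == 0].mean() - pc1[labels == 1].mean())
        spread = max(pc1[labels == 0].std(), pc1[labels == 1].std())
        assert gap > 2 * spread


class TestGRMIO:
    def test_round_trip_float32(self, small_panel, tmp_path):
        g = build_grm(small_panel, GRMSpec(model="gcta"))
        prefix = str(tmp_path / "test")
        write_grm(g, prefix)
        back = read_grm(prefix)
        np.testing.assert_allclose(
            back.matrix, g.matrix.astype(np.float32).astype(float), atol=0
        )
        assert back.ids == g.ids
        assert back.n_variants_used == g.n_variants_used

    def test_single_individual(self, tmp_path):
        g = GRM(matrix=np.array([[1.25]]), spec=GRMSpec(model="vanraden"), n_variants_used=3)
        write_grm(g, str(tmp_path / "one"))
        back = read_grm(str(tmp_path / "one"))
        assert back.matrix[0, 0] == pytest.approx(1.25)

    def test_byte_layout_lower_triangle(self, tmp_path):
        """3x3 kinship: grm.bin holds (0,0),(1,0),(1,1),(2,0),(2,1),(2,2) as <f4."""
        M = np.array([[1.0, 0.1, 0.2], [0.1, 1.1, 0.3], [0.2, 0.3, 1.2]])
        g = GRM(matrix=M, spec=GRMSpec(model="vanraden"), n_variants_used=7)
        prefix = str(tmp_path / "layout")
        write_grm(g, prefix)
        raw = np.fromfile(prefix + ".grm.bin", dtype="<f4")
        np.testing.assert_allclose(raw, [1.0, 0.1, 1.1, 0.2, 0.3, 1.2], atol=1e-7)
        counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
        assert counts.shape == (6,) and np.all(counts == 7)

    def test_truncated_file_raises(self, small_panel, tmp_path):
        g = build_grm(small_panel.take_variants(np.arange(50)), GRMSpec(model="gcta"))
        prefix = str(tmp_path / "trunc")
        write_grm(g, prefix)
        data = open(prefix + ".grm.bin", "rb").read()
        open(prefix + ".grm.bin", "wb").write(data[:-8])
        with pytest.raises(ValueError, match="truncated"):
            read_grm(prefix)
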