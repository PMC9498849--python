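"""Genotype panel simulation, QC and subset definitions."""

import numpy as np
import pytest
from scipy import stats

from enrichsim import (
    MAFSpectrum,
    apply_qc,
    define_functional_subset,
    define_random_subset,
    hwe_test,
    simulate_panel,
)
from enrichsim.panel import MISSING, ParameterError

from conftest import make_panel_from_dosages


class TestHWE:
    @pytest.mark.parametrize(
        "counts, expected_p",
        [
            ((25, 50, 25), 1.0),  # exact HWE proportions, statistic 0
            ((100, 0, 0), 1.0),  # monomorphic convention
            ((0, 0, 77), 1.0),
        ],
    )
    def test_boundary_cases(self, counts, expected_p):
        assert hwe_test(*counts) == pytest.approx(expected_p)

    def test_het_deficit_rejected(self):
        # counts (40, 20, 40): p-hat = 0.5, expected (25, 50, 25),
        # statistic 9 + 18 + 9 = 36, p = sf(36, 1) ~ 1.97e-9 < 1e-6
        p = hwe_test(40, 20, 40)
        assert p == pytest.approx(stats.chi2.sf(36.0, 1), rel=1e-10)
        assert p < 1e-6

    def test_agrees_with_direct_chi_square(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            counts = rng.integers(0, 200, size=3)
            if counts.sum() == 0:
                continue
            n = counts.sum()
            p_hat = (2 * counts[0] + counts[1]) / (2 * n)
            if p_hat in (0.0, 1.0):
                assert hwe_test(*counts) == 1.0
                continue
            exp = n * np.array([p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
            stat = float(np.sum((counts - exp) ** 2 / exp))
            assert hwe_test(*counts) == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-10)

    def test_exact_flavor_matches_enumeration(self):
        """Conditional exact p equals a factorial-enumeration oracle."""
        from math import factorial

        def oracle(nAA, nAa, naa):
            n = nAA + nAa + naa
            na = min(2 * nAA + nAa, 2 * n - (2 * nAA + nAa))
            hs = list(range(na % 2, na + 1, 2))
            ps = [
                2**h / (factorial(h) * factorial((na - h) // 2) * factorial(n - h - (na - h) // 2))
                for h in hs
            ]
            tot = sum(ps)
            ps = [x / tot for x in ps]
            p_obs = dict(zip(hs, ps))[nAa]
            return sum(x for x in ps if x <= p_obs * (1 + 1e-12))

        for counts in [(5, 2, 5), (3, 7, 2), (1, 1, 10), (0, 2, 10), (12, 9, 4)]:
            got = hwe_test(*counts, method="exact")
            assert got == pytest.approx(oracle(*counts), rel=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)


class TestSimulatePanel:
    def test_degenerate_single_variant(self):
        panel = simulate_panel(2, 1, seed=7)
        assert panel.dosages.shape == (2, 1)
        assert set(np.unique(panel.dosages)).issubset({0, 1, 2})

    def test_deterministic_given_seed(self):
        a = simulate_panel(50, 120, seed=33)
        b = simulate_panel(50, 120, seed=33)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(a.pos, b.pos)
        c = simulate_panel(50, 120, seed=34)
        assert np.any(c.dosages != a.dosages)

    def test_positions_strictly_increasing_per_chromosome(self):
        panel = simulate_panel(10, 500, seed=3, n_chromosomes=3)
        for c in np.unique(panel.chrom):
            assert np.all(np.diff(panel.pos[panel.chrom == c]) > 0)

    def test_freq_matches_dosages(self):
        panel = simulate_panel(100, 300, seed=9, missing_rate=0.05)
        obs = panel.dosages != MISSING
        freq = np.where(obs, panel.dosages, 0).sum(0) / (2.0 * obs.sum(0))
        np.testing.assert_allclose(panel.freq, freq, atol=1e-12)

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ParameterError):
            MAFSpectrum(kind="cauchy")
        with pytest.raises(ParameterError):
            MAFSpectrum(lo=0.2, hi=0.1)
        with pytest.raises(ParameterError):
            simulate_panel(10, 10, maf_spectrum="uniform", seed=0)

    def test_ld_decay_target_at_40kb(self):
        """Median r^2 of pairs 35-45 kb apart hits the 0.5 calibration target."""
        panel = simulate_panel(2000, 5000, 50_000_000, ld_decay_bp=40_000, seed=3)
        X = panel.dosages.astype(float)
        Xc = X - X.mean(0)
        sd = Xc.std(0)
        rng = np.random.default_rng(0)
        r2 = []
        for _ in range(3000):
            i = rng.integers(0, panel.m)
            d = panel.pos - panel.pos[i]
            cand = np.flatnonzero((d > 35_000) & (d < 45_000))
            if cand.size == 0:
                continue
            j = cand[rng.integers(cand.size)]
            r = (Xc[:, i] @ Xc[:, j]) / (panel.n * sd[i] * sd[j])
            r2.append(r * r)
        assert 0.4 <= np.median(r2) <= 0.6

    def test_maf_spectrum_ks(self):
        """Empirical MAF distribution matches the requested spectrum (KS < 0.05)."""
        spec = MAFSpectrum()
        panel = simulate_panel(
            500, 50_000, 100_000_000, maf_spectrum=spec, seed=11, n_chromosomes=5
        )
        maf = np.sort(panel.maf)
        m = len(maf)
        ks = np.max(np.abs(spec.cdf(maf) - (np.arange(1, m + 1) - 0.5) / m))
        assert ks < 0.05

    def test_r2_decay_monotone_in_distance(self):
        """Binned mean r^2 is non-increasing with distance (>=1000 pairs/bin)."""
        from enrichsim import ld_decay_profile

        panel = simulate_panel(400, 4000, 40_000_000, ld_decay_bp=40_000, seed=21)
        prof = ld_decay_profile(
            panel, bin_edges_kb=[0, 25, 50, 100, 200, 400], max_pairs=1_500_000, seed=0
        )
        assert (prof["n_pairs"] >= 1000).all()
        means = prof["mean_r2"].to_numpy()
        assert np.all(np.diff(means) <= 1e-3)


class TestQC:
    def _dirty_panel(self):
        rng = np.random.default_rng(0)
        n = 200
        clean1 = rng.binomial(2, 0.3, n).astype(np.int8)
        clean2 = rng.binomial(2, 0.45, n).astype(np.int8)
        rare = np.zeros(n, dtype=np.int8)
        rare[0] = 1  # maf 1/400 = 0.0025 < 0.005
        lowcall = rng.binomial(2, 0.3, n).astype(np.int8)
        lowcall[: n // 4] = MISSING  # call rate 0.75 < 0.90
        hwe_bad = np.zeros(n, dtype=np.int8)  # 100 hom-ref, 100 hom-alt, no hets
        hwe_bad[: n // 2] = 2
        dosages = np.column_stack([rare, lowcall, hwe_bad, clean1, clean2])
        return make_panel_from_dosages(dosages)

    def test_toy_report_counts_each_rule_once(self):
        panel = self._dirty_panel()
        clean, report = apply_qc(panel)
        assert (
            report.n_input,
            report.n_removed_maf,
            report.n_removed_callrate,
            report.n_removed_hwe,
            report.n_retained,
        ) == (5, 1, 1, 1, 2)
        assert clean.m == 2
        assert clean.is_complete

    def test_clean_panel_unchanged(self, small_panel):
        again, report = apply_qc(small_panel)
        assert report.n_retained == small_panel.m
        assert report.n_removed_maf == report.n_removed_callrate == report.n_removed_hwe == 0
        np.testing.assert_array_equal(again.dosages, small_panel.dosages)

    def test_idempotent(self):
        panel = simulate_panel(150, 400, seed=4, missing_rate=0.08)
        once, _ = apply_qc(panel)
        twice, rep2 = apply_qc(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)
        assert rep2.n_retained == once.m

    def test_retained_satisfy_thresholds(self):
        panel = simulate_panel(300, 600, seed=12, missing_rate=0.04)
        clean, _ = apply_qc(panel)
        assert clean.maf.min() >= 0.005
        assert clean.is_complete

    def test_all_removed_raises(self):
        dosages = np.zeros((50, 2), dtype=np.int8)  # monomorphic, maf 0
        panel = make_panel_from_dosages(dosages)
        with pytest.raises(ValueError, match="empty"):
            apply_qc(panel)


class TestSubsets:
    def test_functional_subset_size_and_clustering(self, small_panel):
        target = 100
        sub = define_functional_subset(small_panel, target_size=target, seed=3)
        per_gene = small_panel.m / (small_panel.pos.max() - small_panel.pos.min()) * 250_000
        assert target - per_gene <= sub.size <= target + per_gene
        # clustered: mean nearest-neighbour bp gap well below a random subset's
        rnd = define_random_subset(small_panel, sub.size, seed=3)
        gap = lambda s: np.median(np.diff(np.sort(small_panel.pos[s.indices])))
        assert gap(sub) < 0.5 * gap(rnd)

    def test_functional_subset_all_variants(self, small_panel):
        sub = define_functional_subset(small_panel, target_size=small_panel.m, seed=0)
        assert sub.size == small_panel.m

    def test_functional_unreachable_raises(self, small_panel):
        with pytest.raises(ValueError):
            define_functional_subset(
                small_panel, target_size=small_panel.m - 1, n_genes=1,
                gene_length_bp=1000, seed=0,
            )

    def test_random_subset_full_and_oversize(self, small_panel):
        sub = define_random_subset(small_panel, small_panel.m, seed=0)
        assert sub.size == small_panel.m
        with pytest.raises(ValueError):
            define_random_subset(small_panel, small_panel.m + 1, seed=0)

    def test_random_subsets_overlap_hypergeometric(self, small_panel):
        """Two independent draws overlap by about size^2/m on average."""
        m = small_panel.m
        size = m // 4
        overlaps = [
            len(
                np.intersect1d(
                    define_random_subset(small_panel, size, seed=2 * s).indices,
                    define_random_subset(small_panel, size, seed=2 * s + 1).indices,
                )
            )
            for s in range(40)
        ]
        expected = size**2 / m
        sd = np.sqrt(expected)  # hypergeometric sd is below sqrt(mean) here
        assert abs(np.mean(overlaps) - expected) < 4 * sd / np.sqrt(40) + 1
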