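"""Window statistics against independent transcriptions of the published
formulas (Weir & Cockerham 1984 components, Tajima 1989 constants) and
hand-evaluated examples."""

import numpy as np
import pytest

from divscan.vcfio import make_windows
from divscan.windows import (
    TajimaConstants,
    classify_fixed,
    compute_window_stats,
    count_fixed_and_df,
    dxy_per_site,
    site_allele_stats,
    tajimas_d,
    wc_components,
    window_dxy,
    window_fst,
    window_pi,
)


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Independent, scalar transcription of the W&C (1984) two-population
    variance components, kept deliberately separate from the implementation."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    return a, b, c


class TestWeirCockerham:
    def test_fixed_difference_gives_fst_one(self):
        a, b, c = wc_components(
            np.array([5.0]), np.array([1.0]), np.array([0.0]),
            np.array([5.0]), np.array([0.0]), np.array([0.0]))
        assert b[0] == pytest.approx(0.0, abs=1e-15)
        assert c[0] == pytest.approx(0.0, abs=1e-15)
        assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_site_contributes_nothing(self):
        a, b, c = wc_components(
            np.array([5.0]), np.array([0.0]), np.array([0.0]),
            np.array([5.0]), np.array([0.0]), np.array([0.0]))
        assert a[0] == pytest.approx(0.0, abs=1e-15)
        assert a[0] + b[0] + c[0] == pytest.approx(0.0, abs=1e-15)

    def test_matches_frozen_hand_evaluation(self):
        # pop1: 5 individuals, 3 alt alleles (p=0.3), 1 het; pop2: 5, 9 alt, 1 het
        a, b, c = wc_components(
            np.array([5.0]), np.array([0.3]), np.array([0.2]),
            np.array([5.0]), np.array([0.9]), np.array([0.2]))
        assert a[0] == pytest.approx(0.155, abs=1e-12)
        assert b[0] == pytest.approx(0.075, abs=1e-12)
        assert c[0] == pytest.approx(0.100, abs=1e-12)

    def test_random_sites_match_oracle(self):
        rng = np.random.default_rng(3)
        n1 = rng.integers(2, 11, 20).astype(float)
        n2 = rng.integers(2, 11, 20).astype(float)
        p1, p2 = rng.random(20), rng.random(20)
        h1, h2 = rng.random(20) * 0.5, rng.random(20) * 0.5
        a, b, c = wc_components(n1, p1, h1, n2, p2, h2)
        for i in range(20):
            ao, bo, co = wc_oracle(n1[i], p1[i], h1[i], n2[i], p2[i], h2[i])
            assert a[i] == pytest.approx(ao, abs=1e-12)
            assert b[i] == pytest.approx(bo, abs=1e-12)
            assert c[i] == pytest.approx(co, abs=1e-12)
        # window ratio-of-sums against the oracle sums
        oracle = [wc_oracle(n1[i], p1[i], h1[i], n2[i], p2[i], h2[i]) for i in range(20)]
        num = sum(o[0] for o in oracle)
        den = sum(sum(o) for o in oracle)
        assert window_fst(a, b, c) == pytest.approx(num / den, abs=1e-12)

    def test_undersized_population_gives_nan(self):
        a, _, _ = wc_components(
            np.array([1.0]), np.array([0.5]), np.array([1.0]),
            np.array([5.0]), np.array([0.5]), np.array([0.2]))
        assert np.isnan(a[0])

    def test_identical_frequencies_fst_at_most_zero(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, 50)
        h = 2 * p * (1 - p)
        n = np.full(50, 10.0)
        a, b, c = wc_components(n, p, h, n, p, h)
        assert window_fst(a, b, c) <= 1e-9


class TestDxyProperties:
    """Hypothesis checks of the D_xy contract over arbitrary frequencies."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    freqs = st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)

    @given(p1=freqs, p2=freqs)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_range_and_symmetry(self, p1, p2):
        m = min(len(p1), len(p2))
        a = np.array(p1[:m])
        b = np.array(p2[:m])
        snp_ab, _ = window_dxy(a, b, 1000)
        snp_ba, _ = window_dxy(b, a, 1000)
        assert 0.0 <= snp_ab <= 1.0
        assert snp_ab == pytest.approx(snp_ba, abs=1e-12)


class TestDxy:
    def test_fixed_difference_site(self):
        assert dxy_per_site(np.array([1.0]), np.array([0.0]))[0] == 1.0

    def test_hand_example(self):
        p1 = np.array([1.0, 0.5, 0.0])
        p2 = np.array([0.0, 0.5, 0.5])
        per_snp, per_bp = window_dxy(p1, p2, 100)
        assert per_snp == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert per_bp == pytest.approx(2.0 / 100, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        p1, p2 = rng.random(30), rng.random(30)
        assert window_dxy(p1, p2, 50)[0] == pytest.approx(window_dxy(p2, p1, 50)[0])


class TestPi:
    def test_monomorphic_is_zero(self):
        assert window_pi(np.array([0, 4]), np.array([4, 4]), 100) == 0.0

    def test_hand_example(self):
        # one site, 4 alleles, 2 ref / 2 alt, L = 100
        assert window_pi(np.array([2]), np.array([4]), 100) == pytest.approx(
            2 * 2 * 2 / (4 * 3) / 100, abs=1e-15)


class TestTajima:
    def test_constants_a1(self):
        c = TajimaConstants.for_n(10)
        assert c.a1 == pytest.approx(sum(1 / i for i in range(1, 10)), abs=1e-12)
        assert c.e1 > 0 and c.e2 > 0

    def test_zero_when_k_equals_S_over_a1(self):
        c = TajimaConstants.for_n(10)
        assert tajimas_d(5, 5 / c.a1, 10) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_oracle_value(self):
        assert tajimas_d(5, 2.0, 10) == pytest.approx(0.5276433822908873, abs=1e-12)

    def test_no_segregating_sites_is_nan(self):
        assert np.isnan(tajimas_d(0, 0.0, 10))


class TestFixedSites:
    def test_planted_patterns_match_set_intersection_oracle(self):
        rng = np.random.default_rng(11)
        from divscan.vcfio import GenotypeMatrix, PopulationMap

        n = 50
        dosages = rng.integers(0, 3, (n, 10)).astype(np.int8)
        dosages[:10, :5] = 0
        dosages[:10, 5:] = 2       # planted fixed
        dosages[10:20] = 1          # shared het
        dosages[20:25, :5] = 2
        dosages[20:25, 5:] = 2      # same allele both sides
        miss = rng.random((n, 10)) < 0.1
        dosages[miss] = -1
        samples = [f"s{i}" for i in range(10)]
        pm = PopulationMap({s: ("P1" if i < 5 else "P2") for i, s in enumerate(samples)})
        gm = GenotypeMatrix(samples, pm, np.array(["c"] * n, dtype=object),
                            np.arange(1, n + 1), np.full(n, "A", "<U1"),
                            np.full(n, "T", "<U1"), dosages)
        fixed = classify_fixed(site_allele_stats(gm))

        for i in range(n):
            d1 = dosages[i, :5]
            d2 = dosages[i, 5:]
            al1 = set()
            for d in d1[d1 >= 0]:
                al1 |= {0} if d == 0 else ({1} if d == 2 else {0, 1})
            al2 = set()
            for d in d2[d2 >= 0]:
                al2 |= {0} if d == 0 else ({1} if d == 2 else {0, 1})
            expect = bool(al1) and bool(al2) and not (al1 & al2)
            assert fixed[i] == expect, f"site {i}"

    def test_het_breaks_fixation(self, tiny_gm):
        fixed = classify_fixed(site_allele_stats(tiny_gm))
        np.testing.assert_array_equal(fixed, [True, False, False, False, True, False])

    def test_df_is_count_over_length(self):
        n_fixed, df = count_fixed_and_df(np.array([True] * 223 + [False] * 100), 100_000)
        assert n_fixed == 223
        assert df == pytest.approx(0.00223)
        assert df * 100_000 == pytest.approx(n_fixed)


class TestComputeWindowStats:
    def test_all_fixed_window(self):
        from divscan.vcfio import GenotypeMatrix, PopulationMap

        n = 10
        dosages = np.zeros((n, 8), dtype=np.int8)
        dosages[:, 4:] = 2
        samples = [f"s{i}" for i in range(8)]
        pm = PopulationMap({s: ("P1" if i < 4 else "P2") for i, s in enumerate(samples)})
        gm = GenotypeMatrix(samples, pm, np.array(["c"] * n, dtype=object),
                            np.arange(1000, 1000 + n), np.full(n, "A", "<U1"),
                            np.full(n, "T", "<U1"), dosages)
        stats = compute_window_stats(gm, make_windows(gm, 100_000))
        row = stats.iloc[0]
        assert row["fst"] == pytest.approx(1.0, abs=1e-12)
        assert row["dxy_per_snp"] == pytest.approx(1.0, abs=1e-12)
        assert row["n_fixed"] == n
        assert row["pi_pop1"] == 0.0

    def test_empty_windows_emit_no_record(self, tiny_gm):
        wins = make_windows(tiny_gm, 100)
        stats = compute_window_stats(tiny_gm, wins)
        assert len(stats) == stats["n_snps"].gt(0).sum()

    def test_population_label_swap_symmetry(self, small_genome):
        from divscan.vcfio import GenotypeMatrix, PopulationMap

        gm, _, _ = small_genome
        sub = gm.take_sites(np.arange(0, 4000))
        # list NESP samples first so it becomes population 1 in the output
        reordered = sorted(sub.popmap.assignments.items(),
                           key=lambda kv: kv[1] != "NESP")
        swapped_pm = PopulationMap(dict(reordered))
        swapped = GenotypeMatrix(sub.samples, swapped_pm, sub.scaffolds,
                                 sub.positions, sub.ref, sub.alt, sub.dosages,
                                 sub.depths)
        s1 = compute_window_stats(sub, make_windows(sub, 100_000))
        s2 = compute_window_stats(swapped, make_windows(swapped, 100_000))
        np.testing.assert_allclose(s1["fst"], s2["fst"], atol=1e-12)
        np.testing.assert_allclose(s1["dxy_per_snp"], s2["dxy_per_snp"], atol=1e-12)
        np.testing.assert_array_equal(s1["n_fixed"], s2["n_fixed"])
        np.testing.assert_allclose(s1["pi_pop1"], s2["pi_pop2"], atol=1e-12)

    def test_fields_match_per_statistic_oracles(self, small_genome):
        """Every column of one window equals a direct recomputation from the
        raw dosages of that window."""
        gm, _, _ = small_genome
        wins = make_windows(gm, 100_000)
        stats = compute_window_stats(gm, wins)
        win = next(w for w in wins if len(w.site_idx) > 50)
        row = stats[(stats["scaffold"] == win.spec.scaffold)
                    & (stats["start"] == win.spec.start)].iloc[0]
        d = gm.dosages[win.site_idx]
        idx = gm.pop_indices
        d1 = d[:, idx["SALS"]].astype(float)
        d2 = d[:, idx["NESP"]].astype(float)
        d1[d1 < 0] = np.nan
        d2[d2 < 0] = np.nan
        n1 = np.isfinite(d1).sum(axis=1)
        n2 = np.isfinite(d2).sum(axis=1)
        p1 = np.nansum(d1, axis=1) / (2 * n1)
        p2 = np.nansum(d2, axis=1) / (2 * n2)
        # dxy
        dxy = np.mean(p1 * (1 - p2) + p2 * (1 - p1))
        assert row["dxy_per_snp"] == pytest.approx(dxy, abs=1e-10)
        # pi for pop1
        alt1 = np.nansum(d1, axis=1)
        na1 = 2 * n1
        pi1 = np.sum(2 * alt1 * (na1 - alt1) / (na1 * (na1 - 1))) / win.spec.length
        assert row["pi_pop1"] == pytest.approx(pi1, abs=1e-12)
        # fst via the independent oracle transcription (het frequency is
        # heterozygotes over *called* individuals)
        h1 = (d1 == 1).sum(axis=1) / n1
        h2 = (d2 == 1).sum(axis=1) / n2
        comps = [wc_oracle(n1[i], p1[i], h1[i], n2[i], p2[i], h2[i])
                 for i in range(len(p1)) if n1[i] >= 2 and n2[i] >= 2]
        fst = sum(c[0] for c in comps) / sum(sum(c) for c in comps)
        assert row["fst"] == pytest.approx(fst, abs=1e-10)
        # fixed count
        n_fixed = np.sum(((p1 == 0) & (p2 == 1)) | ((p1 == 1) & (p2 == 0)))
        assert row["n_fixed"] == n_fixed
        assert row["df"] == pytest.approx(n_fixed / win.spec.length)
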