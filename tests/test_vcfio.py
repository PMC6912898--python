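"""VCF round trips, site filters, and window tiling."""

import numpy as np
import pytest

from divscan.vcfio import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    SiteFilterConfig,
    apply_site_filters,
    make_windows,
    read_vcf,
    write_vcf,
)


def test_popmap_requires_two_populations():
    with pytest.raises(ValueError):
        PopulationMap({"a": "X", "b": "X", "c": "X", "d": "X"})
    with pytest.raises(ValueError):
        PopulationMap({"a": "X", "b": "Y", "c": "Y"})  # X has one sample


def test_popmap_tsv_roundtrip(tmp_path):
    pm = PopulationMap({"s1": "SALS", "s2": "SALS", "s3": "NESP", "s4": "NESP"})
    pm.to_tsv(tmp_path / "pm.tsv")
    assert PopulationMap.from_tsv(tmp_path / "pm.tsv").assignments == pm.assignments


class TestVcfRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path, small_genome):
        gm, _, _ = small_genome
        sub = gm.take_sites(np.arange(0, gm.n_sites, 97))  # thin for speed
        path = tmp_path / "x.vcf"
        write_vcf(sub, path)
        back = read_vcf(path, gm.popmap)
        assert back.samples == sub.samples
        np.testing.assert_array_equal(back.positions, sub.positions)
        np.testing.assert_array_equal(back.dosages, sub.dosages)
        np.testing.assert_array_equal(
            back.scaffolds.astype(str), sub.scaffolds.astype(str))
        np.testing.assert_allclose(back.depths, sub.depths)

    def test_deterministic_output(self, tmp_path, small_genome):
        gm, _, _ = small_genome
        sub = gm.take_sites(np.arange(0, gm.n_sites, 199))
        write_vcf(sub, tmp_path / "a.vcf")
        write_vcf(sub, tmp_path / "b.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_dosage_encoding_and_multiallelic_skip(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=s1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\td\n"
        )
        rows = [
            "s1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\t0/1\t./.",
            "s1\t20\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t1/1\t0/2\t0/0",  # tri-allelic
            "s1\t30\t.\tA\tAT\t.\tPASS\t.\tGT\t0/0\t0/0\t1/1\t0/1",   # indel
            "s1\t40\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t0/0\t0/0",
        ]
        vcf.write_text(header + "\n".join(rows) + "\n")
        pm = PopulationMap({"a": "P1", "b": "P1", "c": "P2", "d": "P2"})
        gm = read_vcf(vcf, pm)
        assert gm.n_sites == 2
        np.testing.assert_array_equal(gm.positions, [10, 40])
        np.testing.assert_array_equal(gm.dosages[0], [0, 2, 1, MISSING])

    def test_missing_popmap_sample_raises(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=s1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "s1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\n"
        )
        pm = PopulationMap({"a": "P1", "zz": "P1", "b": "P2", "yy": "P2"})
        with pytest.raises(ValueError, match="absent"):
            read_vcf(vcf, pm)


def _matrix(dosages, positions=None, scaffolds=None, depths=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    half = n_samples // 2
    samples = [f"x{i}" for i in range(n_samples)]
    pm = PopulationMap({s: ("P1" if i < half else "P2") for i, s in enumerate(samples)})
    return GenotypeMatrix(
        samples=samples,
        popmap=pm,
        scaffolds=np.array(scaffolds or ["s1"] * n_sites, dtype=object),
        positions=np.array(positions or range(100, 100 + 10 * n_sites, 10), dtype=np.int64),
        ref=np.full(n_sites, "A", dtype="<U1"),
        alt=np.full(n_sites, "T", dtype="<U1"),
        dosages=dosages,
        depths=None if depths is None else np.asarray(depths, dtype=np.float32),
    )


class TestSiteFilters:
    def test_missingness_rule(self):
        # 20 samples, 5 missing genotypes = 25% missing > 20%
        row = [1] * 15 + [MISSING] * 5
        gm = _matrix([row, [1] * 20])
        out, rep = apply_site_filters(gm, SiteFilterConfig())
        assert rep.removed["missingness"] == 1
        assert out.n_sites == 1

    def test_maf_rule(self):
        # alt count 1 of 40 called alleles: MAF 0.025 < 0.05
        low = [0] * 19 + [1]
        ok = [1] * 10 + [0] * 10
        gm = _matrix([low, ok])
        out, rep = apply_site_filters(gm, SiteFilterConfig())
        assert rep.removed["maf"] == 1
        assert out.n_sites == 1

    def test_excluded_scaffold(self):
        gm = _matrix([[1] * 8, [1] * 8], scaffolds=["chrZ", "s1"])
        out, rep = apply_site_filters(
            gm, SiteFilterConfig(excluded_scaffolds={"chrZ"}))
        assert rep.removed["excluded_scaffold"] == 1
        assert list(out.scaffolds) == ["s1"]

    def test_planted_violations_match_bruteforce(self):
        """100 sites with planted rule violations: survivors equal an
        independent per-rule re-application."""
        rng = np.random.default_rng(5)
        n_samples = 20
        dosages = rng.integers(0, 3, (100, n_samples)).astype(np.int8)
        dosages[:, :10] = 1  # guarantee decent MAF baseline
        low_maf = rng.choice(100, 10, replace=False)
        for i in low_maf:
            dosages[i] = 0
            dosages[i, 0] = 1  # MAF = 1/40
        high_miss = rng.choice(100, 10, replace=False)
        for i in high_miss:
            dosages[i, :6] = MISSING  # 30% missing
        scaffolds = ["sEx" if i < 5 else "s1" for i in range(100)]
        depths = rng.normal(10, 2, (100, n_samples))
        gm = _matrix(dosages, scaffolds=scaffolds, depths=depths)
        cfg = SiteFilterConfig(excluded_scaffolds={"sEx"})
        out, rep = apply_site_filters(gm, cfg)

        # brute force, same order of rules
        keep = []
        site_means = depths.mean(axis=1)
        ceiling = site_means.mean() + 2 * site_means.std()
        for i in range(100):
            if scaffolds[i] == "sEx":
                continue
            d = dosages[i]
            called = d != MISSING
            p = d[called].sum() / (2 * called.sum())
            if min(p, 1 - p) < 0.05:
                continue
            if 1 - called.mean() > 0.20:
                continue
            if site_means[i] < 3 or site_means[i] > ceiling:
                continue
            keep.append(i)
        assert out.n_sites == len(keep)
        np.testing.assert_array_equal(out.positions, gm.positions[keep])

    def test_idempotent_with_recorded_ceiling(self):
        rng = np.random.default_rng(6)
        dosages = rng.integers(0, 3, (200, 8)).astype(np.int8)
        depths = rng.normal(10, 3, (200, 8))
        gm = _matrix(dosages, depths=depths)
        cfg = SiteFilterConfig()
        once, rep = apply_site_filters(gm, cfg)
        cfg2 = SiteFilterConfig(depth_ceiling=rep.depth_ceiling)
        twice, rep2 = apply_site_filters(once, cfg2)
        assert twice.n_sites == once.n_sites
        assert all(v == 0 for v in rep2.removed.values())

    def test_no_depths_skips_depth_screen(self):
        gm = _matrix([[1] * 8, [1] * 8])
        out, rep = apply_site_filters(gm, SiteFilterConfig())
        assert rep.removed["low_depth"] == 0 and rep.depth_ceiling is None
        assert out.n_sites == 2


class TestWindows:
    def test_boundary_positions(self):
        gm = _matrix([[1] * 4] * 3, positions=[100_000, 100_001, 1_300_001])
        wins = make_windows(gm, 100_000)
        # site at 100,000 belongs to window [1, 100000]
        assert wins[0].spec.start == 1 and wins[0].spec.end == 100_000
        assert list(wins[0].site_idx) == [0]
        # site at 1,300,001 belongs to window index 13, start 1,300,001
        w13 = wins[13]
        assert w13.spec.start == 1_300_001
        assert list(w13.site_idx) == [2]
        # sites fell in three distinct windows; the rest are retained empty
        assert sum(w.is_empty for w in wins) == len(wins) - 3

    def test_binning_matches_histogram(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 1_000_001), 250, replace=False))
        gm = _matrix([[1] * 4] * 250, positions=list(pos))
        wins = make_windows(gm, 100_000)
        counts = [len(w.site_idx) for w in wins]
        expected, _ = np.histogram(pos, bins=np.arange(1, 1_100_002, 100_000))
        np.testing.assert_array_equal(counts, expected[: len(counts)])
        # partition property: each site in exactly one window
        assert sum(counts) == 250
        all_idx = np.concatenate([w.site_idx for w in wins])
        assert len(np.unique(all_idx)) == 250

    def test_scaffold_lengths_truncate_last_window(self):
        gm = _matrix([[1] * 4], positions=[50])
        wins = make_windows(gm, 100_000, scaffold_lengths={"s1": 150_000})
        assert len(wins) == 2
        assert wins[1].spec.end == 150_000
        assert wins[1].spec.length == 50_000
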