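"""Synthetic two-population SNP genomes with known truth.

The generator emulates the structure of a deeply diverged two-species
resequencing cohort: 10+10 diploid individuals, multi-scaffold genomes in
100-kb windows, background differentiation near window F_ST 0.32 with a
between-species fixed-difference density near 0.00022/bp, planted elevated
windows (F_ST ~ 0.6, fixed density ~ 0.0013/bp), planted candidate genes,
missing genotypes, and per-sample depths.

Background sites follow the Balding-Nichols model: an ancestral frequency
p ~ Uniform(0.05, 0.95) and independent per-population frequencies
Beta(p(1-F)/F, (1-p)(1-F)/F), genotypes Binomial(2, p_pop).  The
differentiation parameter F is calibrated by bisection so that the realized
mean window Weir-Cockerham F_ST hits the requested target.  Fixed
differences are planted explicitly (dosage 0 in one population, 2 in the
other), which also exempts them from the pooled MAF filter by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import GeneAnnotation
from .vcfio import MISSING, GenotypeMatrix, PopulationMap
from .windows import wc_components


@dataclass
class PlantedWindow:
    scaffold: str
    window_index: int          # 0-based index of the 100-kb window
    target_fst: float = 0.6
    fixed_density: float = 0.0013


@dataclass
class PlantedGene:
    gene: GeneAnnotation
    fixed_fraction: float = 0.5  # fraction of the gene region's SNPs planted fixed


@dataclass
class SyntheticGenomeConfig:
    n_scaffolds: int = 20
    scaffold_length: int = 5_000_000
    snp_density: float = 0.006          # SNPs per bp after discovery
    n_individuals: tuple[int, int] = (10, 10)
    labels: tuple[str, str] = ("SALS", "NESP")
    target_background_fst: float = 0.32
    background_fixed_density: float = 0.00022
    planted_windows: list[PlantedWindow] = field(default_factory=list)
    planted_genes: list[PlantedGene] = field(default_factory=list)
    missing_rate: float = 0.05
    depth_mean: float = 10.7
    depth_sd: float = 3.0
    window_length: int = 100_000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.background_fixed_density < 0 or self.snp_density <= 0:
            raise ValueError("densities must be non-negative (snp_density > 0)")
        n_win = self.scaffold_length // self.window_length
        seen = set()
        for pw in self.planted_windows:
            if pw.window_index < 0 or pw.window_index >= n_win:
                raise ValueError(f"planted window {pw} outside scaffold bounds")
            key = (pw.scaffold, pw.window_index)
            if key in seen:
                raise ValueError(f"planted windows overlap at {key}")
            seen.add(key)


# ---------------------------------------------------------------------------
# Balding-Nichols calibration
# ---------------------------------------------------------------------------


def _bn_site_freqs(p_anc: np.ndarray, F: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    shape1 = p_anc * (1 - F) / F
    shape2 = (1 - p_anc) * (1 - F) / F
    return rng.beta(shape1, shape2), rng.beta(shape1, shape2)


def _realized_window_fst(F: float, n_per_pop: int, n_sites: int,
                         rng: np.random.Generator, sites_per_window: int = 100,
                         missing_rate: float = 0.0, maf_min: float = 0.05,
                         fixed_fraction: float = 0.0) -> float:
    """Mean ratio-of-sums window F_ST of a probe Balding-Nichols genome.

    The probe mirrors the analysis conditions the generated data will meet:
    optional missing genotypes, the pooled MAF screen, and a fraction of
    sites planted as between-population fixed differences.
    """
    p_anc = rng.uniform(0.05, 0.95, n_sites)
    p1, p2 = _bn_site_freqs(p_anc, F, rng)
    g1 = rng.binomial(2, p1[:, None], (n_sites, n_per_pop)).astype(float)
    g2 = rng.binomial(2, p2[:, None], (n_sites, n_per_pop)).astype(float)
    if fixed_fraction > 0:
        fx = rng.random(n_sites) < fixed_fraction
        g1[fx] = 0.0
        g2[fx] = 2.0
    if missing_rate > 0:
        g1[rng.random(g1.shape) < missing_rate] = np.nan
        g2[rng.random(g2.shape) < missing_rate] = np.nan
    n1 = np.isfinite(g1).sum(axis=1)
    n2 = np.isfinite(g2).sum(axis=1)
    alt1 = np.nansum(g1, axis=1)
    alt2 = np.nansum(g2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1s = alt1 / (2 * n1)
        p2s = alt2 / (2 * n2)
        pooled = (alt1 + alt2) / (2 * (n1 + n2))
    maf = np.minimum(pooled, 1 - pooled)
    keep = maf >= maf_min
    with np.errstate(invalid="ignore", divide="ignore"):
        h1s = (g1 == 1).sum(axis=1) / n1
        h2s = (g2 == 1).sum(axis=1) / n2
    a, b, c = wc_components(n1, p1s, h1s, n2, p2s, h2s)
    ok = keep & np.isfinite(a)
    n_win = n_sites // sites_per_window
    fsts = []
    for w in range(n_win):
        sl = np.arange(w * sites_per_window, (w + 1) * sites_per_window)
        sl = sl[ok[sl]]
        denom = (a + b + c)[sl].sum()
        if len(sl) and denom > 0:
            fsts.append(a[sl].sum() / denom)
    return float(np.mean(fsts))


def calibrate_bn_parameter(
    target_fst: float,
    n_per_pop: int = 10,
    n_probe_sites: int = 5000,
    seed: int = 0,
    tol: float = 0.01,
    max_iter: int = 30,
    missing_rate: float = 0.0,
    maf_min: float = 0.05,
    fixed_fraction: float = 0.0,
) -> tuple[float, float]:
    """Bisection on the Balding-Nichols F so the realized mean window
    Weir-Cockerham F_ST matches ``target_fst``.  Returns (F, achieved).

    ``target_fst`` is the window value *after* the pooled MAF screen and
    including any planted fixed-difference fraction, so calibrated genomes
    hit the target under the same filters the scan applies.
    """
    if not (0 < target_fst < 1):
        raise ValueError("target_fst must be in (0, 1)")
    probe = dict(missing_rate=missing_rate, maf_min=maf_min, fixed_fraction=fixed_fraction)
    lo, hi = 0.001, 0.99
    f_lo = _realized_window_fst(lo, n_per_pop, n_probe_sites, np.random.default_rng(seed + 1), **probe)
    f_hi = _realized_window_fst(hi, n_per_pop, n_probe_sites, np.random.default_rng(seed + 2), **probe)
    if not (f_lo - tol <= target_fst <= f_hi + tol):
        raise ValueError(f"target F_ST {target_fst} unreachable in F=[{lo}, {hi}] "
                         f"(realized range [{f_lo:.3f}, {f_hi:.3f}])")
    F, achieved = lo, f_lo
    for it in range(max_iter):
        F = 0.5 * (lo + hi)
        achieved = _realized_window_fst(F, n_per_pop, n_probe_sites,
                                        np.random.default_rng(seed + 3 + it), **probe)
        if abs(achieved - target_fst) <= tol:
            return F, achieved
        if achieved < target_fst:
            lo = F
        else:
            hi = F
    return F, achieved


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside the synthetic VCF."""

    planted_windows: list[PlantedWindow]
    planted_genes: list[PlantedGene]
    background_F: float
    planted_F: dict[tuple[str, int], float]
    site_labels: pd.DataFrame  # scaffold, position, label

    def planted_window_keys(self) -> set[tuple[str, int]]:
        return {(pw.scaffold, pw.window_index) for pw in self.planted_windows}

    def to_tsv(self, path) -> None:
        self.site_labels.to_csv(path, sep="\t", index=False)


def generate_genome(
    config: SyntheticGenomeConfig,
) -> tuple[GenotypeMatrix, TruthTable, list[GeneAnnotation]]:
    """Generate a genotype matrix with planted truth. Deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_individuals
    lab1, lab2 = config.labels
    L = config.scaffold_length
    wlen = config.window_length

    F_bg, _ = calibrate_bn_parameter(
        config.target_background_fst, n_per_pop=min(n1, n2), seed=config.seed,
        missing_rate=config.missing_rate,
        fixed_fraction=config.background_fixed_density / config.snp_density)
    planted_F: dict[tuple[str, int], float] = {}
    target_cache: dict[tuple[float, float], float] = {}
    for pw in config.planted_windows:
        key = (pw.target_fst, pw.fixed_density)
        if key not in target_cache:
            target_cache[key], _ = calibrate_bn_parameter(
                pw.target_fst, n_per_pop=min(n1, n2), seed=config.seed + 17,
                missing_rate=config.missing_rate,
                fixed_fraction=pw.fixed_density / config.snp_density)
        planted_F[(pw.scaffold, pw.window_index)] = target_cache[key]

    planted_by_key = {(pw.scaffold, pw.window_index): pw for pw in config.planted_windows}
    genes = [pg.gene for pg in config.planted_genes]

    scaffolds_all, positions_all, labels_all = [], [], []
    dosage_blocks = []
    for s in range(config.n_scaffolds):
        scaf = f"scaffold_{s}"
        n_sites = rng.poisson(L * config.snp_density)
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=n_sites, replace=False))
        widx = (pos - 1) // wlen

        # per-site differentiation parameter and fixed-difference probability
        F_site = np.full(n_sites, F_bg)
        p_fixed = np.full(n_sites, min(config.background_fixed_density / config.snp_density, 1.0))
        for (pscaf, pwin), F_hi in planted_F.items():
            if pscaf != scaf:
                continue
            pw = planted_by_key[(pscaf, pwin)]
            in_win = widx == pwin
            F_site[in_win] = F_hi
            p_fixed[in_win] = min(pw.fixed_density / config.snp_density, 1.0)

        is_fixed = rng.random(n_sites) < p_fixed
        label = np.where(is_fixed, "planted-fixed", "background")
        in_planted = np.isin(widx, [pw.window_index for pw in config.planted_windows
                                    if pw.scaffold == scaf])
        label = np.where(in_planted & ~is_fixed, "planted-elevated", label)

        for pg in config.planted_genes:
            g = pg.gene
            if g.scaffold != scaf:
                continue
            in_gene = (pos >= g.start) & (pos <= g.end)
            gene_fixed = in_gene & (rng.random(n_sites) < pg.fixed_fraction)
            is_fixed = is_fixed | gene_fixed
            label = np.where(gene_fixed, "planted-fixed", label)

        p_anc = rng.uniform(*config.ancestral_freq_range, n_sites)
        # draw per-site with its own F (vectorized over the F values present)
        q1 = np.empty(n_sites)
        q2 = np.empty(n_sites)
        for Fv in np.unique(F_site):
            m = F_site == Fv
            q1[m], q2[m] = _bn_site_freqs(p_anc[m], Fv, rng)

        g1 = rng.binomial(2, q1[:, None], (n_sites, n1)).astype(np.int8)
        g2 = rng.binomial(2, q2[:, None], (n_sites, n2)).astype(np.int8)
        # planted fixed differences: dosage 0 vs 2, random orientation
        orient = rng.random(n_sites) < 0.5
        fx = np.where(is_fixed)[0]
        g1[fx] = np.where(orient[fx, None], 0, 2)
        g2[fx] = np.where(orient[fx, None], 2, 0)

        dosage_blocks.append(np.hstack([g1, g2]))
        scaffolds_all.append(np.full(n_sites, scaf, dtype=object))
        positions_all.append(pos)
        labels_all.append(label)

    dosages = np.vstack(dosage_blocks)
    scaffolds = np.concatenate(scaffolds_all)
    positions = np.concatenate(positions_all)
    site_labels = np.concatenate(labels_all)

    # missingness and depths
    miss = rng.random(dosages.shape) < config.missing_rate
    dosages = np.where(miss, MISSING, dosages).astype(np.int8)
    depths = np.clip(rng.normal(config.depth_mean, config.depth_sd, dosages.shape),
                     0, None).round().astype(np.float32)
    depths[miss] = 0.0

    samples = [f"{lab1}_{i:02d}" for i in range(n1)] + [f"{lab2}_{i:02d}" for i in range(n2)]
    popmap = PopulationMap({s: (lab1 if i < n1 else lab2) for i, s in enumerate(samples)})
    n_total = len(positions)
    refalt = rng.choice(np.array(["A", "C", "G", "T"]), size=(n_total, 2))
    same = refalt[:, 0] == refalt[:, 1]
    refalt[same, 1] = np.where(refalt[same, 0] == "A", "T", "A")

    gm = GenotypeMatrix(
        samples=samples,
        popmap=popmap,
        scaffolds=scaffolds,
        positions=positions,
        ref=refalt[:, 0].astype("<U1"),
        alt=refalt[:, 1].astype("<U1"),
        dosages=dosages,
        depths=depths,
    )
    truth = TruthTable(
        planted_windows=list(config.planted_windows),
        planted_genes=list(config.planted_genes),
        background_F=F_bg,
        planted_F=planted_F,
        site_labels=pd.DataFrame({
            "scaffold": scaffolds, "position": positions, "label": site_labels,
        }),
    )
    return gm, truth, genes
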