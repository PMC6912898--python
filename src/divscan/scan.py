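"""Dual-percentile outlier scan, gene proximity, and candidate-gene scoring.

Elevated windows are those strictly above the empirical 99th percentile of
both the window F_ST distribution and the fixed-difference density (df)
distribution, computed after discarding windows with too few SNPs and
scaffolds contributing too few retained windows.  The scan is exposed both
as plain functions and as a :class:`DivergenceScan` model whose ``fit()``
returns a :class:`ScanResults` object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .vcfio import GenotypeMatrix, Window, make_windows
from .windows import (
    classify_fixed,
    compute_window_stats,
    site_allele_stats,
    wc_components_sites,
    window_fst,
)

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Tunables of the outlier scan (defaults follow the study design)."""

    percentile_q: float = 0.99
    min_snps_per_window: int = 10
    min_windows_per_scaffold: int = 2
    gene_flank: int = 50_000
    candidate_flank: int = 20_000
    ci_level: float = 0.95
    window_length: int = 100_000

    def __post_init__(self):
        if not (0 < self.percentile_q < 1):
            raise ValueError("percentile_q must be in (0, 1)")
        if self.gene_flank < 0 or self.candidate_flank < 0:
            raise ValueError("flanks must be >= 0")


# ---------------------------------------------------------------------------
# thresholds and flagging
# ---------------------------------------------------------------------------


def percentile_threshold(values: np.ndarray, q: float) -> float:
    """Empirical quantile with linear interpolation between order statistics."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise ValueError("need at least two finite values for a percentile threshold")
    return float(np.quantile(vals, q, method="linear"))


@dataclass
class ElevatedWindowSet:
    """Outcome of the dual-criterion scan over retained windows.

    Index arrays refer to rows of ``retained`` (the post-discard window
    table).  ``regions`` merges runs of adjacent intersection windows on a
    scaffold into single intervals.
    """

    retained: pd.DataFrame
    fst_threshold: float
    df_threshold: float
    fst_flagged: np.ndarray
    df_flagged: np.ndarray
    intersection: np.ndarray
    regions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_scaffolds_intersection(self) -> int:
        return self.retained.iloc[self.intersection]["scaffold"].nunique()


def _merge_regions(windows: pd.DataFrame, window_length: int) -> list[tuple[str, int, int]]:
    """Merge adjacent flagged windows (same scaffold, contiguous starts)."""
    regions: list[tuple[str, int, int]] = []
    for scaf, grp in windows.groupby("scaffold", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        for _, row in grp.iterrows():
            if cur_end is not None and row["start"] == cur_end + 1:
                cur_end = row["end"]
            else:
                if cur_start is not None:
                    regions.append((scaf, int(cur_start), int(cur_end)))
                cur_start, cur_end = row["start"], row["end"]
        if cur_start is not None:
            regions.append((scaf, int(cur_start), int(cur_end)))
    return regions


def flag_elevated_windows(stats: pd.DataFrame, cfg: ScanConfig) -> ElevatedWindowSet:
    """Apply the discard rules, compute both thresholds, intersect the flags.

    Windows with fewer than ``min_snps_per_window`` SNPs are dropped first,
    then scaffolds contributing fewer than ``min_windows_per_scaffold``
    retained windows.  Thresholds are empirical quantiles of the retained
    distributions; "above" means strictly greater.
    """
    if stats.empty:
        raise ValueError("no window statistics supplied")
    retained = stats[stats["n_snps"] >= cfg.min_snps_per_window]
    scaf_counts = retained.groupby("scaffold")["start"].transform("size")
    retained = retained[scaf_counts >= cfg.min_windows_per_scaffold].reset_index(drop=True)
    if len(retained) < 100:
        logger.warning("flag_elevated_windows: only %d retained windows; percentile unstable", len(retained))

    fst_thr = percentile_threshold(retained["fst"].to_numpy(), cfg.percentile_q)
    df_thr = percentile_threshold(retained["df"].to_numpy(), cfg.percentile_q)
    fst_flag = np.where(retained["fst"].to_numpy() > fst_thr)[0]
    df_flag = np.where(retained["df"].to_numpy() > df_thr)[0]
    inter = np.intersect1d(fst_flag, df_flag)
    regions = _merge_regions(retained.iloc[inter], cfg.window_length)
    return ElevatedWindowSet(
        retained=retained,
        fst_threshold=fst_thr,
        df_threshold=df_thr,
        fst_flagged=fst_flag,
        df_flagged=df_flag,
        intersection=inter,
        regions=regions,
    )


# ---------------------------------------------------------------------------
# gene annotations and proximity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene model with 1-based inclusive coordinates."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_bed_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read gene models from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = []
    for _, row in df.iterrows():
        name = str(row[3]) if len(row) > 3 else f"gene_{len(genes)}"
        strand = str(row[5]) if len(row) > 5 else None
        genes.append(GeneAnnotation(name, str(row[0]), int(row[1]) + 1, int(row[2]), strand))
    return genes


def read_gff3_genes(path: str | Path, feature: str = "gene") -> list[GeneAnnotation]:
    """Read gene features from GFF3 (already 1-based inclusive)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("Name") or f"gene_{len(genes)}"
            genes.append(GeneAnnotation(gid, f[0], int(f[3]), int(f[4]), f[6] if f[6] in "+-" else None))
    return genes


def write_bed_genes(genes: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.scaffold}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t.\t{g.strand or '.'}\n")


def genes_near(
    regions: list[tuple[str, int, int]],
    annotations: list[GeneAnnotation],
    flank: int = 50_000,
) -> list[list[GeneAnnotation]]:
    """Genes whose flank-extended span intersects each region (inclusive)."""
    out = []
    for scaf, start, end in regions:
        hits = [
            g for g in annotations
            if g.scaffold == scaf and g.start - flank <= end and g.end + flank >= start
        ]
        out.append(hits)
    return out


# ---------------------------------------------------------------------------
# genome-wide CI and candidate genes
# ---------------------------------------------------------------------------


def genomewide_ci(window_fsts: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation interval mean +/- z*SD of window F_ST values."""
    vals = np.asarray(window_fsts, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise ValueError("need >= 2 window F_ST values")
    z = sps.norm.ppf(0.5 + level / 2)
    mu, sd = float(vals.mean()), float(vals.std(ddof=1))
    return mu - z * sd, mu + z * sd


def block_bootstrap_ci(
    window_fsts: np.ndarray, level: float = 0.95, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Scaffold-free bootstrap alternative to the normal approximation."""
    rng = np.random.default_rng(seed)
    vals = np.asarray(window_fsts, dtype=float)
    vals = vals[np.isfinite(vals)]
    means = rng.choice(vals, size=(n_boot, len(vals)), replace=True).mean(axis=1)
    alpha = (1 - level) / 2
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha))


@dataclass
class CandidateGeneReport:
    gene_id: str
    scaffold: str
    region_start: int
    region_end: int
    n_variable_sites: int
    mean_fst: float
    n_fixed: int
    pct_fixed: float
    exceeds_ci: bool


def candidate_gene_stats(
    gm: GenotypeMatrix,
    gene: GeneAnnotation,
    flank: int,
    genomewide_ci_bounds: tuple[float, float],
    pct_denominator: str = "variable",
) -> CandidateGeneReport:
    """Score a gene region (gene +/- flank) against the genome-wide CI.

    ``mean_fst`` is the ratio-of-sums F_ST over the region's sites;
    ``pct_fixed`` is 100 * n_fixed / n_variable_sites (the denominator
    choice is exposed because the printed convention is ambiguous; only
    "variable" is implemented as sites are the only positions held).
    """
    if pct_denominator != "variable":
        raise ValueError("only the 'variable' denominator is available from SNP-only input")
    start = max(1, gene.start - flank)
    end = gene.end + flank
    on = (gm.scaffolds.astype(str) == gene.scaffold) & (gm.positions >= start) & (gm.positions <= end)
    idx = np.where(on)[0]
    if len(idx) == 0:
        return CandidateGeneReport(gene.gene_id, gene.scaffold, start, end, 0,
                                   float("nan"), 0, float("nan"), False)
    sub = gm.take_sites(idx)
    stats = site_allele_stats(sub)
    a, b, c = wc_components_sites(stats)
    mean_fst = window_fst(a, b, c)
    n_fixed = int(classify_fixed(stats).sum())
    pct = 100.0 * n_fixed / len(idx)
    exceeds = bool(np.isfinite(mean_fst) and mean_fst > genomewide_ci_bounds[1])
    return CandidateGeneReport(gene.gene_id, gene.scaffold, start, end, len(idx),
                               mean_fst, n_fixed, pct, exceeds)


# ---------------------------------------------------------------------------
# inside/outside partition
# ---------------------------------------------------------------------------

PARTITION_STATS = ["fst", "dxy_per_snp", "df", "pi_pop1", "pi_pop2", "tajd_pop1", "tajd_pop2"]


def summarize_partition(retained: pd.DataFrame, elevated_idx: np.ndarray) -> pd.DataFrame:
    """Mean/SD of each statistic inside vs outside the elevated window set."""
    inside_mask = np.zeros(len(retained), dtype=bool)
    inside_mask[elevated_idx] = True
    rows = []
    for stat in PARTITION_STATS:
        vals = retained[stat].to_numpy(dtype=float)
        for where, mask in (("inside", inside_mask), ("outside", ~inside_mask)):
            sel = vals[mask]
            sel = sel[np.isfinite(sel)]
            rows.append({
                "statistic": stat,
                "partition": where,
                "mean": float(sel.mean()) if len(sel) else float("nan"),
                "sd": float(sel.std(ddof=1)) if len(sel) > 1 else float("nan"),
                "n_windows": int(mask.sum()),
                "n_na": int(mask.sum() - len(sel)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class DivergenceScan:
    """Outlier-scan model over a table of per-window statistics.

    Parameters
    ----------
    window_stats : DataFrame
        Output of :func:`divscan.windows.compute_window_stats`.
    config : ScanConfig
    genotypes : GenotypeMatrix, optional
        Needed only for candidate-gene scoring on ``fit`` results.
    """

    def __init__(self, window_stats: pd.DataFrame, config: ScanConfig | None = None,
                 genotypes: GenotypeMatrix | None = None):
        self.window_stats = window_stats
        self.config = config or ScanConfig()
        self.genotypes = genotypes

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix, config: ScanConfig | None = None,
                       scaffold_lengths=None) -> "DivergenceScan":
        config = config or ScanConfig()
        windows = make_windows(gm, config.window_length, scaffold_lengths)
        stats = compute_window_stats(gm, windows)
        return cls(stats, config, genotypes=gm)

    def fit(self) -> "ScanResults":
        elevated = flag_elevated_windows(self.window_stats, self.config)
        ci = genomewide_ci(elevated.retained["fst"].to_numpy(), self.config.ci_level)
        partition = summarize_partition(elevated.retained, elevated.intersection)
        return ScanResults(self, elevated, ci, partition)


class ScanResults:
    """Fitted scan: thresholds, flagged windows, regions, partition summary."""

    def __init__(self, model: DivergenceScan, elevated: ElevatedWindowSet,
                 ci: tuple[float, float], partition: pd.DataFrame):
        self.model = model
        self.elevated = elevated
        self.genomewide_fst_ci = ci
        self.partition = partition

    @property
    def elevated_windows(self) -> pd.DataFrame:
        return self.elevated.retained.iloc[self.elevated.intersection]

    @property
    def regions(self) -> list[tuple[str, int, int]]:
        return self.elevated.regions

    def genes_near_regions(self, annotations: list[GeneAnnotation]) -> list[list[GeneAnnotation]]:
        return genes_near(self.regions, annotations, self.model.config.gene_flank)

    def candidate_gene_reports(self, annotations: list[GeneAnnotation]) -> pd.DataFrame:
        if self.model.genotypes is None:
            raise ValueError("candidate-gene scoring needs the genotype matrix")
        reports = [
            candidate_gene_stats(self.model.genotypes, g, self.model.config.candidate_flank,
                                 self.genomewide_fst_ci)
            for g in annotations
        ]
        return pd.DataFrame([r.__dict__ for r in reports])

    def summary(self) -> str:
        e = self.elevated
        lines = [
            "Divergence scan summary",
            "=" * 55,
            f"retained windows            {len(e.retained)}",
            f"F_ST threshold (q={self.model.config.percentile_q})    {e.fst_threshold:.6g}",
            f"df threshold (q={self.model.config.percentile_q})      {e.df_threshold:.6g}",
            f"flagged by F_ST             {len(e.fst_flagged)}",
            f"flagged by df               {len(e.df_flagged)}",
            f"intersection windows        {len(e.intersection)}",
            f"intersection scaffolds      {e.n_scaffolds_intersection}",
            f"merged regions              {len(e.regions)}",
            f"genome-wide F_ST 95% CI     ({self.genomewide_fst_ci[0]:.4f}, {self.genomewide_fst_ci[1]:.4f})",
            "",
            "Inside vs outside elevated windows (mean (SD)):",
        ]
        piv = self.partition.pivot(index="statistic", columns="partition", values=["mean", "sd"])
        for stat in PARTITION_STATS:
            mi, mo = piv.loc[stat, ("mean", "inside")], piv.loc[stat, ("mean", "outside")]
            si, so = piv.loc[stat, ("sd", "inside")], piv.loc[stat, ("sd", "outside")]
            lines.append(f"  {stat:<12} inside {mi:.5g} ({si:.3g})   outside {mo:.5g} ({so:.3g})")
        return "\n".join(lines)

    def plot_manhattan(self, statistic: str = "fst", ax=None):
        """Manhattan-style plot of a window statistic with its threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        ret = self.elevated.retained
        x = np.arange(len(ret))
        scaf_codes = pd.factorize(ret["scaffold"])[0]
        ax.scatter(x, ret[statistic], c=scaf_codes % 2, cmap="tab10", s=6)
        thr = self.elevated.fst_threshold if statistic == "fst" else self.elevated.df_threshold
        ax.axhline(thr, ls="--", color="k", lw=0.8)
        ax.set_xlabel("window")
        ax.set_ylabel(statistic)
        return ax
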