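"""Reading, filtering and windowing of multi-sample biallelic SNP data.

All coordinate conventions live here: positions are 1-based with inclusive
ends (as in VCF), genotypes are stored as alt-allele dosages in {0, 1, 2}
with ``MISSING = -1``, and windows tile every scaffold from position 1 in
fixed-length, non-overlapping blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of samples to exactly two population labels."""

    assignments: Mapping[str, str]

    def __post_init__(self):
        labels = self.labels
        if len(labels) != 2:
            raise ValueError(f"expected exactly two population labels, got {labels}")
        for lab in labels:
            if len(self.samples_for(lab)) < 2:
                raise ValueError(f"population {lab!r} has fewer than 2 samples")

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lab in self.assignments.values():
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def samples_for(self, label: str) -> list[str]:
        return [s for s, lab in self.assignments.items() if lab == label]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        """Read a two-column (sample_id, population) TSV without header."""
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
        return cls(dict(zip(df["sample"], df["pop"])))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, lab in self.assignments.items():
                fh.write(f"{s}\t{lab}\n")


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic SNP sites by diploid samples, sorted by (scaffold, position).

    ``dosages`` is an int8 array of shape (n_sites, n_samples) holding the
    alt-allele dosage per genotype, with ``MISSING`` (-1) for uncalled ones.
    ``depths`` is an optional float array of the same shape (NaN = absent).
    """

    samples: list[str]
    popmap: PopulationMap
    scaffolds: np.ndarray  # object array of scaffold names, per site
    positions: np.ndarray  # int64, 1-based, per site
    ref: np.ndarray  # '<U1'
    alt: np.ndarray  # '<U1'
    dosages: np.ndarray  # int8 (n_sites, n_samples)
    depths: np.ndarray | None = None  # float32 (n_sites, n_samples)

    def __post_init__(self):
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (self.n_sites, self.n_samples):
            raise ValueError("dosage matrix shape does not match sites x samples")
        if self.n_sites and self.positions.min() < 1:
            raise ValueError("positions must be 1-based (>= 1)")
        self._check_sorted_unique()

    def _check_sorted_unique(self) -> None:
        """Sites must be grouped by scaffold (contiguous blocks, VCF contig
        order) with strictly increasing positions within each scaffold."""
        if self.n_sites < 2:
            return
        seen_done: set[str] = set()
        prev_scaf = None
        prev_pos = -1
        for scaf, pos in zip(self.scaffolds, self.positions):
            if scaf != prev_scaf:
                if scaf in seen_done:
                    raise ValueError(f"scaffold {scaf} appears in two blocks")
                if prev_scaf is not None:
                    seen_done.add(prev_scaf)
                prev_scaf, prev_pos = scaf, -1
            if pos <= prev_pos:
                raise ValueError(f"sites not strictly sorted at {scaf}:{pos}")
            prev_pos = pos

    # -- basic shape ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def pop_indices(self) -> dict[str, np.ndarray]:
        """Column indices of each population, in popmap label order."""
        return {
            lab: np.array([self.samples.index(s) for s in self.popmap.samples_for(lab)])
            for lab in self.popmap.labels
        }

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples,
            popmap=self.popmap,
            scaffolds=self.scaffolds[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosages=self.dosages[idx],
            depths=None if self.depths is None else self.depths[idx],
        )

    def sort(self) -> "GenotypeMatrix":
        first_seen = {s: i for i, s in enumerate(dict.fromkeys(self.scaffolds))}
        rank = np.array([first_seen[s] for s in self.scaffolds])
        return self.take_sites(np.lexsort((self.positions, rank)))


def sort_and_build(
    samples: list[str],
    popmap: PopulationMap,
    scaffolds: Sequence[str],
    positions: Sequence[int],
    ref: Sequence[str],
    alt: Sequence[str],
    dosages: np.ndarray,
    depths: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix, sorting sites by (scaffold, position)."""
    scaff = np.asarray(scaffolds, dtype=object)
    pos = np.asarray(positions, dtype=np.int64)
    first_seen = {s: i for i, s in enumerate(dict.fromkeys(scaff))}
    scaf_rank = np.array([first_seen[s] for s in scaff])
    order = np.lexsort((pos, scaf_rank))
    return GenotypeMatrix(
        samples=samples,
        popmap=popmap,
        scaffolds=scaff[order],
        positions=pos[order],
        ref=np.asarray(ref, dtype="<U1")[order],
        alt=np.asarray(alt, dtype="<U1")[order],
        dosages=np.asarray(dosages, dtype=np.int8)[order],
        depths=None if depths is None else np.asarray(depths, dtype=np.float32)[order],
    )


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, popmap: PopulationMap) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, keeping biallelic SNPs only.

    Multi-allelic and non-SNP records are skipped with a logged count.
    ``./.`` genotypes become MISSING; FORMAT/DP is read into depths when
    present. Raises if a popmap sample is absent from the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in popmap.assignments if s not in vcf_samples]
    if missing_samples:
        raise ValueError(f"popmap samples absent from VCF: {missing_samples}")
    samples = [s for s in vcf_samples if s in popmap.assignments]
    cols = np.array([vcf_samples.index(s) for s in samples])

    scaffolds, positions, refs, alts, dosages, depths = [], [], [], [], [], []
    skipped = 0
    has_dp = False
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        # gts012: 0/1/2 dosage, 3 = unknown
        gt = rec.gt_types[cols].astype(np.int8)
        gt[gt == 3] = MISSING
        dosages.append(gt)
        scaffolds.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_dp = True
            d = dp[cols, 0].astype(np.float32)
            d[d < 0] = np.nan
            depths.append(d)
        else:
            depths.append(np.full(len(cols), np.nan, dtype=np.float32))
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", skipped)
    n = len(positions)
    return sort_and_build(
        samples,
        popmap,
        scaffolds,
        positions,
        refs,
        alts,
        np.array(dosages, dtype=np.int8).reshape(n, len(samples)),
        np.array(depths, dtype=np.float32).reshape(n, len(samples)) if has_dp else None,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 with GT (and DP)."""
    has_dp = gm.depths is not None
    fmt = "GT:DP" if has_dp else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divscan\n")
        for scaf in dict.fromkeys(gm.scaffolds):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            fields = [
                str(gm.scaffolds[i]),
                str(gm.positions[i]),
                ".",
                str(gm.ref[i]),
                str(gm.alt[i]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for j in range(gm.n_samples):
                cell = _GT_STR[int(gm.dosages[i, j])]
                if has_dp:
                    d = gm.depths[i, j]
                    cell += ":" + (str(int(d)) if np.isfinite(d) else ".")
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------


@dataclass
class SiteFilterConfig:
    """Cohort-level SNP filters applied before any per-population statistic.

    ``depth_ceiling`` is the absolute maximum site mean depth; when None it
    is derived as genome-wide mean + ``depth_sd_multiplier`` x SD of site
    mean depths of the input matrix, and the realized value is recorded in
    the FilterReport (pass it back to make re-application exactly
    idempotent).
    """

    maf_min: float = 0.05
    max_missing_fraction: float = 0.20
    min_mean_depth: float = 3.0
    depth_sd_multiplier: float = 2.0
    depth_ceiling: float | None = None
    excluded_scaffolds: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0 <= self.max_missing_fraction <= 1):
            raise ValueError("max_missing_fraction must be in [0, 1]")
        self.excluded_scaffolds = frozenset(self.excluded_scaffolds)


@dataclass
class FilterReport:
    removed: dict[str, int]
    n_in: int
    n_out: int
    depth_ceiling: float | None = None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rule\tremoved_count\n")
            for rule, n in self.removed.items():
                fh.write(f"{rule}\t{n}\n")


RULE_ORDER = ("excluded_scaffold", "maf", "missingness", "low_depth", "high_depth")


def apply_site_filters(
    gm: GenotypeMatrix, cfg: SiteFilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the cohort SNP filters in a fixed, reported order.

    Order: excluded scaffolds -> MAF (pooled, called alleles only) ->
    missingness -> low mean depth -> high mean depth.  Depth screens are
    skipped with a warning when depths are absent.  MAF uses called alleles
    pooled over both populations.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    keep = np.ones(gm.n_sites, dtype=bool)
    removed: dict[str, int] = {}

    in_excluded = np.isin(gm.scaffolds.astype(str), list(cfg.excluded_scaffolds))
    removed["excluded_scaffold"] = int((keep & in_excluded).sum())
    keep &= ~in_excluded

    called = gm.dosages != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt_count = np.where(called, gm.dosages, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    low_maf = ~(maf >= cfg.maf_min)  # NaN (no calls) also removed here
    removed["maf"] = int((keep & low_maf).sum())
    keep &= ~low_maf

    miss_frac = 1 - called.sum(axis=1) / gm.n_samples
    high_miss = miss_frac > cfg.max_missing_fraction
    removed["missingness"] = int((keep & high_miss).sum())
    keep &= ~high_miss

    depth_ceiling = cfg.depth_ceiling
    if gm.depths is None:
        logger.warning("apply_site_filters: depths absent, depth screens skipped")
        removed["low_depth"] = 0
        removed["high_depth"] = 0
    else:
        with np.errstate(invalid="ignore"):
            site_mean = np.nanmean(gm.depths, axis=1)
        if depth_ceiling is None:
            # genome-wide stats on the input (post-biallelic) matrix
            depth_ceiling = float(np.nanmean(site_mean) + cfg.depth_sd_multiplier * np.nanstd(site_mean))
        low = site_mean < cfg.min_mean_depth
        removed["low_depth"] = int((keep & low).sum())
        keep &= ~low
        high = site_mean > depth_ceiling
        removed["high_depth"] = int((keep & high).sum())
        keep &= ~high

    out = gm.take_sites(np.where(keep)[0])
    if out.n_sites == 0:
        logger.warning("apply_site_filters: all sites removed")
    report = FilterReport(removed=removed, n_in=gm.n_sites, n_out=out.n_sites, depth_ceiling=depth_ceiling)
    return out, report


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """A 1-based, inclusive-end genomic window."""

    scaffold: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Window:
    spec: WindowSpec
    site_idx: np.ndarray  # indices into the GenotypeMatrix

    @property
    def is_empty(self) -> bool:
        return len(self.site_idx) == 0


def make_windows(
    gm: GenotypeMatrix,
    length: int = 100_000,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[Window]:
    """Tile each scaffold into non-overlapping windows of ``length`` bp.

    Windows run [1, L], [L+1, 2L], ...; a site at position p belongs to
    window index floor((p-1)/L).  Empty windows between occupied ones are
    retained (marked by an empty index array).  When scaffold lengths are
    supplied the final window is truncated to the scaffold end; otherwise
    scaffolds extend to the last full window containing a site.
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    windows: list[Window] = []
    scaffold_names = list(dict.fromkeys(gm.scaffolds))
    for scaf in scaffold_names:
        on_scaf = np.where(gm.scaffolds.astype(str) == str(scaf))[0]
        pos = gm.positions[on_scaf]
        scaf_len = None if scaffold_lengths is None else scaffold_lengths.get(str(scaf))
        if scaf_len is None:
            n_win = int((pos.max() - 1) // length) + 1 if len(pos) else 0
            scaf_len = n_win * length
        n_win = int((scaf_len - 1) // length) + 1 if scaf_len else 0
        widx = (pos - 1) // length
        for w in range(n_win):
            start = w * length + 1
            end = min((w + 1) * length, scaf_len)
            windows.append(Window(WindowSpec(str(scaf), start, end), on_scaf[widx == w]))
    return windows
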