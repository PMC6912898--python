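"""Per-window divergence and diversity statistics, from first principles.

Implements the Weir & Cockerham (1984) two-population variance components,
absolute divergence D_xy, nucleotide diversity pi, Tajima's D, observed and
expected heterozygosity, and between-population fixed-difference counts, all
on a filtered :class:`~divscan.vcfio.GenotypeMatrix`.

The windowed F_ST is the weighted "ratio of sums" estimator
sum(a) / sum(a + b + c); a mean-of-ratios column is also emitted.  Negative
values are reported as computed, never truncated at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix, Window

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-site allele stats
# ---------------------------------------------------------------------------


@dataclass
class SiteAlleleStats:
    """Vectorized per-site, per-population allele counts.

    Arrays have shape (n_sites,).  ``n_ind`` counts called diploid
    individuals; ``n_alleles = 2 * n_ind``; ``het`` counts heterozygous
    individuals; ``p`` is the alt-allele frequency among called alleles
    (NaN where nothing is called).
    """

    n_ind: tuple[np.ndarray, np.ndarray]
    alt: tuple[np.ndarray, np.ndarray]
    het: tuple[np.ndarray, np.ndarray]

    @property
    def n_alleles(self) -> tuple[np.ndarray, np.ndarray]:
        return (2 * self.n_ind[0], 2 * self.n_ind[1])

    @property
    def p(self) -> tuple[np.ndarray, np.ndarray]:
        out = []
        for alt, na in zip(self.alt, self.n_alleles):
            with np.errstate(invalid="ignore", divide="ignore"):
                out.append(np.where(na > 0, alt / np.maximum(na, 1), np.nan))
        return tuple(out)

    @property
    def h(self) -> tuple[np.ndarray, np.ndarray]:
        """Observed heterozygote frequency among called individuals."""
        out = []
        for het, ni in zip(self.het, self.n_ind):
            with np.errstate(invalid="ignore", divide="ignore"):
                out.append(np.where(ni > 0, het / np.maximum(ni, 1), np.nan))
        return tuple(out)


def site_allele_stats(gm: GenotypeMatrix) -> SiteAlleleStats:
    """Count called individuals, alt alleles and heterozygotes per population."""
    idx = gm.pop_indices
    labels = gm.popmap.labels
    n_ind, alt, het = [], [], []
    for lab in labels:
        d = gm.dosages[:, idx[lab]]
        called = d != MISSING
        n_ind.append(called.sum(axis=1))
        alt.append(np.where(called, d, 0).sum(axis=1))
        het.append((d == 1).sum(axis=1))
    return SiteAlleleStats(n_ind=tuple(n_ind), alt=tuple(alt), het=tuple(het))


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) components, r = 2 populations
# ---------------------------------------------------------------------------


def wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site W&C variance components (a, b, c) for two populations.

    ``n_i`` are called diploid individuals, ``p_i`` alt frequencies, ``h_i``
    observed heterozygote frequencies.  Sites with fewer than 2 called
    individuals in either population yield NaN components (callers skip
    them with a logged count).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(p1) | ~np.isfinite(p2)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def wc_components_sites(stats: SiteAlleleStats) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p1, p2 = stats.p
    h1, h2 = stats.h
    return wc_components(stats.n_ind[0], p1, h1, stats.n_ind[1], p2, h2)


def window_fst(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Weighted (ratio-of-sums) F_ST over a window's per-site components.

    NaN components (skipped sites) are excluded; returns NaN when no site
    has a + b + c > 0 (all monomorphic).
    """
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if not ok.any() or denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def fst_mean_of_ratios(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Unweighted mean of per-site a/(a+b+c), excluding undefined sites."""
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    theta = theta[np.isfinite(theta)]
    return float(theta.mean()) if len(theta) else float("nan")


# ---------------------------------------------------------------------------
# D_xy, pi, heterozygosity, fixed differences
# ---------------------------------------------------------------------------


def dxy_per_site(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-site absolute divergence d = p1(1-p2) + p2(1-p1)."""
    return p1 * (1 - p2) + p2 * (1 - p1)


def window_dxy(p1: np.ndarray, p2: np.ndarray, window_length: int) -> tuple[float, float]:
    """(dxy_per_snp, dxy_per_bp) over a window; NaN per-SNP value when empty."""
    d = dxy_per_site(p1, p2)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        return float("nan"), 0.0
    return float(d.mean()), float(d.sum() / window_length)


def pi_per_site(alt: np.ndarray, n_alleles: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2*c_ref*c_alt / (n*(n-1))."""
    n = np.asarray(n_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = 2.0 * alt * (n - alt) / (n * (n - 1))
    return np.where(n >= 2, contrib, np.nan)


def window_pi(alt: np.ndarray, n_alleles: np.ndarray, window_length: int) -> float:
    contrib = pi_per_site(alt, n_alleles)
    return float(np.nansum(contrib) / window_length)


def h_exp_per_site(alt: np.ndarray, n_alleles: np.ndarray) -> np.ndarray:
    """Unbiased within-population expected heterozygosity n(1-sum p^2)/(n-1)."""
    n = np.asarray(n_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
        he = n * (1 - p**2 - (1 - p) ** 2) / (n - 1)
    return np.where(n >= 2, he, np.nan)


def classify_fixed(stats: SiteAlleleStats) -> np.ndarray:
    """Boolean per site: the two populations carry disjoint allele sets.

    True iff each population is monomorphic among its called genotypes, for
    different alleles; requires at least one called individual per side.
    """
    n_a1, n_a2 = stats.n_alleles
    a1, a2 = stats.alt
    ok = (n_a1 > 0) & (n_a2 > 0)
    ref_fixed_1 = a1 == 0
    alt_fixed_1 = a1 == n_a1
    ref_fixed_2 = a2 == 0
    alt_fixed_2 = a2 == n_a2
    return ok & ((ref_fixed_1 & alt_fixed_2) | (alt_fixed_1 & ref_fixed_2))


def count_fixed_and_df(fixed_mask: np.ndarray, window_length: int) -> tuple[int, float]:
    n_fixed = int(fixed_mask.sum())
    return n_fixed, n_fixed / window_length


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 constants of Tajima (1989) for n sequences."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("Tajima constants need n >= 2 sequences")
        i = np.arange(1, n)
        a1 = float((1.0 / i).sum())
        a2 = float((1.0 / i**2).sum())
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S: int, k: float, n: int) -> float:
    """Tajima's D = (k - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    ``S`` segregating sites, ``k`` mean pairwise differences, ``n``
    sequences.  Returns NaN for S = 0 or n < 4.
    """
    if S == 0 or n < 4:
        return float("nan")
    c = TajimaConstants.for_n(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((k - S / c.a1) / np.sqrt(var))


def _window_tajima(alt: np.ndarray, n_ind: np.ndarray) -> float:
    """Tajima's D for one window and one population.

    n is 2x the modal number of called individuals in the window; sites
    with other called counts still contribute to S and k (per-site n used
    for k's pairwise normalization).
    """
    called = n_ind > 0
    if not called.any():
        return float("nan")
    counts = np.bincount(n_ind[called])
    n_modal = 2 * int(counts.argmax())
    n_alleles = 2 * n_ind
    seg = (alt > 0) & (alt < n_alleles)
    S = int(seg.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        k_site = 2.0 * alt * (n_alleles - alt) / (n_alleles * (n_alleles - 1.0))
    k = float(np.nansum(np.where(n_alleles >= 2, k_site, 0.0)))
    return tajimas_d(S, k, n_modal)


# ---------------------------------------------------------------------------
# full per-window computation
# ---------------------------------------------------------------------------

STAT_COLUMNS = [
    "scaffold", "start", "end", "n_snps", "fst", "fst_mean_of_ratios",
    "dxy_per_snp", "dxy_per_bp", "pi_pop1", "pi_pop2", "tajd_pop1",
    "tajd_pop2", "h_obs", "h_exp", "n_fixed", "df",
]


def compute_window_stats(gm: GenotypeMatrix, windows: list[Window]) -> pd.DataFrame:
    """One row of divergence/diversity statistics per non-empty window.

    Returns a DataFrame with columns ``STAT_COLUMNS``; undefined values are
    NaN.  Population 1/2 follow the popmap label order.
    """
    stats = site_allele_stats(gm)
    a, b, c = wc_components_sites(stats)
    p1, p2 = stats.p
    h1, h2 = stats.h
    alt1, alt2 = stats.alt
    na1, na2 = stats.n_alleles
    fixed = classify_fixed(stats)
    n_skipped = int(((stats.n_ind[0] < 2) | (stats.n_ind[1] < 2)).sum())
    if n_skipped:
        logger.info("compute_window_stats: %d sites skipped for F_ST (<2 called per pop)", n_skipped)

    he1 = h_exp_per_site(alt1, na1)
    he2 = h_exp_per_site(alt2, na2)
    with np.errstate(invalid="ignore"):
        h_exp_site = np.nanmean(np.stack([he1, he2]), axis=0)
        h_obs_site = np.nanmean(np.stack([h1, h2]), axis=0)

    rows = []
    for win in windows:
        idx = win.site_idx
        if len(idx) == 0:
            continue
        L = win.spec.length
        n_fixed, df = count_fixed_and_df(fixed[idx], L)
        dxy_snp, dxy_bp = window_dxy(p1[idx], p2[idx], L)
        rows.append({
            "scaffold": win.spec.scaffold,
            "start": win.spec.start,
            "end": win.spec.end,
            "n_snps": len(idx),
            "fst": window_fst(a[idx], b[idx], c[idx]),
            "fst_mean_of_ratios": fst_mean_of_ratios(a[idx], b[idx], c[idx]),
            "dxy_per_snp": dxy_snp,
            "dxy_per_bp": dxy_bp,
            "pi_pop1": window_pi(alt1[idx], na1[idx], L),
            "pi_pop2": window_pi(alt2[idx], na2[idx], L),
            "tajd_pop1": _window_tajima(alt1[idx], stats.n_ind[0][idx]),
            "tajd_pop2": _window_tajima(alt2[idx], stats.n_ind[1][idx]),
            "h_obs": float(np.nanmean(h_obs_site[idx])),
            "h_exp": float(np.nanmean(h_exp_site[idx])),
            "n_fixed": n_fixed,
            "df": df,
        })
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def write_window_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")
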