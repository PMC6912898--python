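"""The ten-component ABC summary-statistic vector.

For two populations of diploid samples typed at unlinked biallelic loci:

index  statistic
0,1    mean, variance of nonzero per-locus genic diversity, population 1
2      proportion of zero-diversity loci, population 1
3,4    mean, variance of nonzero per-locus genic diversity, population 2
5      proportion of zero-diversity loci, population 2
6,7    mean, variance of nonzero per-locus pairwise Weir-Cockerham F_ST
8,9    mean, variance of nonzero per-locus Nei (1972) distance

Genic diversity is the unbiased form n(1 - sum p^2)/(n - 1) over the n
called alleles of a population.  "Nonzero" means finite and different from
zero: the Nei distance is +inf at loci where the populations share no
allele, and per-locus F_ST is undefined at loci monomorphic in the pooled
sample; both are excluded from the nonzero means/variances (variance uses
ddof=1 and is 0 when fewer than two values remain).
"""

from __future__ import annotations

import numpy as np

from .vcfio import GenotypeMatrix
from .windows import site_allele_stats, wc_components

STAT_NAMES = [
    "gd_mean_pop1", "gd_var_pop1", "gd_pzero_pop1",
    "gd_mean_pop2", "gd_var_pop2", "gd_pzero_pop2",
    "fst_mean", "fst_var",
    "nei_mean", "nei_var",
]


def _nonzero_mean_var(x: np.ndarray) -> tuple[float, float]:
    x = x[np.isfinite(x) & (x != 0)]
    if len(x) == 0:
        return 0.0, 0.0
    m = float(x.mean())
    v = float(x.var(ddof=1)) if len(x) > 1 else 0.0
    return m, v


def genic_diversity(p: np.ndarray, n_alleles: np.ndarray | float) -> np.ndarray:
    """Unbiased per-locus genic diversity n(1 - p^2 - q^2)/(n - 1)."""
    n = np.asarray(n_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return n * (1 - p**2 - (1 - p) ** 2) / (n - 1)


def nei_distance(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-locus Nei distance -ln(J12 / sqrt(J1*J2)) for a biallelic locus."""
    q1, q2 = 1 - p1, 1 - p2
    j1 = p1**2 + q1**2
    j2 = p2**2 + q2**2
    j12 = p1 * p2 + q1 * q2
    with np.errstate(divide="ignore", invalid="ignore"):
        return -np.log(j12 / np.sqrt(j1 * j2))


def stats_from_locus_arrays(
    n1_ind: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2_ind: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> np.ndarray:
    """Assemble the 10-vector from per-locus per-population frequencies."""
    gd1 = genic_diversity(p1, 2 * np.asarray(n1_ind, dtype=float))
    gd2 = genic_diversity(p2, 2 * np.asarray(n2_ind, dtype=float))
    a, b, c = wc_components(n1_ind, p1, h1, n2_ind, p2, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    nei = nei_distance(p1, p2)

    out = np.empty(10)
    out[0], out[1] = _nonzero_mean_var(gd1)
    out[2] = float((gd1 == 0).mean()) if len(gd1) else 0.0
    out[3], out[4] = _nonzero_mean_var(gd2)
    out[5] = float((gd2 == 0).mean()) if len(gd2) else 0.0
    out[6], out[7] = _nonzero_mean_var(theta)
    out[8], out[9] = _nonzero_mean_var(nei)
    return out


def compute_summary_stats(gm: GenotypeMatrix) -> np.ndarray:
    """The 10-component vector from a GenotypeMatrix of unlinked loci."""
    s = site_allele_stats(gm)
    p1, p2 = s.p
    h1, h2 = s.h
    return stats_from_locus_arrays(
        s.n_ind[0].astype(float), p1, h1, s.n_ind[1].astype(float), p2, h2
    )


def stats_from_masks(masks: np.ndarray, sample_sizes: tuple[int, int]) -> np.ndarray:
    """Fast path: the 10-vector straight from coalescent chromosome masks."""
    from .coalescent import masks_to_pop_arrays

    p1, h1, p2, h2 = masks_to_pop_arrays(masks, sample_sizes)
    n0 = np.full(len(masks), float(sample_sizes[0]))
    n1 = np.full(len(masks), float(sample_sizes[1]))
    return stats_from_locus_arrays(n0, p1, h1, n1, p2, h2)
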