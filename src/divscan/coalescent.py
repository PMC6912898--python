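"""Structured Kingman coalescent for unlinked SNP loci.

Each locus is an independent genealogy of the sampled chromosomes, run
backward in time over the scenario's populations with piecewise-constant
diploid sizes (pairwise coalescence rate 1/(2N) per generation within a
population).  Population merges and the single admixture pulse are applied
at the compiled breakpoint times.

Each locus carries exactly one mutation, simulated in the infinite-sites
low-mutation limit: conditional on a locus being variable, its genealogy is
distributed proportionally to total branch length, and the mutation falls
uniformly along the branches.  (Placing the mutation branch-proportionally
on an *unweighted* genealogy — the ms ``-s 1`` shortcut — distorts the site
frequency spectrum, overweighting singletons; length-biasing the genealogy
restores the neutral 1/i spectrum exactly.)  The length-biased draw is
implemented by importance resampling among ``RESAMPLE_K`` candidate
genealogies per locus, with O(1/K) residual bias, undetectable at the
locus counts used here.  Every locus is variable in the pooled sample by
construction.

A locus is returned as a 64-bit mask over sampled chromosomes (bit set =
carries the derived allele): population 1 occupies bits 0..2*n0-1 and
population 2 bits 2*n0..2*(n0+n1)-1; chromosomes 2j and 2j+1 form diploid
individual j.  Chromosome exchangeability under the coalescent makes this
fixed pairing equivalent to random pairing.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .demography import EventTable, ScalingConstants, Scenario, build_event_table
from .vcfio import GenotypeMatrix, PopulationMap

_MAX_CHROMS = 64

#: candidate genealogies per locus for the length-biased draw
RESAMPLE_K = 8


@njit(cache=True)
def _one_tree(n0, n1, times, types, sizes, admix_r, branch_len, branch_mask):  # pragma: no cover - jitted
    """Simulate one genealogy; fill branch arrays, return total length."""
    n = n0 + n1
    lin_pop = np.empty(n, np.int64)
    lin_mask = np.empty(n, np.uint64)
    lin_birth = np.zeros(n, np.float64)
    for i in range(n0):
        lin_pop[i] = 0
        lin_mask[i] = np.uint64(1) << np.uint64(i)
    for i in range(n1):
        lin_pop[n0 + i] = 1
        lin_mask[n0 + i] = np.uint64(1) << np.uint64(n0 + i)
    n_active = n
    nb = 0
    t = 0.0
    epoch = 0
    n_events = len(times)
    rates = np.zeros(4, np.float64)
    k = np.zeros(4, np.int64)
    k[0] = n0
    k[1] = n1
    while n_active > 1:
        t_end = times[epoch] if epoch < n_events else 1.0e308
        lam = 0.0
        for p in range(4):
            rates[p] = k[p] * (k[p] - 1) / 2.0 / (2.0 * sizes[epoch, p])
            lam += rates[p]
        if lam > 0.0:
            wait = np.random.exponential(1.0 / lam)
        else:
            wait = 1.0e308
        if t + wait >= t_end:
            t = t_end
            ev = types[epoch]
            if ev == 1:  # admixture pulse: NESP lineage stays w.p. r else to SALS
                for i in range(n_active):
                    if lin_pop[i] == 1 and np.random.random() >= admix_r:
                        lin_pop[i] = 0
                        k[1] -= 1
                        k[0] += 1
            elif ev == 2:  # NESP joins ancestral NESP
                for i in range(n_active):
                    if lin_pop[i] == 1:
                        lin_pop[i] = 2
                k[2] += k[1]
                k[1] = 0
            elif ev == 3:  # SALS + ancestral NESP join the common ancestor
                for i in range(n_active):
                    if lin_pop[i] == 0 or lin_pop[i] == 2:
                        lin_pop[i] = 3
                k[3] += k[0] + k[2]
                k[0] = 0
                k[2] = 0
            epoch += 1
            continue
        t += wait
        u = np.random.random() * lam
        p_sel = 3
        acc = 0.0
        for p in range(4):
            acc += rates[p]
            if u < acc:
                p_sel = p
                break
        kp = k[p_sel]
        i_ord = np.random.randint(kp)
        j_ord = np.random.randint(kp - 1)
        if j_ord >= i_ord:
            j_ord += 1
        if i_ord > j_ord:
            i_ord, j_ord = j_ord, i_ord
        ii = -1
        jj = -1
        seen = 0
        for i in range(n_active):
            if lin_pop[i] == p_sel:
                if seen == i_ord:
                    ii = i
                elif seen == j_ord:
                    jj = i
                seen += 1
        branch_len[nb] = t - lin_birth[ii]
        branch_mask[nb] = lin_mask[ii]
        nb += 1
        branch_len[nb] = t - lin_birth[jj]
        branch_mask[nb] = lin_mask[jj]
        nb += 1
        lin_mask[ii] = lin_mask[ii] | lin_mask[jj]
        lin_birth[ii] = t
        lin_pop[jj] = lin_pop[n_active - 1]
        lin_mask[jj] = lin_mask[n_active - 1]
        lin_birth[jj] = lin_birth[n_active - 1]
        n_active -= 1
        k[p_sel] -= 1
    total = 0.0
    for i in range(nb):
        total += branch_len[i]
    return total


@njit(cache=True)
def _one_locus(n0, n1, times, types, sizes, admix_r, k_resample,
               blen, bmask):  # pragma: no cover - jitted
    """One SNP locus: length-biased genealogy, mutation uniform on branches."""
    nb = 2 * (n0 + n1)
    tot = 0.0
    for j in range(k_resample):
        tot += _one_tree(n0, n1, times, types, sizes, admix_r, blen[j], bmask[j])
    u = np.random.random() * tot
    acc = 0.0
    for j in range(k_resample):
        for i in range(nb):
            acc += blen[j, i]
            if u < acc:
                return bmask[j, i]
    return bmask[k_resample - 1, nb - 3]


@njit(cache=True)
def _simulate_masks_jit(n0, n1, times, types, sizes, admix_r, n_loci, seed,
                        k_resample):  # pragma: no cover
    np.random.seed(seed)
    out = np.empty(n_loci, np.uint64)
    nb = 2 * (n0 + n1)
    blen = np.zeros((k_resample, nb), np.float64)
    bmask = np.zeros((k_resample, nb), np.uint64)
    for l in range(n_loci):
        out[l] = _one_locus(n0, n1, times, types, sizes, admix_r, k_resample, blen, bmask)
    return out


def simulate_masks(
    event_table: EventTable,
    n_loci: int,
    sample_sizes: tuple[int, int] = (10, 10),
    seed: int = 0,
    resample_k: int = RESAMPLE_K,
) -> np.ndarray:
    """Simulate ``n_loci`` unlinked SNP loci; returns uint64 chromosome masks."""
    n0, n1 = sample_sizes
    if 2 * (n0 + n1) > _MAX_CHROMS:
        raise ValueError("at most 32 diploid samples supported")
    if np.any(event_table.sizes <= 0):
        raise ValueError("non-positive population size in event table")
    return _simulate_masks_jit(
        2 * n0, 2 * n1,
        event_table.times, event_table.types, event_table.sizes,
        event_table.admix_r, n_loci, int(seed) % (2**31 - 1), resample_k,
    )


def single_population_masks(n_diploid: int, N: float, n_loci: int, seed: int = 0,
                            resample_k: int = RESAMPLE_K) -> np.ndarray:
    """Panmictic control: one population of constant size N."""
    table = EventTable(
        times=np.empty(0, dtype=np.float64),
        types=np.empty(0, dtype=np.int64),
        sizes=np.full((1, 4), float(N), dtype=np.float64),
        admix_r=0.0,
    )
    return _simulate_masks_jit(2 * n_diploid, 0, table.times, table.types,
                               table.sizes, 0.0, n_loci,
                               int(seed) % (2**31 - 1), resample_k)


# ---------------------------------------------------------------------------
# mask decoding
# ---------------------------------------------------------------------------


def masks_to_dosages(masks: np.ndarray, n_individuals: int) -> np.ndarray:
    """Decode chromosome masks into an (n_loci, n_individuals) dosage matrix."""
    masks = np.asarray(masks, dtype=np.uint64)
    j = np.arange(n_individuals, dtype=np.uint64)
    lo = (masks[:, None] >> (np.uint64(2) * j)) & np.uint64(1)
    hi = (masks[:, None] >> (np.uint64(2) * j + np.uint64(1))) & np.uint64(1)
    return (lo + hi).astype(np.int8)


def masks_to_pop_arrays(
    masks: np.ndarray, sample_sizes: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (p1, h1, p2, h2): alt frequency and het frequency per population."""
    masks = np.asarray(masks, dtype=np.uint64)
    n0, n1 = sample_sizes
    even = np.uint64(0x5555555555555555)
    het_bits = (masks ^ (masks >> np.uint64(1))) & even
    pop0 = np.uint64((1 << (2 * n0)) - 1)
    pop1 = np.uint64(((1 << (2 * (n0 + n1))) - 1) ^ int(pop0))
    p1 = np.bitwise_count(masks & pop0) / (2 * n0)
    p2 = np.bitwise_count(masks & pop1) / (2 * n1)
    h1 = np.bitwise_count(het_bits & pop0) / n0
    h2 = np.bitwise_count(het_bits & pop1) / n1
    return p1, h1, p2, h2


def simulate_dataset(
    scenario: Scenario,
    params: dict[str, float],
    n_loci: int,
    sample_sizes: tuple[int, int] = (10, 10),
    seed: int = 0,
    constants: ScalingConstants | None = None,
    labels: tuple[str, str] = ("SALS", "NESP"),
) -> GenotypeMatrix:
    """Simulate a dataset of unlinked SNP loci as a GenotypeMatrix.

    Each locus is placed on its own pseudo-scaffold (loci are unlinked).
    """
    table = build_event_table(scenario, params, constants)
    masks = simulate_masks(table, n_loci, sample_sizes, seed)
    n0, n1 = sample_sizes
    dosages = masks_to_dosages(masks, n0 + n1)
    samples = [f"{labels[0]}_{i:02d}" for i in range(n0)] + [
        f"{labels[1]}_{i:02d}" for i in range(n1)
    ]
    popmap = PopulationMap({s: labels[0] if i < n0 else labels[1] for i, s in enumerate(samples)})
    width = len(str(n_loci))
    return GenotypeMatrix(
        samples=samples,
        popmap=popmap,
        scaffolds=np.array([f"locus_{i:0{width}d}" for i in range(n_loci)], dtype=object),
        positions=np.ones(n_loci, dtype=np.int64),
        ref=np.full(n_loci, "A", dtype="<U1"),
        alt=np.full(n_loci, "T", dtype="<U1"),
        dosages=dosages,
    )
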