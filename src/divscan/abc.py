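"""Approximate Bayesian computation: reference tables, model choice,
parameter estimation, and posterior error rates.

Model choice follows the logistic-regression approach: pool the per-scenario
reference tables, standardize every summary statistic by its pooled median
absolute deviation (falling back to the SD when the MAD is zero), rank rows
by Euclidean distance to the observed vector, keep the closest fraction, and
fit a multinomial logistic regression of scenario label on the centered
statistics with Epanechnikov weights in distance; posterior probabilities
are the fitted class probabilities at the observed point.

Parameter estimation is the weighted local-linear adjustment of Beaumont,
Zhang & Balding (2002), ridge-regularized against the collinearity of the
statistic families and performed on a logit scale mapped to each
parameter's prior support; posteriors are summarized by the weighted
median and the equal-tailed 95% interval of the adjusted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from sklearn.linear_model import LogisticRegression

from .coalescent import simulate_masks
from .demography import (
    PriorSet,
    ScalingConstants,
    Scenario,
    SCENARIO_PARAMS,
    build_event_table,
    sample_prior,
)
from .sumstats import STAT_NAMES, stats_from_masks
from .vcfio import MISSING, GenotypeMatrix
from .windows import site_allele_stats, wc_components_sites

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Per-scenario collection of (parameter vector, summary-stat vector)."""

    scenario: Scenario
    params: pd.DataFrame          # one column per scenario parameter
    stats: np.ndarray             # (n_sims, 10)
    n_loci: int
    sample_sizes: tuple[int, int]
    seeds: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    priors: PriorSet | None = None

    @property
    def n_sims(self) -> int:
        return len(self.params)

    def to_tsv(self, path) -> None:
        df = self.params.copy()
        for i, name in enumerate(STAT_NAMES):
            df[name] = self.stats[:, i]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, scenario: Scenario, n_loci: int = 0,
                 sample_sizes: tuple[int, int] = (10, 10),
                 priors: PriorSet | None = None) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t")
        stats = df[STAT_NAMES].to_numpy()
        params = df.drop(columns=STAT_NAMES)
        return cls(scenario, params, stats, n_loci, sample_sizes, priors=priors)


def build_reference_table(
    scenario: Scenario,
    priors: PriorSet | None = None,
    n_sims: int = 1000,
    n_loci: int = 2000,
    seed: int = 0,
    sample_sizes: tuple[int, int] = (10, 10),
    constants: ScalingConstants | None = None,
    progress_every: int = 0,
) -> ReferenceTable:
    """Simulate ``n_sims`` draws from the scenario's prior predictive.

    Reproducible under ``seed``; per-row kernel seeds are recorded for
    exact replay of any single row.
    """
    priors = priors or PriorSet()
    constants = constants or ScalingConstants()
    rng = np.random.default_rng(seed)
    names = SCENARIO_PARAMS[scenario]
    param_rows = np.empty((n_sims, len(names)))
    stats = np.empty((n_sims, len(STAT_NAMES)))
    seeds = np.empty(n_sims, dtype=np.int64)
    for i in range(n_sims):
        draw = sample_prior(scenario, priors, rng)
        table = build_event_table(scenario, draw, constants)
        row_seed = int(rng.integers(2**31 - 1))
        masks = simulate_masks(table, n_loci, sample_sizes, row_seed)
        stats[i] = stats_from_masks(masks, sample_sizes)
        param_rows[i] = [draw[n] for n in names]
        seeds[i] = row_seed
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("%s: %d/%d simulations", scenario.value, i + 1, n_sims)
    return ReferenceTable(
        scenario=scenario,
        params=pd.DataFrame(param_rows, columns=list(names)),
        stats=stats,
        n_loci=n_loci,
        sample_sizes=sample_sizes,
        seeds=seeds,
        priors=priors,
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _robust_scale(stats: np.ndarray) -> np.ndarray:
    scale = median_abs_deviation(stats, axis=0)
    sd = stats.std(axis=0)
    scale = np.where(scale > 0, scale, sd)
    return np.where(scale > 0, scale, 1.0)


def _distances(stats: np.ndarray, observed: np.ndarray, scale: np.ndarray) -> np.ndarray:
    z = (stats - observed) / scale
    return np.sqrt((z**2).sum(axis=1))


def _epanechnikov(d: np.ndarray, d_max: float) -> np.ndarray:
    if d_max <= 0:
        return np.ones_like(d)
    w = 1 - (d / d_max) ** 2
    return np.clip(w, 1e-12, None)  # keep the boundary row usable


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------


@dataclass
class ModelChoiceResult:
    posterior: dict[str, float]
    n_accepted: int
    distance_threshold: float
    flags: list[str] = field(default_factory=list)

    @property
    def best(self) -> str:
        return max(self.posterior, key=self.posterior.get)


def abc_model_choice(
    observed: np.ndarray,
    tables: dict[Scenario, ReferenceTable] | list[ReferenceTable],
    accept_fraction: float = 0.01,
) -> ModelChoiceResult:
    """Posterior scenario probabilities by weighted multinomial logistic
    regression on the closest ``accept_fraction`` of pooled simulations."""
    if isinstance(tables, dict):
        tables = list(tables.values())
    scenarios = [t.scenario.value for t in tables]
    pooled = np.vstack([t.stats for t in tables])
    labels = np.concatenate([np.full(t.n_sims, i) for i, t in enumerate(tables)])
    scale = _robust_scale(pooled)
    d = _distances(pooled, observed, scale)
    n_keep = max(int(np.ceil(accept_fraction * len(d))), len(scenarios) + 1)
    order = np.argsort(d, kind="stable")[:n_keep]
    d_max = float(d[order[-1]])
    w = _epanechnikov(d[order], d_max)
    X = (pooled[order] - observed) / scale
    y = labels[order]

    flags = []
    probs = np.zeros(len(scenarios))
    present = np.unique(y)
    if len(present) == 1:
        probs[present[0]] = 1.0
        flags.extend(f"scenario {scenarios[i]} absent from accepted set"
                     for i in range(len(scenarios)) if i != present[0])
    else:
        clf = LogisticRegression(C=1e6, max_iter=2000)
        clf.fit(X, y, sample_weight=w)
        p = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        for cls_idx, pi in zip(clf.classes_, p):
            probs[cls_idx] = pi
        for i in range(len(scenarios)):
            if i not in present:
                flags.append(f"scenario {scenarios[i]} absent from accepted set")
    probs = probs / probs.sum()
    return ModelChoiceResult(
        posterior=dict(zip(scenarios, probs.tolist())),
        n_accepted=n_keep,
        distance_threshold=d_max,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

# parameters adjusted on a log scale (times and sizes; proportions stay linear)
_LOG_PARAMS = {"T1", "T2", "T_rise", "T_fall", "T_admix",
               "N_SALS", "N_NESP", "N_AncestralNESP", "N_Ancestral",
               "N_smallNESP", "N_largeNESP"}


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(q, cum, x)


@dataclass
class ParameterPosterior:
    """Equal-tailed posterior summaries per parameter (2.5/50/97.5%)."""

    table: pd.DataFrame  # index: parameter; columns: median, lower, upper
    adjusted: pd.DataFrame
    weights: np.ndarray
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Parameter posterior (median [95% equal-tailed interval])",
                 "=" * 58]
        for name, row in self.table.iterrows():
            lines.append(f"  {name:<16} {row['median']:>12.4g}  "
                         f"[{row['lower']:.4g}, {row['upper']:.4g}]")
        return "\n".join(lines)


def abc_parameter_estimate(
    observed: np.ndarray,
    table: ReferenceTable,
    accept_fraction: float = 0.01,
    ridge_lambda: float = 0.05,
) -> ParameterPosterior:
    """Rejection + weighted ridge-regularized local-linear adjustment.

    The local-linear regression is ridge-penalized (relative strength
    ``ridge_lambda`` on the covariate block) because the summary statistics
    are collinear (mean/variance pairs), which destabilizes the plain
    least-squares adjustment.  Parameters with known prior bounds are
    adjusted on a logit scale mapped to the prior support, so the adjusted
    posterior cannot leave the prior range; unbounded positive parameters
    fall back to a log scale.
    """
    scale = _robust_scale(table.stats)
    d = _distances(table.stats, observed, scale)
    n_keep = max(int(np.ceil(accept_fraction * len(d))), 20)
    order = np.argsort(d, kind="stable")[:n_keep]
    d_max = float(d[order[-1]])
    w = _epanechnikov(d[order], d_max)
    X = (table.stats[order] - observed) / scale
    design = np.column_stack([np.ones(len(order)), X])
    sw = np.sqrt(w)

    flags: list[str] = []
    adj = {}
    eps = 1e-9
    for name in table.params.columns:
        theta = table.params[name].to_numpy()[order].astype(float)
        bounds = table.priors.bounds.get(name) if table.priors is not None else None
        if bounds is not None:
            # logit transform to the prior support: the adjusted posterior
            # cannot leave the prior range (abc-package style)
            lo_b, hi_b = bounds
            u = np.clip((theta - lo_b) / (hi_b - lo_b), eps, 1 - eps)
            t = np.log(u / (1 - u))
            back = lambda x, lo_b=lo_b, hi_b=hi_b: lo_b + (hi_b - lo_b) / (1 + np.exp(-x))
        elif name in _LOG_PARAMS and (theta > 0).all():
            t = np.log(theta)
            back = np.exp
        else:
            t = theta
            back = lambda x: x
        A = design * sw[:, None]
        AtA = A.T @ A
        p_cov = AtA.shape[0] - 1
        pen = ridge_lambda * (np.trace(AtA[1:, 1:]) / max(p_cov, 1)) * np.eye(AtA.shape[0])
        pen[0, 0] = 0.0  # never penalize the intercept
        try:
            coef = np.linalg.solve(AtA + pen, A.T @ (t * sw))
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(A, t * sw, rcond=None)
        fitted = design @ coef
        resid = t - fitted
        # undo the small-sample variance shrinkage of the weighted fit
        n_eff = w.sum() ** 2 / (w**2).sum()
        if n_eff > design.shape[1] + 1:
            resid = resid * np.sqrt(n_eff / (n_eff - design.shape[1]))
        adjusted = coef[0] + resid
        if not np.all(np.isfinite(adjusted)):
            adjusted = t
            flags.append(f"{name}: singular regression, rejection posterior used")
        adj[name] = back(adjusted)

    adj_df = pd.DataFrame(adj)
    rows = {}
    for name in adj_df.columns:
        lo, med, hi = _weighted_quantile(adj_df[name].to_numpy(), w,
                                         np.array([0.025, 0.5, 0.975]))
        rows[name] = {"median": med, "lower": lo, "upper": hi}
    return ParameterPosterior(
        table=pd.DataFrame(rows).T[["median", "lower", "upper"]],
        adjusted=adj_df,
        weights=w,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# posterior error rate
# ---------------------------------------------------------------------------


def posterior_error_rate(
    tables: dict[Scenario, ReferenceTable] | list[ReferenceTable],
    observed: np.ndarray,
    n_pseudo: int = 1000,
    n_closest: int = 500,
    seed: int = 0,
    accept_fraction: float = 0.01,
    constants: ScalingConstants | None = None,
) -> float:
    """Scenario-choice error among pseudo-observed datasets resampled from
    the ``n_closest`` simulations nearest the observed vector."""
    if isinstance(tables, dict):
        tables = list(tables.values())
    constants = constants or ScalingConstants()
    rng = np.random.default_rng(seed)
    pooled = np.vstack([t.stats for t in tables])
    scale = _robust_scale(pooled)
    d = _distances(pooled, observed, scale)
    order = np.argsort(d, kind="stable")[:n_closest]
    owner = np.concatenate([np.full(t.n_sims, i) for i, t in enumerate(tables)])
    offsets = np.concatenate([[0], np.cumsum([t.n_sims for t in tables])])

    errors = 0
    for _ in range(n_pseudo):
        row = int(rng.choice(order))
        ti = int(owner[row])
        t = tables[ti]
        local = row - offsets[ti]
        params = t.params.iloc[local].to_dict()
        ev = build_event_table(t.scenario, params, constants)
        masks = simulate_masks(ev, t.n_loci, t.sample_sizes, int(rng.integers(2**31 - 1)))
        stats = stats_from_masks(masks, t.sample_sizes)
        result = abc_model_choice(stats, tables, accept_fraction)
        if result.best != t.scenario.value:
            errors += 1
    return errors / n_pseudo


# ---------------------------------------------------------------------------
# observed-data SNP selection
# ---------------------------------------------------------------------------


def per_snp_fst(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site Weir-Cockerham a/(a+b+c); NaN where undefined."""
    a, b, c = wc_components_sites(site_allele_stats(gm))
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / (a + b + c)


def select_abc_snps(
    gm: GenotypeMatrix,
    n_per_set: int = 2000,
    n_sets: int = 3,
    min_depth_all: float = 5,
    mean_depth_range: tuple[float, float] = (8, 12),
    fst_sd_window: float = 1.0,
    min_spacing: int = 20_000,
    seed: int = 0,
) -> list[np.ndarray]:
    """Select disjoint sets of high-confidence, effectively neutral SNPs.

    Filters: no missing genotypes; depth >= ``min_depth_all`` in every
    individual; site mean depth strictly inside ``mean_depth_range``;
    per-SNP F_ST within ``fst_sd_window`` SDs of the genome-wide mean.
    Spacing (>= ``min_spacing`` bp within a scaffold) is enforced greedily
    over a seeded random ordering, then the pool is split into disjoint
    random sets.
    """
    if gm.depths is None:
        raise ValueError("SNP selection requires per-sample depths")
    rng = np.random.default_rng(seed)

    no_missing = (gm.dosages != MISSING).all(axis=1)
    depth_ok = np.nan_to_num(gm.depths, nan=-1.0).min(axis=1) >= min_depth_all
    site_mean = np.nanmean(gm.depths, axis=1)
    mean_ok = (site_mean > mean_depth_range[0]) & (site_mean < mean_depth_range[1])
    fst = per_snp_fst(gm)
    finite = np.isfinite(fst)
    mu, sd = float(fst[finite].mean()), float(fst[finite].std())
    fst_ok = finite & (np.abs(fst - mu) <= fst_sd_window * sd)
    candidates = np.where(no_missing & depth_ok & mean_ok & fst_ok)[0]

    # greedy spacing over a random ordering
    shuffled = rng.permutation(candidates)
    taken_pos: dict[str, list[int]] = {}
    pool = []
    for i in shuffled:
        scaf = str(gm.scaffolds[i])
        pos = int(gm.positions[i])
        nearby = taken_pos.setdefault(scaf, [])
        if all(abs(pos - q) >= min_spacing for q in nearby):
            nearby.append(pos)
            pool.append(i)
    pool = np.array(sorted(pool))

    needed = n_per_set * n_sets
    if len(pool) < needed:
        raise ValueError(f"eligible SNP pool has {len(pool)} sites; "
                         f"{needed} required for {n_sets} sets of {n_per_set}")
    chosen = rng.permutation(pool)[:needed]
    return [np.sort(chosen[k * n_per_set:(k + 1) * n_per_set]) for k in range(n_sets)]


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class DemographicABC:
    """ABC model over an observed summary-stat vector and reference tables.

    Parameters
    ----------
    observed : (10,) array
        Output of :func:`divscan.sumstats.compute_summary_stats`.
    tables : mapping of Scenario -> ReferenceTable
    accept_fraction : float
        Fraction of pooled simulations retained for the regressions.
    """

    def __init__(self, observed: np.ndarray,
                 tables: dict[Scenario, ReferenceTable],
                 accept_fraction: float = 0.01):
        self.observed = np.asarray(observed, dtype=float)
        self.tables = tables
        self.accept_fraction = accept_fraction

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix, tables, accept_fraction=0.01):
        from .sumstats import compute_summary_stats

        return cls(compute_summary_stats(gm), tables, accept_fraction)

    def fit(self) -> "ABCResults":
        choice = abc_model_choice(self.observed, self.tables, self.accept_fraction)
        best = Scenario(choice.best)
        posterior = abc_parameter_estimate(self.observed, self.tables[best],
                                           self.accept_fraction)
        return ABCResults(self, choice, best, posterior)


class ABCResults:
    """Fitted ABC: scenario posterior plus the chosen scenario's parameters."""

    def __init__(self, model: DemographicABC, choice: ModelChoiceResult,
                 best: Scenario, posterior: ParameterPosterior):
        self.model = model
        self.model_choice = choice
        self.best_scenario = best
        self.parameter_posterior = posterior

    def error_rate(self, n_pseudo: int = 1000, n_closest: int = 500, seed: int = 0) -> float:
        return posterior_error_rate(self.model.tables, self.model.observed,
                                    n_pseudo, n_closest, seed,
                                    self.model.accept_fraction)

    def summary(self) -> str:
        lines = ["Demographic ABC summary", "=" * 58,
                 "Scenario posterior probabilities:"]
        for name, p in self.model_choice.posterior.items():
            mark = " <-- selected" if name == self.best_scenario.value else ""
            lines.append(f"  {name:<14} {p:8.4f}{mark}")
        lines.append(f"accepted simulations: {self.model_choice.n_accepted}")
        lines.append("")
        lines.append(self.parameter_posterior.summary())
        return "\n".join(lines)
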