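"""Binomial support functions and maximum-likelihood estimation.

The support (log-likelihood up to the binomial coefficients, which do not
affect estimation, G-statistics or likelihood ratios) of the transmission
parameters given a set of familial studies is

    S_T = sum_studies sum_classes  R ln T[R] + L ln T[L]

for the unadjusted table T, and S_M with the per-study measured table
M = P T O when adjusting for criterion shift.  Three analysis scenarios are
supported: A (estimate and test on T), B (estimate on T, test on M) and C
(estimate and test on M).  Estimation uses multi-start Nelder-Mead over the
feasible region with infeasible proposals receiving a large penalty, backed
by an exhaustive grid search for validation, and non-parametric bootstrap
for confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .io import (
    FamilialStudy,
    SexStratifiedStudy,
    compute_offspring_incidence,
    compute_parent_incidence,
)
from .model import (
    BaseParams,
    ExtendedParams,
    InvalidParameters,
    equilibrium,
    extended_equilibrium,
    transmission_table,
)
from .shift import adjust_familial, build_adjustment, parent_matrix_ordered, offspring_matrix

__all__ = [
    "FitResult",
    "loglik_T",
    "loglik_M",
    "loglik_extended",
    "fit_mle",
    "grid_search",
    "bootstrap_ci",
    "NAMED_STARTS",
    "SENTINEL",
]

#: support value assigned to infeasible parameter proposals
SENTINEL = -1e12

#: the five fixed (rho, alpha) starting guesses used by the simulation harness
NAMED_STARTS = (
    (0.1, 0.1),
    (0.01, 0.1),
    (0.1, 0.01),
    (0.45, 0.01),
    (0.01, 0.45),
)

BASE_MODELS = ("two", "three")
EXTENDED_MODELS = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params: object
    scenario: str
    model: str
    loglik: float
    n_starts: int
    best_start_index: int
    converged: bool
    seed: int | None = None
    grid_checked: float | None = None

    @property
    def n_free(self) -> int:
        return {"two": 2, "three": 3, "I": 2, "II": 3, "III": 4,
                "IV": 5, "V": 7}[self.model]


# ---------------------------------------------------------------------------
# prepared array views of the data (fast path used by fitting and bootstrap)

@dataclass(frozen=True)
class _FamilialArrays:
    counts: np.ndarray          # (S, 3, 2) int
    m_p: np.ndarray | None      # (S,) measured parental incidences
    m_o: np.ndarray | None      # (S,) measured offspring incidences
    pairs: np.ndarray | None = None  # (S, 3) parental couple counts


def _prepare(studies, incidence_mode: str | None):
    counts = np.stack([s.offspring_counts for s in studies]).astype(float)
    m_p = m_o = pairs = None
    if incidence_mode is not None:
        m_p = np.array(
            [compute_parent_incidence(s, mode=incidence_mode) for s in studies]
        )
        m_o = np.array([compute_offspring_incidence(s) for s in studies])
        if all(s.parental_pair_counts is not None for s in studies):
            pairs = np.stack([s.parental_pair_counts for s in studies])
    return _FamilialArrays(counts=counts, m_p=m_p, m_o=m_o, pairs=pairs)


def _cell_support(counts: np.ndarray, probs: np.ndarray) -> float:
    """sum counts * ln(probs) with 0 * ln(0) = 0; SENTINEL if prob 0 meets count > 0."""
    pos = counts > 0
    if np.any(probs[pos] <= 0):
        return SENTINEL
    out = np.zeros_like(probs)
    np.log(probs, out=out, where=pos & (probs > 0))
    return float(np.sum(counts * out))


def _loglik_T_arrays(params: BaseParams, counts: np.ndarray) -> float:
    p = params.right_probs()
    t_mat = np.column_stack([p, 1 - p])
    total = counts.sum(axis=0) if counts.ndim == 3 else counts
    return _cell_support(total, t_mat)


def _measured_tables(params: BaseParams, m_p: np.ndarray, m_o: np.ndarray) -> np.ndarray:
    """Per-study measured tables M = P T O, shape (S, 3, 2)."""
    t = equilibrium(params).true_incidence
    if not 0.0 < t < 1.0:
        raise InvalidParameters("true incidence at the boundary")
    u = np.where(m_p > t, (m_p - t) / m_p, 0.0)
    v = np.where(m_p < t, (t - m_p) / (1.0 - m_p), 0.0)
    w = np.where(m_o > t, (m_o - t) / (1.0 - t), 0.0)
    x = np.where(m_o < t, (t - m_o) / t, 0.0)
    s = len(m_p)
    # per-parent measured->true map entries
    rr, rl = 1.0 - v, v
    lr, ll = u, 1.0 - u
    P = np.empty((s, 3, 3))
    P[:, 0, 0] = rr * rr
    P[:, 0, 1] = 2 * rr * rl
    P[:, 0, 2] = rl * rl
    P[:, 1, 0] = rr * lr
    P[:, 1, 1] = rr * ll + rl * lr
    P[:, 1, 2] = rl * ll
    P[:, 2, 0] = lr * lr
    P[:, 2, 1] = 2 * lr * ll
    P[:, 2, 2] = ll * ll
    O = np.empty((s, 2, 2))
    O[:, 0, 0] = 1.0 - w
    O[:, 0, 1] = w
    O[:, 1, 0] = x
    O[:, 1, 1] = 1.0 - x
    p = params.right_probs()
    t_mat = np.column_stack([p, 1 - p])
    return np.einsum("sij,jk,skl->sil", P, t_mat, O)


def _loglik_M_arrays(params: BaseParams, arrays: _FamilialArrays) -> float:
    m_tables = _measured_tables(params, arrays.m_p, arrays.m_o)
    return _cell_support(arrays.counts, m_tables)


def _binom_constant(counts: np.ndarray) -> float:
    """sum of ln C(n, r) over every mating-class cell pair."""
    counts = counts.reshape(-1, 2)
    n = counts.sum(axis=1)
    return float(
        np.sum(gammaln(n + 1) - gammaln(counts[:, 0] + 1) - gammaln(counts[:, 1] + 1))
    )


def loglik_T(params: BaseParams, studies, include_binom_coef: bool = False) -> float:
    """Unadjusted support S_T of the parameters given familial studies."""
    arrays = _prepare(studies, None)
    val = _loglik_T_arrays(params, arrays.counts)
    if include_binom_coef and val > SENTINEL:
        val += _binom_constant(arrays.counts)
    return val


def loglik_M(params: BaseParams, studies, incidence_mode: str = "reported",
             include_binom_coef: bool = False) -> float:
    """Criterion-shift adjusted support S_M (per-study M = P T O)."""
    arrays = _prepare(studies, incidence_mode)
    try:
        val = _loglik_M_arrays(params, arrays)
    except (InvalidParameters, ValueError):
        return SENTINEL
    if include_binom_coef and val > SENTINEL:
        val += _binom_constant(arrays.counts)
    return val


# ---------------------------------------------------------------------------
# sex-difference extension

def _sex_m_p(study: SexStratifiedStudy) -> float:
    """Pooled measured parental incidence over the four ordered matings."""
    if study.parental_pair_counts is not None:
        pairs = study.parental_pair_counts.astype(float)
    else:
        pairs = study.offspring_counts.sum(axis=(1, 2)) / 3.0  # triplet imputation
    total = pairs.sum()
    # one left parent in RmLf and LmRf matings, two in LmLf
    return float((pairs[1] + pairs[2] + 2 * pairs[3]) / (2 * total))


def _loglik_extended_study(params: ExtendedParams, study: SexStratifiedStudy,
                           adjusted: bool) -> float:
    counts = study.offspring_counts.astype(float)  # (4, 2, 2)
    p = params.right_probs()  # (4 matings, 2 sexes)
    if not adjusted:
        probs = np.stack([p, 1 - p], axis=-1)  # (4, 2, 2)
        return _cell_support(counts, probs)
    pooled, ff, fm = extended_equilibrium(params)
    t_pool = pooled.true_incidence
    t_sex = np.array([1 - ff, 1 - fm])
    if not (0 < t_pool < 1) or np.any(t_sex <= 0) or np.any(t_sex >= 1):
        raise InvalidParameters("extended equilibrium at the boundary")
    m_p = _sex_m_p(study)
    from .shift import parent_nuisance, offspring_nuisance

    u, v = parent_nuisance(t_pool, m_p)
    P4 = parent_matrix_ordered(u, v)
    total = 0.0
    for si in range(2):  # (F, M)
        sex_counts = counts[:, si, :]  # (4, 2)
        n_sex = sex_counts.sum()
        if n_sex == 0:
            continue
        m_o = sex_counts[:, 1].sum() / n_sex
        if not 0 < m_o < 1:
            raise InvalidParameters("degenerate per-sex offspring incidence")
        w, x = offspring_nuisance(t_sex[si], m_o)
        O = offspring_matrix(w, x)
        t_mat = np.column_stack([p[:, si], 1 - p[:, si]])
        m_mat = P4 @ t_mat @ O
        val = _cell_support(sex_counts, m_mat)
        if val <= SENTINEL:
            return SENTINEL
        total += val
    return total


def loglik_extended(params: ExtendedParams, studies, adjusted: bool = True) -> float:
    """Support of the sex-difference model given sex-stratified studies."""
    total = 0.0
    for study in studies:
        try:
            val = _loglik_extended_study(params, study, adjusted)
        except (InvalidParameters, ValueError, RuntimeError):
            return SENTINEL
        if val <= SENTINEL:
            return SENTINEL
        total += val
    return total


# ---------------------------------------------------------------------------
# parameter packing per model

def _unpack_base(x: np.ndarray, model: str) -> BaseParams:
    if model == "two":
        return BaseParams(rho=x[0], alpha=x[1], beta=0.0)
    return BaseParams(rho=x[0], alpha=x[1], beta=x[2])


def _unpack_extended(x: np.ndarray, model: str) -> ExtendedParams:
    if model == "I":
        return ExtendedParams(x[0], x[1], x[1], 0, 0, 0, 0, model_id="I")
    if model == "II":
        return ExtendedParams(x[0], x[1], x[1], x[2], x[2], x[2], x[2], model_id="II")
    if model == "III":
        return ExtendedParams(x[0], x[1], x[1], x[2], x[2], x[3], x[3], model_id="III")
    if model == "IV":
        return ExtendedParams(x[0], x[1], x[2], x[3], x[4], x[3], x[4], model_id="IV")
    return ExtendedParams(x[0], x[1], x[2], x[3], x[4], x[5], x[6], model_id="V")


def _n_free(model: str) -> int:
    return {"two": 2, "three": 3, "I": 2, "II": 3, "III": 4, "IV": 5, "V": 7}[model]


def _random_start(rng: np.random.Generator, model: str) -> np.ndarray:
    rho = rng.uniform(0.0, 0.5)
    alpha = rng.uniform(0.0, 0.5 - rho)
    if model == "two" or model == "I":
        return np.array([rho, alpha])
    lo = -min(0.5, 0.5 + rho)
    hi = 0.5 - rho
    if model == "three" or model == "II":
        return np.array([rho, alpha, rng.uniform(lo, hi)])
    if model == "III":
        return np.array([rho, alpha, rng.uniform(lo, hi), rng.uniform(lo, hi)])
    alpha2 = rng.uniform(0.0, 0.5 - rho)
    if model == "IV":
        return np.array([rho, alpha, alpha2, rng.uniform(lo, hi), rng.uniform(lo, hi)])
    return np.array(
        [rho, alpha, alpha2] + [rng.uniform(lo, hi) for _ in range(4)]
    )


def _make_objective(studies, scenario: str, model: str, incidence_mode: str,
                    adjusted_extended: bool | None = None):
    """Return (objective_on_x, loglik_of_params) closures for NM minimisation."""
    if model in BASE_MODELS:
        arrays = _prepare(studies, incidence_mode if scenario == "C" else None)

        def loglik_of(params: BaseParams) -> float:
            if scenario in ("A", "B"):
                return _loglik_T_arrays(params, arrays.counts)
            try:
                return _loglik_M_arrays(params, arrays)
            except (InvalidParameters, ValueError):
                return SENTINEL

        def objective(x: np.ndarray) -> float:
            try:
                params = _unpack_base(x, model)
            except (InvalidParameters, ValueError):
                return -SENTINEL
            return -loglik_of(params)

    elif model in EXTENDED_MODELS:
        adjusted = (scenario == "C") if adjusted_extended is None else adjusted_extended

        def loglik_of(params: ExtendedParams) -> float:
            return loglik_extended(params, studies, adjusted=adjusted)

        def objective(x: np.ndarray) -> float:
            try:
                params = _unpack_extended(x, model)
            except (InvalidParameters, ValueError):
                return -SENTINEL
            return -loglik_of(params)

    else:
        raise ValueError(f"unknown model {model!r}")
    return objective, loglik_of


def fit_mle(studies, scenario: str = "B", model: str = "two",
            n_starts: int = 1000, seed: int | None = None,
            incidence_mode: str = "reported",
            starts: list | None = None,
            xatol: float = 1e-8, fatol: float = 1e-8,
            maxiter: int | None = None) -> FitResult:
    """Multi-start Nelder-Mead maximum-likelihood fit.

    Scenarios A and B maximise S_T (identical estimates by construction);
    scenario C maximises the adjusted support.  ``starts`` overrides random
    start generation with explicit parameter vectors (e.g. the five named
    guesses of the simulation harness).
    """
    if scenario not in ("A", "B", "C"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if not studies:
        raise ValueError("no studies supplied")
    unpack = _unpack_base if model in BASE_MODELS else _unpack_extended
    objective, _ = _make_objective(studies, scenario, model, incidence_mode)
    rng = np.random.default_rng(seed)
    if starts is None:
        start_points = [_random_start(rng, model) for _ in range(n_starts)]
    else:
        start_points = [np.asarray(s, dtype=float) for s in starts]
    best = None
    best_idx = -1
    options = {"xatol": xatol, "fatol": fatol}
    if maxiter is not None:
        options["maxiter"] = maxiter
    for i, x0 in enumerate(start_points):
        if objective(x0) >= -SENTINEL:
            continue
        res = minimize(objective, x0, method="Nelder-Mead", options=options)
        if res.fun < (-SENTINEL) and (best is None or res.fun < best.fun):
            best = res
            best_idx = i
    if best is None:
        raise RuntimeError("all starting points were infeasible")
    params = unpack(np.asarray(best.x), model)
    return FitResult(
        params=params,
        scenario=scenario,
        model=model,
        loglik=-float(best.fun),
        n_starts=len(start_points),
        best_start_index=best_idx,
        converged=bool(best.success),
        seed=seed,
    )


@dataclass(frozen=True)
class GridSearchResult:
    params: object
    loglik: float
    axes: tuple
    surface: np.ndarray


def grid_search(studies, scenario: str = "B", model: str = "two",
                n_points: int = 201, incidence_mode: str = "reported") -> GridSearchResult:
    """Exhaustive support evaluation over the feasible parameter box.

    Used to validate the simplex optimum and to visualise the support
    surface.  For scenarios A/B the support depends on the data only through
    the pooled counts, so the whole grid is evaluated vectorised; scenario C
    loops over grid points.
    """
    if model not in BASE_MODELS:
        raise ValueError("grid_search supports the base two/three-parameter models")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rho_ax = np.linspace(0.0, 0.5, n_points)
    alpha_ax = np.linspace(0.0, 0.5, n_points)
    axes = (rho_ax, alpha_ax)
    if model == "three":
        beta_ax = np.linspace(-0.5, 0.5, n_points)
        axes = (rho_ax, alpha_ax, beta_ax)
    if scenario in ("A", "B"):
        total = np.stack([s.offspring_counts for s in studies]).sum(axis=0).astype(float)
        rho = rho_ax.reshape(-1, 1) if model == "two" else rho_ax.reshape(-1, 1, 1)
        alpha = alpha_ax.reshape(1, -1) if model == "two" else alpha_ax.reshape(1, -1, 1)
        beta = 0.0 if model == "two" else beta_ax.reshape(1, 1, -1)
        p1 = 0.5 + rho + alpha
        p2 = 0.5 + rho + beta
        p3 = 0.5 + rho - alpha
        feasible = (p1 <= 1.0) & (p3 >= 0.0) & (p2 >= 0.0) & (p2 <= 1.0)
        shape = np.broadcast_shapes(p1.shape, np.shape(p2), p3.shape)
        surface = np.full(shape, SENTINEL, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = (
                total[0, 0] * np.log(p1) + total[0, 1] * np.log1p(-p1)
                + total[1, 0] * np.log(p2) + total[1, 1] * np.log1p(-p2)
                + total[2, 0] * np.log(p3) + total[2, 1] * np.log1p(-p3)
            )
        good = feasible & np.isfinite(val)
        surface[good] = np.broadcast_to(val, surface.shape)[good]
    else:
        objective, _ = _make_objective(studies, scenario, model, incidence_mode)
        shape = tuple(len(a) for a in axes)
        surface = np.full(shape, SENTINEL, dtype=float)
        for idx in np.ndindex(shape):
            x = np.array([axes[d][idx[d]] for d in range(len(axes))])
            surface[idx] = -objective(x)
    best_idx = np.unravel_index(np.argmax(surface), surface.shape)
    x_best = np.array([axes[d][best_idx[d]] for d in range(len(axes))])
    params = _unpack_base(x_best, model) if surface[best_idx] > SENTINEL else None
    return GridSearchResult(
        params=params, loglik=float(surface[best_idx]), axes=axes, surface=surface
    )


def _resample_counts(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample offspring outcomes within each study x mating cell.

    Cell totals are fixed; the number of right-handers is redrawn binomially
    at the empirical proportion (equivalent to resampling the individual
    outcomes with replacement)."""
    n = counts.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, counts[..., 0] / np.maximum(n, 1), 0.0)
    r = rng.binomial(n.astype(np.int64), p)
    return np.stack([r, n - r], axis=-1).astype(float)


def bootstrap_ci(studies, scenario: str = "B", model: str = "two",
                 n_boot: int = 200, levels=(0.8, 0.9, 0.95),
                 seed: int | None = None, incidence_mode: str = "reported",
                 fit0: FitResult | None = None,
                 refit_maxiter: int = 400,
                 resample_parents: bool | None = None) -> dict:
    """Non-parametric bootstrap percentile confidence intervals.

    Offspring outcomes are resampled with replacement within each study x
    mating-class cell (cell totals fixed); measured offspring incidences are
    recomputed per resample and the model is refitted from the original
    point estimate.  When the parental incidence m_p is itself derived from
    couple counts (triplets mode, or a stored value that matches the couple
    counts), those counts are resampled too and m_p recomputed — otherwise
    the intervals omit the parental sampling noise that feeds the
    criterion-shift adjustment and under-cover.  ``resample_parents=None``
    auto-detects this.  Returns per-parameter percentile intervals at the
    requested levels plus the bootstrap estimate matrix.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if model not in BASE_MODELS:
        raise ValueError("bootstrap_ci supports the base models")
    rng = np.random.default_rng(seed)
    if fit0 is None:
        fit0 = fit_mle(studies, scenario=scenario, model=model,
                       starts=[np.array(s) for s in NAMED_STARTS]
                       if model == "two" else None,
                       n_starts=20, seed=int(rng.integers(2**31 - 1)),
                       incidence_mode=incidence_mode)
    x0 = np.array(
        [fit0.params.rho, fit0.params.alpha]
        + ([fit0.params.beta] if model == "three" else [])
    )
    arrays = _prepare(studies, incidence_mode if scenario == "C" else None)
    counts0 = arrays.counts
    if resample_parents is None:
        resample_parents = (
            scenario == "C"
            and arrays.pairs is not None
            and (
                incidence_mode == "triplets"
                or np.allclose(
                    (arrays.pairs[:, 1] + 2 * arrays.pairs[:, 2])
                    / (2 * arrays.pairs.sum(axis=1)),
                    arrays.m_p,
                    atol=1e-9,
                )
            )
        )
    estimates = []
    n_failed = 0
    options = {"xatol": 1e-6, "fatol": 1e-6, "maxiter": refit_maxiter}
    for _ in range(n_boot):
        counts_b = _resample_counts(counts0, rng)
        if scenario == "C":
            totals = counts_b.sum(axis=(1, 2))
            m_o_b = counts_b[:, :, 1].sum(axis=1) / totals
            m_p_b = arrays.m_p
            if resample_parents:
                n_pairs = arrays.pairs.sum(axis=1)
                pairs_b = np.stack(
                    [
                        rng.multinomial(int(n), arrays.pairs[s] / n_pairs[s])
                        for s, n in enumerate(n_pairs)
                    ]
                )
                with np.errstate(invalid="ignore"):
                    m_p_b = (pairs_b[:, 1] + 2 * pairs_b[:, 2]) / (2 * n_pairs)
                if np.any(m_p_b <= 0) or np.any(m_p_b >= 1):
                    n_failed += 1
                    continue
            arrays_b = _FamilialArrays(counts=counts_b, m_p=m_p_b, m_o=m_o_b)

            def loglik_of(params):
                try:
                    return _loglik_M_arrays(params, arrays_b)
                except (InvalidParameters, ValueError):
                    return SENTINEL
        else:
            def loglik_of(params, _c=counts_b):
                return _loglik_T_arrays(params, _c)

        def objective(x):
            try:
                params = _unpack_base(x, model)
            except (InvalidParameters, ValueError):
                return -SENTINEL
            return -loglik_of(params)

        res = minimize(objective, x0, method="Nelder-Mead", options=options)
        if res.fun >= -SENTINEL:
            n_failed += 1
            continue
        estimates.append(res.x)
    if n_failed > n_boot / 2:
        raise RuntimeError(f"bootstrap failed on {n_failed}/{n_boot} resamples")
    est = np.array(estimates)
    names = ["rho", "alpha"] + (["beta"] if model == "three" else [])
    intervals = {}
    for level in levels:
        lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        intervals[level] = {
            name: (float(np.percentile(est[:, j], lo_q)),
                   float(np.percentile(est[:, j], hi_q)))
            for j, name in enumerate(names)
        }
    return {
        "intervals": intervals,
        "estimates": est,
        "names": names,
        "n_failed": n_failed,
        "point": {name: float(x0[j]) for j, name in enumerate(names)},
    }
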