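"""Fixed-D gene-culture transmission model for human hand preference.

The model follows Laland et al. (1995): a single locus with a right-shift
allele D assumed fixed in the population, so every individual carries the
same genetic bias ``rho`` towards right-handedness, and parental phenotypes
exert a vertical cultural effect on the probability that an offspring
becomes right-handed.  With both parents right- (left-) handed the
right-hand probability is shifted up (down) by ``alpha``; with one parent
of each handedness it is shifted by ``beta`` (zero in the two-parameter
model).

Under random mating by phenotype the frequency of right-handers F obeys a
one-generation recursion whose fixed point gives the equilibrium frequency
of right-handers and hence the model's *true incidence* of left-handedness,
``t = 1 - F``.  A sex-structured extension allows the cultural effects to
depend on the sex of the discordant parent (``beta`` for a right-handed
mother with left-handed father, ``gamma`` for the reverse) and on the sex
of the offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BaseParams",
    "ExtendedParams",
    "TransmissionTable",
    "EquilibriumResult",
    "MATING_CLASSES",
    "MATING_CLASSES_4",
    "transmission_table",
    "recursion_step",
    "equilibrium",
    "extended_transmission_table",
    "extended_equilibrium",
    "twin_expectations",
]

#: unordered parental mating classes of the base model
MATING_CLASSES = ("RxR", "mixed", "LxL")
#: ordered mother x father mating classes of the sex-difference extension
MATING_CLASSES_4 = ("RmRf", "RmLf", "LmRf", "LmLf")

_PROB_TOL = 1e-12


class InvalidParameters(ValueError):
    """Raised when parameters imply a transmission probability outside [0, 1]."""


def _check_prob(p: float, name: str) -> None:
    if not (-_PROB_TOL <= p <= 1.0 + _PROB_TOL):
        raise InvalidParameters(f"implied probability {name} = {p!r} outside [0, 1]")


@dataclass(frozen=True)
class BaseParams:
    """Parameters of the base (sex-blind) transmission model.

    rho
        Genetic right-shift of the fixed D allele; right-hand probability is
        1/2 + rho before any cultural effect.
    alpha
        Cultural effect of two same-handed parents (added for RxR,
        subtracted for LxL).
    beta
        Cultural effect of mixed-handed parents; zero in the two-parameter
        model, may be negative.
    """

    rho: float
    alpha: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise InvalidParameters(f"rho must be >= 0, got {self.rho}")
        if self.alpha < 0:
            raise InvalidParameters(f"alpha must be >= 0, got {self.alpha}")
        for name, p in (
            ("P(R|RxR)", 0.5 + self.rho + self.alpha),
            ("P(R|mixed)", 0.5 + self.rho + self.beta),
            ("P(R|LxL)", 0.5 + self.rho - self.alpha),
        ):
            _check_prob(p, name)

    @property
    def n_free(self) -> int:
        return 3

    def right_probs(self) -> np.ndarray:
        """P(R | mating class) for (RxR, mixed, LxL)."""
        return np.array(
            [
                0.5 + self.rho + self.alpha,
                0.5 + self.rho + self.beta,
                0.5 + self.rho - self.alpha,
            ]
        )


_EXTENDED_CONSTRAINTS = {
    # model_id -> number of free parameters
    "I": 2,
    "II": 3,
    "III": 4,
    "IV": 5,
    "V": 7,
}

#: nesting graph of the sex-difference model family (simple -> complex)
NESTING = {
    ("I", "II"),
    ("II", "III"),
    ("II", "IV"),
    ("III", "V"),
    ("IV", "V"),
    ("I", "III"),
    ("I", "IV"),
    ("I", "V"),
    ("II", "V"),
}


@dataclass(frozen=True)
class ExtendedParams:
    """Sex-structured transmission parameters.

    ``alpha_f``/``alpha_m`` act on daughters/sons of same-handed parents;
    ``beta_*`` is the effect of a right-handed mother with a left-handed
    father, ``gamma_*`` the effect of a left-handed mother with a
    right-handed father.  ``model_id`` records which equality / zero
    constraints are active:

    I    alpha_f = alpha_m, beta = gamma = 0        (2 free parameters)
    II   alpha_f = alpha_m, beta_* = gamma_* equal  (3)
    III  sex-equal within offspring, beta != gamma  (4)
    IV   per-sex alpha, beta = gamma per sex        (5)
    V    unconstrained                              (7)
    """

    rho: float
    alpha_f: float
    alpha_m: float
    beta_f: float = 0.0
    beta_m: float = 0.0
    gamma_f: float = 0.0
    gamma_m: float = 0.0
    model_id: str = "V"

    def __post_init__(self) -> None:
        if self.model_id not in _EXTENDED_CONSTRAINTS:
            raise InvalidParameters(f"unknown model_id {self.model_id!r}")
        if self.rho < 0:
            raise InvalidParameters(f"rho must be >= 0, got {self.rho}")
        if self.alpha_f < 0 or self.alpha_m < 0:
            raise InvalidParameters("alpha_f and alpha_m must be >= 0")
        for sex, a, b, g in (
            ("F", self.alpha_f, self.beta_f, self.gamma_f),
            ("M", self.alpha_m, self.beta_m, self.gamma_m),
        ):
            for name, p in (
                (f"P(R|RmRf,{sex})", 0.5 + self.rho + a),
                (f"P(R|RmLf,{sex})", 0.5 + self.rho + b),
                (f"P(R|LmRf,{sex})", 0.5 + self.rho + g),
                (f"P(R|LmLf,{sex})", 0.5 + self.rho - a),
            ):
                _check_prob(p, name)
        self._check_constraints()

    def _check_constraints(self) -> None:
        eq = lambda a, b: abs(a - b) <= _PROB_TOL  # noqa: E731
        mid = self.model_id
        ok = True
        if mid == "I":
            ok = eq(self.alpha_f, self.alpha_m) and all(
                eq(p, 0.0)
                for p in (self.beta_f, self.beta_m, self.gamma_f, self.gamma_m)
            )
        elif mid == "II":
            ok = eq(self.alpha_f, self.alpha_m) and all(
                eq(p, self.beta_f) for p in (self.beta_m, self.gamma_f, self.gamma_m)
            )
        elif mid == "III":
            ok = (
                eq(self.alpha_f, self.alpha_m)
                and eq(self.beta_f, self.beta_m)
                and eq(self.gamma_f, self.gamma_m)
            )
        elif mid == "IV":
            ok = eq(self.beta_f, self.gamma_f) and eq(self.beta_m, self.gamma_m)
        if not ok:
            raise InvalidParameters(
                f"parameters violate the constraint pattern of model {mid}"
            )

    @property
    def n_free(self) -> int:
        return _EXTENDED_CONSTRAINTS[self.model_id]

    def right_probs(self) -> np.ndarray:
        """P(R | mating, offspring sex), shape (4, 2), sex order (F, M)."""
        base = 0.5 + self.rho
        return np.array(
            [
                [base + self.alpha_f, base + self.alpha_m],
                [base + self.beta_f, base + self.beta_m],
                [base + self.gamma_f, base + self.gamma_m],
                [base - self.alpha_f, base - self.alpha_m],
            ]
        )


@dataclass(frozen=True)
class TransmissionTable:
    """Row-stochastic mating-class x offspring-phenotype probability table.

    ``role`` is ``"true_T"`` for the model table T or ``"measured_M"``
    after criterion-shift adjustment.  Columns are (R, L).
    """

    role: str
    matrix: np.ndarray
    row_labels: tuple = MATING_CLASSES

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 2:
            raise ValueError(f"expected an (n, 2) table, got shape {m.shape}")
        if np.any(m < -_PROB_TOL) or np.any(m > 1 + _PROB_TOL):
            raise ValueError("table entries must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ValueError("table rows must sum to 1")


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium phenotype frequencies under the fixed-D recursion."""

    f_dr: float
    f_dl: float
    method: str = "closed_form"

    def __post_init__(self) -> None:
        if not (0 <= self.f_dr <= 1) or abs(self.f_dr + self.f_dl - 1) > 1e-9:
            raise ValueError("equilibrium frequencies must be complementary in [0,1]")

    @property
    def true_incidence(self) -> float:
        """Model-implied true incidence of left-handers, t."""
        return self.f_dl


def transmission_table(params: BaseParams) -> TransmissionTable:
    """True transmission table T: rows (RxR, mixed, LxL), columns (R, L)."""
    p = params.right_probs()
    return TransmissionTable(role="true_T", matrix=np.column_stack([p, 1 - p]))


def recursion_step(f_dr: float, params: BaseParams) -> float:
    """One generation of the phenotype-frequency recursion.

    F' = F^2 (1/2+rho+alpha) + 2F(1-F) (1/2+rho+beta) + (1-F)^2 (1/2+rho-alpha)
    """
    if not 0 <= f_dr <= 1:
        raise ValueError(f"f_dr must be in [0, 1], got {f_dr}")
    p = params.right_probs()
    f = f_dr
    return f * f * p[0] + 2 * f * (1 - f) * p[1] + (1 - f) ** 2 * p[2]


def _fixed_point(params: BaseParams, f0: float = 0.5, tol: float = 1e-14,
                 max_iter: int = 100_000) -> float:
    f = f0
    for _ in range(max_iter):
        f_next = recursion_step(f, params)
        if abs(f_next - f) < tol:
            return f_next
        f = f_next
    raise RuntimeError("phenotype-frequency recursion did not converge")


def equilibrium(params: BaseParams, method: str = "closed_form") -> EquilibriumResult:
    """Equilibrium frequency of right-handers under the fixed-D recursion.

    For beta = 0 the fixed point is (1/2 + rho - alpha) / (1 - 2 alpha); for
    beta != 0 it is the root in [0, 1] of the quadratic obtained by setting
    F' = F: -2 beta F^2 + (2 alpha + 2 beta - 1) F + (1/2 + rho - alpha) = 0.
    ``method="fixed_point"`` iterates the recursion instead (used as an
    independent cross-check of the closed form).
    """
    if method == "fixed_point":
        f = _fixed_point(params)
        return EquilibriumResult(f_dr=f, f_dl=1 - f, method="fixed_point")
    rho, alpha, beta = params.rho, params.alpha, params.beta
    if abs(beta) < 1e-15:
        denom = 1 - 2 * alpha
        if denom <= 0:
            raise InvalidParameters("no equilibrium: 1 - 2*alpha must be positive")
        f = (0.5 + rho - alpha) / denom
    else:
        # -2b F^2 + (2a + 2b - 1) F + (1/2 + rho - a) = 0
        a_q = -2 * beta
        b_q = 2 * alpha + 2 * beta - 1
        c_q = 0.5 + rho - alpha
        disc = b_q * b_q - 4 * a_q * c_q
        if disc < 0:
            raise InvalidParameters("no real equilibrium for these parameters")
        roots = [(-b_q + s * np.sqrt(disc)) / (2 * a_q) for s in (+1, -1)]
        feasible = [r for r in roots if -1e-12 <= r <= 1 + 1e-12]
        if not feasible:
            raise InvalidParameters("no equilibrium in [0, 1] for these parameters")
        if len(feasible) == 2:
            # keep the stable root: |d F'/d F| < 1 at the fixed point
            def slope(f: float) -> float:
                return abs(-4 * beta * f + 2 * alpha + 2 * beta)

            feasible.sort(key=slope)
        f = float(np.clip(feasible[0], 0.0, 1.0))
    if not -1e-9 <= f <= 1 + 1e-9:
        raise InvalidParameters("equilibrium outside [0, 1]")
    f = float(np.clip(f, 0.0, 1.0))
    return EquilibriumResult(f_dr=f, f_dl=1 - f, method="closed_form")


def extended_transmission_table(params: ExtendedParams) -> dict:
    """Per-sex true transmission tables of the sex-difference extension.

    Returns ``{"F": TransmissionTable, "M": TransmissionTable}`` with rows
    (RmRf, RmLf, LmRf, LmLf).
    """
    p = params.right_probs()  # (4, 2) sexes (F, M)
    out = {}
    for j, sex in enumerate(("F", "M")):
        out[sex] = TransmissionTable(
            role="true_T",
            matrix=np.column_stack([p[:, j], 1 - p[:, j]]),
            row_labels=MATING_CLASSES_4,
        )
    return out


def extended_equilibrium(params: ExtendedParams, tol: float = 1e-10,
                         max_iter: int = 200_000, damping: float = 1.0):
    """Coupled fixed point of the sex-structured recursion.

    Iterates the pair (F_F, F_M) of right-hander frequencies among females
    and males, assuming a 1:1 sex ratio and random mating between the
    phenotype distributions of the sexes.  Plain iteration converges for
    all valid parameters (the map is a contraction on the unit square);
    ``damping`` < 1 is available as a fallback.  Returns
    ``(EquilibriumResult_pooled, f_female, f_male)`` where the pooled result
    averages the two sexes (the population true incidence).
    """
    p = params.right_probs()  # rows (RmRf, RmLf, LmRf, LmLf), cols (F, M)
    pf = tuple(p[:, 0])
    pm = tuple(p[:, 1])
    ff = fm = 0.5
    for _ in range(max_iter):
        w0 = ff * fm
        w1 = ff - w0
        w2 = fm - w0
        w3 = 1.0 - ff - fm + w0
        ff_next = w0 * pf[0] + w1 * pf[1] + w2 * pf[2] + w3 * pf[3]
        fm_next = w0 * pm[0] + w1 * pm[1] + w2 * pm[2] + w3 * pm[3]
        ff_new = (1 - damping) * ff + damping * ff_next
        fm_new = (1 - damping) * fm + damping * fm_next
        if abs(ff_new - ff) < tol * damping and abs(fm_new - fm) < tol * damping:
            ff, fm = ff_new, fm_new
            break
        ff, fm = ff_new, fm_new
    else:
        raise RuntimeError("sex-structured recursion did not converge")
    f_mean = 0.5 * (ff + fm)
    return (
        EquilibriumResult(f_dr=f_mean, f_dl=1 - f_mean, method="fixed_point"),
        ff,
        fm,
    )


def twin_expectations(params: BaseParams) -> np.ndarray:
    """Expected unordered twin-pair phenotype probabilities (RR, RL, LL).

    Parents mate at random at the phenotype equilibrium; both twins of a
    pair draw their phenotype independently from the same mating-class row
    of T, so MZ and DZ pairs have identical expectations under the fixed-D
    model.
    """
    f = equilibrium(params).f_dr
    mating = np.array([f * f, 2 * f * (1 - f), (1 - f) ** 2])
    p = params.right_probs()
    pair = np.column_stack([p * p, 2 * p * (1 - p), (1 - p) ** 2])  # (3 matings, 3)
    return mating @ pair
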