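"""G-tests of model fit and likelihood-ratio tests between nested models.

The G-statistic compares observed counts O with model-expected counts E
(cell probabilities times class totals), G = 2 sum O ln(O/E), evaluated
against a chi-squared distribution.  Degrees of freedom follow the
convention that each familial study contributes 2 (three mating-class cell
pairs minus one offspring criterion-shift nuisance), so S studies combined
give 2S - k with k fitted transmission parameters.  Twin datasets
contribute 1 each (two free pair proportions minus the criterion-shift
nuisance) and no parameters are subtracted from the combined twin test
because parameters are never fitted to twin data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .fit import FitResult, _measured_tables, _prepare
from .model import (
    BaseParams,
    NESTING,
    transmission_table,
    twin_expectations,
)
from .shift import adjust_twin

__all__ = [
    "GofResult",
    "LrtResult",
    "g_statistic",
    "gof_familial",
    "gof_twins",
    "likelihood_ratio_test",
]


@dataclass(frozen=True)
class GofResult:
    """Per-study and combined G-test results."""

    per_study: list            # (study_id, G, df, p, fits_at_0.05)
    combined_g: float
    combined_df: int
    combined_p: float
    expected_tables: np.ndarray
    assumption_flags: list = field(default_factory=list)

    @property
    def n_fitting(self) -> int:
        return sum(1 for row in self.per_study if row[4])


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test between nested models (Wilks chi-squared)."""

    simple_model_id: str
    complex_model_id: str
    loglik_simple: float
    loglik_complex: float
    lr: float
    df: int
    p: float


def g_statistic(observed: np.ndarray, expected_probs: np.ndarray) -> float:
    """G = 2 sum O ln(O/E) over all cells; E from row totals x probabilities.

    Cells with zero observations contribute nothing; an expected probability
    of zero against a positive observation is a model/data contradiction and
    raises.
    """
    observed = np.asarray(observed, dtype=float)
    expected_probs = np.asarray(expected_probs, dtype=float)
    totals = observed.sum(axis=-1, keepdims=True)
    expected = totals * expected_probs
    pos = observed > 0
    if np.any(expected[pos] <= 0):
        raise ValueError("model assigns zero probability to an observed outcome")
    ratio = np.ones_like(observed)
    np.divide(observed, expected, out=ratio, where=pos)
    terms = np.zeros_like(observed)
    np.log(ratio, out=terms, where=pos)
    return float(2.0 * np.sum(observed * terms))


def _expected_tables(fit: FitResult, studies, adjusted: bool,
                     incidence_mode: str) -> np.ndarray:
    params: BaseParams = fit.params
    if not adjusted:
        t_mat = transmission_table(params).matrix
        return np.broadcast_to(t_mat, (len(studies), 3, 2)).copy()
    arrays = _prepare(studies, incidence_mode)
    return _measured_tables(params, arrays.m_p, arrays.m_o)


def gof_familial(studies, fit: FitResult, adjusted: bool = True,
                 incidence_mode: str = "reported",
                 min_expected: float = 5.0) -> GofResult:
    """G-test of a fitted base model against familial studies.

    ``adjusted=False`` tests against the true table T-hat (scenario A);
    ``adjusted=True`` tests each study against its measured table M-hat
    (scenarios B and C).  Per-study df = 2; combined df = 2S - k.
    """
    expected = _expected_tables(fit, studies, adjusted, incidence_mode)
    per_study = []
    flags = []
    combined_g = 0.0
    for s, study in enumerate(studies):
        obs = study.offspring_counts.astype(float)
        probs = expected[s]
        exp_counts = obs.sum(axis=1, keepdims=True) * probs
        # totals match per mating class by construction (E = n_c * probs);
        # warn on sparse expected cells rather than dropping them
        if np.any((exp_counts < min_expected) & (obs.sum(axis=1, keepdims=True) > 0)):
            flags.append(f"{study.study_id}: expected cell below {min_expected}")
        g = g_statistic(obs, probs)
        df = 2
        p = float(chi2.sf(g, df))
        per_study.append((study.study_id, g, df, p, p >= 0.05))
        combined_g += g
    k = fit.n_free
    combined_df = 2 * len(studies) - k
    if combined_df < 1:
        raise ValueError("combined degrees of freedom below 1")
    combined_p = float(chi2.sf(combined_g, combined_df))
    return GofResult(
        per_study=per_study,
        combined_g=combined_g,
        combined_df=combined_df,
        combined_p=combined_p,
        expected_tables=expected,
        assumption_flags=flags,
    )


def gof_twins(twin_studies, fit: FitResult) -> GofResult:
    """G-test of a familial fit against held-out twin data.

    Expected pair frequencies come from the model's twin expectations
    adjusted for each dataset's measured incidence; per-dataset df = 1 and
    the combined df is the plain sum because no parameters were fitted to
    the twin data.
    """
    params: BaseParams = fit.params
    base_pairs = twin_expectations(params)
    from .model import equilibrium

    t = equilibrium(params).true_incidence
    per_study = []
    expected_rows = []
    combined_g = 0.0
    combined_df = 0
    for study in twin_studies:
        m_o = study.measured_incidence
        probs = adjust_twin(base_pairs, t, m_o)
        obs = study.pair_counts.astype(float)
        g = g_statistic(obs[None, :], probs[None, :])
        df = 1
        p = float(chi2.sf(g, df))
        per_study.append((study.study_id, g, df, p, p >= 0.05))
        expected_rows.append(probs)
        combined_g += g
        combined_df += df
    combined_p = float(chi2.sf(combined_g, combined_df)) if combined_df else 1.0
    return GofResult(
        per_study=per_study,
        combined_g=combined_g,
        combined_df=combined_df,
        combined_p=combined_p,
        expected_tables=np.array(expected_rows),
    )


def likelihood_ratio_test(fit_simple: FitResult, fit_complex: FitResult) -> LrtResult:
    """Wilks likelihood-ratio test: LR = 2 (S_complex - S_simple) ~ chi2(m - n)."""
    simple_id = fit_simple.model
    complex_id = fit_complex.model
    base_pairs = {("two", "three")}
    if (simple_id, complex_id) not in (NESTING | base_pairs):
        raise ValueError(f"model {simple_id} is not nested in {complex_id}")
    if fit_simple.scenario != fit_complex.scenario:
        raise ValueError("fits must share the same analysis scenario")
    df = fit_complex.n_free - fit_simple.n_free
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    lr = 2.0 * (fit_complex.loglik - fit_simple.loglik)
    if lr < -1e-6:
        raise ValueError(
            f"negative likelihood ratio ({lr:.3g}): complex-model optimiser failure"
        )
    lr = max(lr, 0.0)
    return LrtResult(
        simple_model_id=simple_id,
        complex_model_id=complex_id,
        loglik_simple=fit_simple.loglik,
        loglik_complex=fit_complex.loglik,
        lr=lr,
        df=df,
        p=float(chi2.sf(lr, df)),
    )
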