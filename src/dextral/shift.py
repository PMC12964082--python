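"""Criterion-shift misclassification adjustment.

Different handedness studies apply different criteria for calling an
individual left-handed, so the *measured incidence* of left-handers in a
study (``m_p`` in the parent generation, ``m_o`` in the offspring
generation) can deviate from the population's *true incidence* ``t``
implied by the transmission model.  Following McManus (1985) and Laland et
al. (1995), the deviation in each generation is attributed to exactly one
of two mutually exclusive error types:

* measured incidence above ``t``: some true right-handers were recorded as
  left-handed (proportions ``u`` among measured-left parents, ``w`` among
  true-right offspring);
* measured incidence below ``t``: some true left-handers were recorded as
  right-handed (``v`` among measured-right parents, ``x`` among true-left
  offspring).

These nuisance proportions are fixed by requiring that the per-individual
misclassification map carries the measured incidence onto ``t`` (parents)
or ``t`` onto the measured incidence (offspring); they are never fitted.
The per-parent map expands to a 3x3 row-stochastic matrix P on unordered
matings (measured -> true) and the offspring map to a 2x2 matrix O (true ->
measured), giving the measured-frequency table M = P T O.  The same
offspring map applied independently to the two members of a twin pair gives
the 3x3 pair-transition matrix used for twin data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TransmissionTable

__all__ = [
    "AdjustmentSet",
    "parent_nuisance",
    "offspring_nuisance",
    "parent_matrix",
    "offspring_matrix",
    "parent_matrix_ordered",
    "adjust_familial",
    "adjust_twin",
    "build_adjustment",
]

_EQ_TOL = 1e-12


def _check_open_unit(value: float, name: str) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")


def parent_nuisance(t: float, m_p: float) -> tuple:
    """Parental misclassification proportions (u, v) from (t, m_p).

    u = (m_p - t) / m_p     when m_p > t (measured-left parents truly right)
    v = (t - m_p) / (1-m_p) when m_p < t (measured-right parents truly left)

    At most one of the two is nonzero; both are zero when m_p = t.
    """
    _check_open_unit(t, "t")
    _check_open_unit(m_p, "m_p")
    if abs(m_p - t) < _EQ_TOL:
        return 0.0, 0.0
    if m_p > t:
        return (m_p - t) / m_p, 0.0
    return 0.0, (t - m_p) / (1.0 - m_p)


def offspring_nuisance(t: float, m_o: float) -> tuple:
    """Offspring misclassification proportions (w, x) from (t, m_o).

    w = (m_o - t) / (1 - t) when m_o > t (true right measured left)
    x = (t - m_o) / t       when m_o < t (true left measured right)
    """
    _check_open_unit(t, "t")
    _check_open_unit(m_o, "m_o")
    if abs(m_o - t) < _EQ_TOL:
        return 0.0, 0.0
    if m_o > t:
        return (m_o - t) / (1.0 - t), 0.0
    return 0.0, (t - m_o) / t


def _per_parent_map(u: float, v: float) -> np.ndarray:
    """2x2 measured -> true map for a single parent, rows (R, L)."""
    return np.array([[1.0 - v, v], [u, 1.0 - u]])


def _check_exclusive(a: float, b: float, names: str) -> None:
    if a < 0 or b < 0 or a > 1 or b > 1:
        raise ValueError(f"{names} must lie in [0, 1]")
    if a > 0 and b > 0:
        raise ValueError(f"at most one of {names} may be nonzero")


def parent_matrix(u: float, v: float) -> np.ndarray:
    """3x3 measured-mating -> true-mating matrix P, rows (RxR, mixed, LxL).

    Each parent is misclassified independently with the same per-parent map;
    the mixed row treats the parents as exchangeable (unordered matings).
    """
    _check_exclusive(u, v, "u and v")
    q = _per_parent_map(u, v)  # q[measured, true]
    rr, rl = q[0]
    lr, ll = q[1]
    return np.array(
        [
            [rr * rr, 2 * rr * rl, rl * rl],
            [rr * lr, rr * ll + rl * lr, rl * ll],
            [lr * lr, 2 * lr * ll, ll * ll],
        ]
    )


def parent_matrix_ordered(u: float, v: float) -> np.ndarray:
    """4x4 ordered-mating (mother x father) analogue of :func:`parent_matrix`.

    Rows/columns ordered (RmRf, RmLf, LmRf, LmLf); the two parents are
    misclassified independently, so P4 is the Kronecker square of the
    per-parent map.
    """
    _check_exclusive(u, v, "u and v")
    q = _per_parent_map(u, v)
    return np.kron(q, q)


def offspring_matrix(w: float, x: float) -> np.ndarray:
    """2x2 true -> measured phenotype matrix O, order (R, L)."""
    _check_exclusive(w, x, "w and x")
    return np.array([[1.0 - w, w], [x, 1.0 - x]])


@dataclass(frozen=True)
class AdjustmentSet:
    """Criterion-shift adjustment pieces for one dataset."""

    t: float
    m_p: float
    m_o: float
    u: float
    v: float
    w: float
    x: float
    P: np.ndarray
    O: np.ndarray


def build_adjustment(t: float, m_p: float, m_o: float) -> AdjustmentSet:
    """Nuisance parameters and transition matrices for one study."""
    u, v = parent_nuisance(t, m_p)
    w, x = offspring_nuisance(t, m_o)
    return AdjustmentSet(
        t=t, m_p=m_p, m_o=m_o, u=u, v=v, w=w, x=x,
        P=parent_matrix(u, v), O=offspring_matrix(w, x),
    )


def adjust_familial(table: TransmissionTable, adj: AdjustmentSet) -> TransmissionTable:
    """Measured-frequency table M = P T O for familial data."""
    if adj.P.shape[1] != table.matrix.shape[0]:
        raise ValueError(
            f"shape mismatch: P is {adj.P.shape}, T is {table.matrix.shape}"
        )
    m = adj.P @ table.matrix @ adj.O
    return TransmissionTable(role="measured_M", matrix=m,
                             row_labels=table.row_labels)


def twin_pair_matrix(w: float, x: float) -> np.ndarray:
    """3x3 true-pair -> measured-pair matrix for unordered pairs (RR, RL, LL).

    Each twin is misclassified independently with the active offspring
    nuisance (w: R measured L; x: L measured R).
    """
    _check_exclusive(w, x, "w and x")
    if w > 0:
        return np.array(
            [
                [(1 - w) ** 2, 2 * w * (1 - w), w * w],
                [0.0, 1 - w, w],
                [0.0, 0.0, 1.0],
            ]
        )
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [x, 1 - x, 0.0],
            [x * x, 2 * x * (1 - x), (1 - x) ** 2],
        ]
    )


def adjust_twin(pair_probs: np.ndarray, t: float, m_o: float) -> np.ndarray:
    """Measured twin-pair probabilities (RR, RL, LL) after criterion shift."""
    pair_probs = np.asarray(pair_probs, dtype=float)
    if pair_probs.shape != (3,) or abs(pair_probs.sum() - 1) > 1e-9:
        raise ValueError("pair_probs must be a length-3 distribution")
    w, x = offspring_nuisance(t, m_o)
    return pair_probs @ twin_pair_matrix(w, x)
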