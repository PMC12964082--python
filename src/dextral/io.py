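"""Count-table I/O and the study containers used throughout the package.

Familial data arrive as per-study offspring counts by parental mating class
(two right-handed parents, one of each, two left-handed), optionally with
parental couple counts and an externally reported parental left-handedness
frequency.  Twin data are per-study unordered pair counts (RR, RL, LL) for
MZ or DZ pairs.  Sex-stratified data use four ordered mother x father
mating classes with offspring counts split by sex.

CSV schemas (comma-separated, UTF-8, header required):

* familial:  study_id, rxr_r, rxr_l, mix_r, mix_l, lxl_r, lxl_l,
  optional pairs_rxr, pairs_mix, pairs_lxl, optional m_p
* twin:      study_id, zygosity (MZ|DZ), n_rr, n_rl, n_ll
* sex table: study_id, mating (rmrf|rmlf|lmrf|lmlf), sex (f|m), n_r, n_l
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MATING_CLASSES, MATING_CLASSES_4

__all__ = [
    "FamilialStudy",
    "TwinStudy",
    "SexStratifiedStudy",
    "read_familial_table",
    "write_familial_table",
    "read_twin_table",
    "write_twin_table",
    "read_sex_table",
    "write_sex_table",
    "compute_parent_incidence",
    "compute_offspring_incidence",
    "write_report",
    "load_fixture_familial",
    "load_fixture_twins",
]


@dataclass(frozen=True)
class FamilialStudy:
    """Offspring counts by parental mating class for one familial study.

    ``offspring_counts`` is a (3, 2) integer array with rows
    (RxR, mixed, LxL) and columns (R, L).  ``parental_pair_counts`` is an
    optional length-3 array of couple counts per mating class, and
    ``reported_parent_incidence`` the externally reported frequency of
    left-handed parents, when available.
    """

    study_id: str
    offspring_counts: np.ndarray
    parental_pair_counts: np.ndarray | None = None
    reported_parent_incidence: float | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.offspring_counts, dtype=np.int64)
        object.__setattr__(self, "offspring_counts", counts)
        if counts.shape != (3, 2):
            raise ValueError(
                f"{self.study_id}: offspring_counts must be (3, 2), got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError(f"{self.study_id}: negative offspring counts")
        if counts.sum() == 0:
            raise ValueError(f"{self.study_id}: study has no offspring")
        if self.parental_pair_counts is not None:
            pairs = np.asarray(self.parental_pair_counts, dtype=np.int64)
            object.__setattr__(self, "parental_pair_counts", pairs)
            if pairs.shape != (3,) or np.any(pairs < 0):
                raise ValueError(f"{self.study_id}: invalid parental_pair_counts")
        if self.reported_parent_incidence is not None and not (
            0.0 < self.reported_parent_incidence < 1.0
        ):
            raise ValueError(
                f"{self.study_id}: reported_parent_incidence must be in (0, 1)"
            )

    @property
    def total_offspring(self) -> int:
        return int(self.offspring_counts.sum())


@dataclass(frozen=True)
class TwinStudy:
    """Unordered twin-pair phenotype counts for one study (one zygosity)."""

    study_id: str
    zygosity: str
    n_rr: int
    n_rl: int
    n_ll: int

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise ValueError(f"{self.study_id}: zygosity must be MZ or DZ")
        if min(self.n_rr, self.n_rl, self.n_ll) < 0:
            raise ValueError(f"{self.study_id}: negative pair counts")
        if self.n_pairs == 0:
            raise ValueError(f"{self.study_id}: study has no twin pairs")

    @property
    def n_pairs(self) -> int:
        return self.n_rr + self.n_rl + self.n_ll

    @property
    def pair_counts(self) -> np.ndarray:
        return np.array([self.n_rr, self.n_rl, self.n_ll], dtype=np.int64)

    @property
    def measured_incidence(self) -> float:
        """Individual-level measured left-handedness rate."""
        return (self.n_rl + 2 * self.n_ll) / (2 * self.n_pairs)

    @property
    def discordance(self) -> float:
        return self.n_rl / self.n_pairs


@dataclass(frozen=True)
class SexStratifiedStudy:
    """Sex-stratified offspring counts over four ordered mating classes.

    ``offspring_counts`` has shape (4, 2, 2): mating (RmRf, RmLf, LmRf,
    LmLf) x offspring sex (F, M) x phenotype (R, L).
    """

    study_id: str
    offspring_counts: np.ndarray
    parental_pair_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.offspring_counts, dtype=np.int64)
        object.__setattr__(self, "offspring_counts", counts)
        if counts.shape != (4, 2, 2):
            raise ValueError(
                f"{self.study_id}: offspring_counts must be (4, 2, 2), got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError(f"{self.study_id}: negative counts")
        if counts.sum() == 0:
            raise ValueError(f"{self.study_id}: study has no offspring")
        if self.parental_pair_counts is not None:
            pairs = np.asarray(self.parental_pair_counts, dtype=np.int64)
            object.__setattr__(self, "parental_pair_counts", pairs)
            if pairs.shape != (4,) or np.any(pairs < 0):
                raise ValueError(f"{self.study_id}: invalid parental_pair_counts")


_FAMILIAL_REQUIRED = ["study_id", "rxr_r", "rxr_l", "mix_r", "mix_l", "lxl_r", "lxl_l"]
_FAMILIAL_PAIRS = ["pairs_rxr", "pairs_mix", "pairs_lxl"]


def _require_columns(df: pd.DataFrame, required: list, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def read_familial_table(path, incidence_mode: str = "reported") -> list:
    """Read a familial count CSV into a list of :class:`FamilialStudy`.

    With ``incidence_mode="triplets"`` and no couple counts in the file,
    couples per mating class are imputed as the class offspring total
    divided by three (rounded), the convention used when family sizes are
    unknown and assumed to average three children.
    """
    if incidence_mode not in ("reported", "triplets"):
        raise ValueError(f"unknown incidence_mode {incidence_mode!r}")
    df = pd.read_csv(path)
    _require_columns(df, _FAMILIAL_REQUIRED, path)
    studies = []
    for idx, row in df.iterrows():
        counts = np.array(
            [
                [row["rxr_r"], row["rxr_l"]],
                [row["mix_r"], row["mix_l"]],
                [row["lxl_r"], row["lxl_l"]],
            ]
        )
        if np.any(pd.isna(counts.astype(float))) or np.any(counts.astype(float) < 0):
            raise ValueError(f"{path} row {idx} ({row['study_id']}): invalid counts")
        pairs = None
        if all(c in df.columns for c in _FAMILIAL_PAIRS) and not any(
            pd.isna(row[c]) for c in _FAMILIAL_PAIRS
        ):
            pairs = np.array([row[c] for c in _FAMILIAL_PAIRS], dtype=np.int64)
        elif incidence_mode == "triplets":
            pairs = np.rint(counts.sum(axis=1) / 3.0).astype(np.int64)
        m_p = None
        if "m_p" in df.columns and not pd.isna(row["m_p"]):
            m_p = float(row["m_p"])
        studies.append(
            FamilialStudy(
                study_id=str(row["study_id"]),
                offspring_counts=counts,
                parental_pair_counts=pairs,
                reported_parent_incidence=m_p,
            )
        )
    return studies


def write_familial_table(studies: list, path) -> None:
    rows = []
    for s in studies:
        row = {
            "study_id": s.study_id,
            "rxr_r": s.offspring_counts[0, 0],
            "rxr_l": s.offspring_counts[0, 1],
            "mix_r": s.offspring_counts[1, 0],
            "mix_l": s.offspring_counts[1, 1],
            "lxl_r": s.offspring_counts[2, 0],
            "lxl_l": s.offspring_counts[2, 1],
        }
        if s.parental_pair_counts is not None:
            row.update(
                pairs_rxr=s.parental_pair_counts[0],
                pairs_mix=s.parental_pair_counts[1],
                pairs_lxl=s.parental_pair_counts[2],
            )
        if s.reported_parent_incidence is not None:
            row["m_p"] = s.reported_parent_incidence
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def compute_parent_incidence(study: FamilialStudy, mode: str = "reported") -> float:
    """Measured parental left-handedness incidence m_p for one study.

    ``mode="reported"`` returns the externally reported value verbatim;
    ``mode="triplets"`` derives it from couple counts as
    (mixed + 2 LxL) / (2 x total couples).
    """
    if mode == "reported":
        if study.reported_parent_incidence is None:
            raise ValueError(
                f"{study.study_id}: no reported parental incidence (mode=reported)"
            )
        return study.reported_parent_incidence
    if mode == "triplets":
        if study.parental_pair_counts is None:
            raise ValueError(
                f"{study.study_id}: no parental pair counts (mode=triplets)"
            )
        pairs = study.parental_pair_counts
        total = pairs.sum()
        if total == 0:
            raise ValueError(f"{study.study_id}: zero parental pairs")
        m_p = (pairs[1] + 2 * pairs[2]) / (2 * total)
        if not 0.0 < m_p < 1.0:
            raise ValueError(
                f"{study.study_id}: parental incidence {m_p} outside (0, 1)"
            )
        return float(m_p)
    raise ValueError(f"unknown mode {mode!r}")


def compute_offspring_incidence(study: FamilialStudy) -> float:
    """Measured offspring left-handedness incidence m_o = sum(L) / total."""
    return float(study.offspring_counts[:, 1].sum() / study.total_offspring)


def read_twin_table(path) -> list:
    df = pd.read_csv(path)
    if df.empty:
        return []
    _require_columns(df, ["study_id", "zygosity", "n_rr", "n_rl", "n_ll"], path)
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                TwinStudy(
                    study_id=str(row["study_id"]),
                    zygosity=str(row["zygosity"]).upper(),
                    n_rr=int(row["n_rr"]),
                    n_rl=int(row["n_rl"]),
                    n_ll=int(row["n_ll"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} row {idx}: {exc}") from exc
    return out


def write_twin_table(studies: list, path) -> None:
    pd.DataFrame(
        [
            {
                "study_id": s.study_id,
                "zygosity": s.zygosity,
                "n_rr": s.n_rr,
                "n_rl": s.n_rl,
                "n_ll": s.n_ll,
            }
            for s in studies
        ]
    ).to_csv(path, index=False)


_MATING4_CODES = {m.lower(): i for i, m in enumerate(MATING_CLASSES_4)}
_SEX_CODES = {"f": 0, "m": 1}


def read_sex_table(path) -> list:
    """Read a long-format sex-stratified CSV into SexStratifiedStudy objects."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    _require_columns(df, ["study_id", "mating", "sex", "n_r", "n_l"], path)
    out = []
    for study_id, grp in df.groupby("study_id", sort=False):
        counts = np.zeros((4, 2, 2), dtype=np.int64)
        for idx, row in grp.iterrows():
            mating = str(row["mating"]).lower()
            sex = str(row["sex"]).lower()
            if mating not in _MATING4_CODES or sex not in _SEX_CODES:
                raise ValueError(
                    f"{path} row {idx}: unknown mating/sex {row['mating']!r}/{row['sex']!r}"
                )
            counts[_MATING4_CODES[mating], _SEX_CODES[sex]] += np.array(
                [int(row["n_r"]), int(row["n_l"])]
            )
        out.append(SexStratifiedStudy(study_id=str(study_id), offspring_counts=counts))
    return out


def write_sex_table(studies: list, path) -> None:
    rows = []
    for s in studies:
        for ci, mating in enumerate(MATING_CLASSES_4):
            for sex, si in (("f", 0), ("m", 1)):
                rows.append(
                    {
                        "study_id": s.study_id,
                        "mating": mating.lower(),
                        "sex": sex,
                        "n_r": s.offspring_counts[ci, si, 0],
                        "n_l": s.offspring_counts[ci, si, 1],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(result, path, **context) -> None:
    """Write a structured JSON report for any dataclass result object.

    Extra keyword arguments (seed, scenario, package version, ...) are
    echoed into the report so every output records its provenance.
    """
    from . import __version__

    if hasattr(result, "__dataclass_fields__"):
        payload = asdict(result)
    elif isinstance(result, dict):
        payload = dict(result)
    else:
        raise TypeError(f"cannot serialise result of type {type(result)}")
    payload = _jsonify(payload)
    payload["_meta"] = _jsonify({"package_version": __version__, **context})
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _fixture_path(name: str):
    return resources.files("dextral.data").joinpath(name)


def load_fixture_familial(incidence_mode: str = "reported") -> list:
    """Bundled 17-study familial fixture.

    SYNTHETIC stand-in: the historical 17-study compilation (McManus 1985 /
    Laland et al. 1995) is not redistributable here, so this fixture was
    generated once by :mod:`dextral.simulate` at the Laland point estimates
    (rho=0.277, alpha=0.138, beta=0) with per-study criterion shift and
    study sizes matching the historical compilation's scale.
    """
    with resources.as_file(_fixture_path("familial17_synthetic.csv")) as p:
        return read_familial_table(p, incidence_mode=incidence_mode)


def load_fixture_twins() -> list:
    """Bundled pooled MZ/DZ twin fixture.

    SYNTHETIC reconstruction: pair cross-tables rebuilt (to integer
    rounding) from the published pooled totals of the 13-study twin
    compilation — 2,900 MZ pairs with a 13.8% left rate and 21.68%
    discordance, 2,589 DZ pairs with 13.34% and 22.6%.
    """
    with resources.as_file(_fixture_path("twins_pooled_synthetic.csv")) as p:
        return read_twin_table(p)
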