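"""Mimicry-accuracy trait scoring.

Nine morphometric/color traits are scored in [0, 1] from linear specimen
measurements (mm) and three boolean color-illusion flags; the overall
accuracy index is their arithmetic mean.  Categories: nonmimic (< 0.15),
inaccurate (0.15 to < 0.30, subdivided into low 0.15-0.19 and moderate
0.20-0.29 on two-decimal rounding), accurate (>= 0.30).

Score formulas (all ratios clamped to [0, 1]):

=========================  ==================================================
thin_legs                  1 - femur III width / femur III length
elong_ceph                 1 - cephalothorax width / cephalothorax length
elong_abd                  1 - abdomen width / abdomen length
elong_pedicel              pedicel length / (ceph len + abd len + pedicel len)
constr_ceph_dors           1 - ceph width at constriction / ceph width
constr_ceph_lat            1 - ceph height at constriction / ceph max height
constr_abd_dors            1 - abd width at constriction / abd width
constr_abd_lat             1 - abd height at constriction / abd max height
illusion_coloration        0 / 0.334 / 0.667 / 1.0 for 0-3 flags set
=========================  ==================================================

Equal constriction and widest/highest measurements encode "no constriction"
(score 0); absent constriction measurements also score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from mimicevo.errors import MeasurementError, UnscorableSpecimenError

__all__ = [
    "TRAIT_NAMES",
    "CATEGORIES",
    "ILLUSION_SCORES",
    "SpecimenMeasurements",
    "TraitScores",
    "AccuracyRecord",
    "CohortSummary",
    "score_traits",
    "overall_accuracy",
    "classify_accuracy",
    "cohort_summary",
    "read_measurements",
    "score_table",
    "summary_table",
]

#: Canonical trait order; overall accuracy averages these nine.
TRAIT_NAMES = (
    "thin_legs",
    "elong_ceph",
    "elong_abd",
    "elong_pedicel",
    "constr_ceph_lat",
    "constr_ceph_dors",
    "constr_abd_lat",
    "constr_abd_dors",
    "illusion_coloration",
)

CATEGORIES = ("nonmimic", "inaccurate_low", "inaccurate_moderate", "accurate")

#: Rounded per-count illusion scores (0..3 flags true).
ILLUSION_SCORES = (0.0, 0.334, 0.667, 1.0)

#: Measurement columns expected in delimited input (booleans may be 0/1 or
#: true/false).  ``clade`` and the constriction columns are optional.
MEASUREMENT_COLUMNS = (
    "specimen_id",
    "clade",
    "femur3_length",
    "femur3_width",
    "ceph_width",
    "ceph_length",
    "abd_width",
    "abd_length",
    "pedicel_length",
    "ceph_width_constr",
    "ceph_height_constr",
    "ceph_height_max",
    "abd_width_constr",
    "abd_height_constr",
    "abd_height_max",
    "band_abdomen",
    "band_cephalothorax",
    "eye_darkening",
)


@dataclass
class SpecimenMeasurements:
    """Raw biometrics for one specimen (linear measurements in mm)."""

    specimen_id: str
    femur3_length: Optional[float] = None
    femur3_width: Optional[float] = None
    ceph_width: Optional[float] = None
    ceph_length: Optional[float] = None
    abd_width: Optional[float] = None
    abd_length: Optional[float] = None
    pedicel_length: Optional[float] = None
    ceph_width_constr: Optional[float] = None
    ceph_height_constr: Optional[float] = None
    ceph_height_max: Optional[float] = None
    abd_width_constr: Optional[float] = None
    abd_height_constr: Optional[float] = None
    abd_height_max: Optional[float] = None
    illusion_flags: tuple[bool, bool, bool] = (False, False, False)
    clade_label: str = ""

    def __post_init__(self) -> None:
        if len(self.illusion_flags) != 3:
            raise MeasurementError("illusion_flags", "exactly three flags required")
        self.illusion_flags = tuple(bool(f) for f in self.illusion_flags)
        for f in fields(self):
            if f.name in ("specimen_id", "clade_label", "illusion_flags"):
                continue
            v = getattr(self, f.name)
            if v is None:
                continue
            # pedicel length 0 is meaningful (no pedicel elongation)
            floor_ok = v >= 0 if f.name == "pedicel_length" else v > 0
            if not math.isfinite(v) or not floor_ok:
                raise MeasurementError(f.name, f"length must be positive and finite, got {v!r}")


@dataclass(frozen=True)
class TraitScores:
    """Nine per-trait scores in [0, 1]; ``None`` marks a missing trait
    (only produced under the partial-scoring option)."""

    thin_legs: Optional[float]
    elong_ceph: Optional[float]
    elong_abd: Optional[float]
    elong_pedicel: Optional[float]
    constr_ceph_lat: Optional[float]
    constr_ceph_dors: Optional[float]
    constr_abd_lat: Optional[float]
    constr_abd_dors: Optional[float]
    illusion_coloration: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in TRAIT_NAMES}

    def as_array(self) -> np.ndarray:
        """Scores in canonical order; missing entries become NaN."""
        return np.array(
            [math.nan if v is None else v for v in self.as_dict().values()], dtype=float
        )

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.as_dict().values())


@dataclass(frozen=True)
class AccuracyRecord:
    specimen_id: str
    overall_accuracy: float
    category: str
    partial: bool = False  # True if averaged over an incomplete score set


@dataclass
class CohortSummary:
    """Per-trait and overall min/max/mean/sample-SD plus category counts."""

    clade_label: str
    n: int
    stats: pd.DataFrame  # index: trait names + "overall_accuracy"; cols: min,max,mean,sd
    category_counts: dict[str, int]
    n_with_any_constriction: int
    constriction_counts: dict[str, int]  # per constriction trait: count of score > 0
    n_with_illusion: int


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def _ratio_score(num: Optional[float], den: Optional[float], den_name: str) -> Optional[float]:
    """1 - num/den, clamped; None if either operand is missing."""
    if num is None or den is None:
        return None
    if den <= 0:
        raise MeasurementError(den_name, f"nonpositive denominator {den!r}")
    return _clamp01(1.0 - num / den)


def _constriction_score(constr: Optional[float], widest: Optional[float], widest_name: str) -> float:
    # Absent constriction measurements encode "no constriction" -> 0.
    if constr is None or widest is None:
        return 0.0
    if widest <= 0:
        raise MeasurementError(widest_name, f"nonpositive denominator {widest!r}")
    return _clamp01(1.0 - constr / widest)


def score_traits(m: SpecimenMeasurements, allow_partial: bool = False) -> TraitScores:
    """Compute the nine trait scores for one specimen.

    Parameters
    ----------
    m
        Specimen measurements; constriction fields may be absent (score 0).
    allow_partial
        If True, missing non-constriction measurements yield ``None`` scores
        instead of raising; otherwise they make the specimen unscorable.

    Raises
    ------
    MeasurementError
        On a nonpositive denominator.
    UnscorableSpecimenError
        If required measurements are missing (``allow_partial=False``) or if
        every trait is missing.
    """
    thin_legs = _ratio_score(m.femur3_width, m.femur3_length, "femur3_length")
    elong_ceph = _ratio_score(m.ceph_width, m.ceph_length, "ceph_length")
    elong_abd = _ratio_score(m.abd_width, m.abd_length, "abd_length")

    elong_pedicel: Optional[float] = None
    if m.pedicel_length is not None and m.ceph_length is not None and m.abd_length is not None:
        total = m.ceph_length + m.abd_length + m.pedicel_length
        if total <= 0:
            raise MeasurementError("pedicel_length", f"nonpositive total body length {total!r}")
        elong_pedicel = _clamp01(m.pedicel_length / total)

    scores = TraitScores(
        thin_legs=thin_legs,
        elong_ceph=elong_ceph,
        elong_abd=elong_abd,
        elong_pedicel=elong_pedicel,
        constr_ceph_dors=_constriction_score(m.ceph_width_constr, m.ceph_width, "ceph_width"),
        constr_ceph_lat=_constriction_score(m.ceph_height_constr, m.ceph_height_max, "ceph_height_max"),
        constr_abd_dors=_constriction_score(m.abd_width_constr, m.abd_width, "abd_width"),
        constr_abd_lat=_constriction_score(m.abd_height_constr, m.abd_height_max, "abd_height_max"),
        illusion_coloration=ILLUSION_SCORES[sum(m.illusion_flags)],
    )

    missing = [k for k, v in scores.as_dict().items() if v is None]
    if missing and not allow_partial:
        raise UnscorableSpecimenError(
            f"specimen {m.specimen_id!r}: missing measurements for trait(s) {', '.join(missing)}"
        )
    if len(missing) == len(TRAIT_NAMES):
        raise UnscorableSpecimenError(f"specimen {m.specimen_id!r}: all measurements missing")
    return scores


def overall_accuracy(s: TraitScores, allow_partial: bool = False) -> float:
    """Arithmetic mean of the nine trait scores (sum divided by 9).

    With ``allow_partial`` the mean is taken over the available scores.
    """
    vals = [v for v in s.as_dict().values() if v is not None]
    if len(vals) < len(TRAIT_NAMES):
        if not allow_partial:
            raise UnscorableSpecimenError("incomplete trait scores; pass allow_partial=True to average")
        return float(np.mean(vals))
    return float(sum(vals) / 9.0)


def classify_accuracy(x: float) -> str:
    """Map an overall accuracy value in [0, 1] to its category.

    Outer thresholds 0.15 / 0.30 are applied to the raw value; the
    low/moderate sub-bin boundary follows the printed bins 0.15-0.19 vs
    0.20-0.29, decided on the value rounded to two decimals.
    """
    if not (0.0 <= x <= 1.0) or not math.isfinite(x):
        raise ValueError(f"accuracy must lie in [0, 1], got {x!r}")
    if x < 0.15:
        return "nonmimic"
    if x >= 0.30:
        return "accurate"
    return "inaccurate_low" if round(x, 2) <= 0.19 else "inaccurate_moderate"


def make_record(
    specimen_id: str, s: TraitScores, allow_partial: bool = False
) -> AccuracyRecord:
    acc = overall_accuracy(s, allow_partial=allow_partial)
    return AccuracyRecord(
        specimen_id=specimen_id,
        overall_accuracy=acc,
        category=classify_accuracy(acc),
        partial=not s.complete,
    )


_CONSTRICTION_TRAITS = ("constr_ceph_lat", "constr_ceph_dors", "constr_abd_lat", "constr_abd_dors")


def cohort_summary(
    records: Sequence[tuple[TraitScores, AccuracyRecord]], clade_label: str = ""
) -> CohortSummary:
    """Summarize a cohort: per-trait and overall min/max/mean/sample SD,
    category counts, constriction prevalence (overall and per region), and
    the count of specimens expressing any illusion coloration."""
    if not records:
        raise ValueError("empty cohort")
    if len(records) == 1:
        import warnings

        warnings.warn("single-record cohort: SD reported as 0", stacklevel=2)

    score_mat = np.vstack([s.as_array() for s, _ in records])
    acc = np.array([r.overall_accuracy for _, r in records])
    data = np.column_stack([score_mat, acc])
    names = list(TRAIT_NAMES) + ["overall_accuracy"]

    with np.errstate(invalid="ignore"):
        stats = pd.DataFrame(
            {
                "min": np.nanmin(data, axis=0),
                "max": np.nanmax(data, axis=0),
                "mean": np.nanmean(data, axis=0),
                "sd": np.nanstd(data, axis=0, ddof=1) if len(records) > 1 else np.zeros(data.shape[1]),
            },
            index=names,
        )

    counts = {c: 0 for c in CATEGORIES}
    for _, r in records:
        counts[r.category] += 1

    constr_idx = [TRAIT_NAMES.index(t) for t in _CONSTRICTION_TRAITS]
    constr = np.nan_to_num(score_mat[:, constr_idx])
    illusion = np.nan_to_num(score_mat[:, TRAIT_NAMES.index("illusion_coloration")])

    return CohortSummary(
        clade_label=clade_label,
        n=len(records),
        stats=stats,
        category_counts=counts,
        n_with_any_constriction=int(np.sum((constr > 0).any(axis=1))),
        constriction_counts={
            t: int(np.sum(constr[:, k] > 0)) for k, t in enumerate(_CONSTRICTION_TRAITS)
        },
        n_with_illusion=int(np.sum(illusion > 0)),
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_BOOL_MAP = {"0": False, "1": True, "true": True, "false": False, "t": True, "f": False}


def _parse_bool(v: object) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, float, np.integer, np.floating)):
        return bool(int(v))
    s = str(v).strip().lower()
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise ValueError(f"cannot interpret {v!r} as a boolean flag")


def read_measurements(path: str, sep: Optional[str] = None) -> list[SpecimenMeasurements]:
    """Read a comma- or tab-separated measurement table (see
    :data:`MEASUREMENT_COLUMNS` for the header contract)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip() for c in df.columns]
    if "specimen_id" not in df.columns:
        raise ValueError("measurement table must have a 'specimen_id' column")
    out = []
    numeric = [
        c
        for c in MEASUREMENT_COLUMNS
        if c not in ("specimen_id", "clade", "band_abdomen", "band_cephalothorax", "eye_darkening")
    ]
    for _, row in df.iterrows():
        kwargs: dict = {"specimen_id": str(row["specimen_id"])}
        if "clade" in df.columns and not pd.isna(row["clade"]):
            kwargs["clade_label"] = str(row["clade"])
        for c in numeric:
            if c in df.columns and not pd.isna(row[c]):
                kwargs[c] = float(row[c])
        flags = []
        for c in ("band_abdomen", "band_cephalothorax", "eye_darkening"):
            flags.append(_parse_bool(row[c]) if c in df.columns and not pd.isna(row[c]) else False)
        kwargs["illusion_flags"] = tuple(flags)
        out.append(SpecimenMeasurements(**kwargs))
    return out


def score_table(
    measurements: Iterable[SpecimenMeasurements], allow_partial: bool = False
) -> pd.DataFrame:
    """Score every specimen; one row per specimen with the nine scores,
    overall accuracy, and category."""
    rows = []
    for m in measurements:
        s = score_traits(m, allow_partial=allow_partial)
        r = make_record(m.specimen_id, s, allow_partial=allow_partial)
        row = {"specimen_id": m.specimen_id, "clade": m.clade_label}
        row.update(s.as_dict())
        row["overall_accuracy"] = r.overall_accuracy
        row["category"] = r.category
        rows.append(row)
    return pd.DataFrame(rows)


def summary_table(summary: CohortSummary) -> pd.DataFrame:
    """Long-form summary table mirroring a min/max/mean/SD block."""
    df = summary.stats.copy()
    df.insert(0, "clade", summary.clade_label)
    df.insert(1, "n", summary.n)
    return df.reset_index(names="characteristic")
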