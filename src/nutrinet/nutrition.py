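"""WHO-style anthropometric z-scores and the cumulative nutritional index.

Child nutritional status is summarised by three LMS-based z-scores —
height-for-age (stunting), weight-for-age (underweight) and
weight-for-height (wasting) — computed against a growth reference table.
Their sum, the *cumulative nutritional index*, is the single severity axis
used throughout the downstream analysis, and cuts the cohort into three
classes: apparently healthy (AH), borderline (BL) and severely
malnourished (SM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AXES",
    "GrowthReference",
    "OutOfRangeError",
    "compute_z_score",
    "invert_z_score",
    "cumulative_index",
    "classify_nutrition",
    "score_metadata",
    "toy_growth_reference",
]

#: Reference axes. The lookup key is age in months for the two *-for-age
#: axes and height in cm for weight-for-height.
AXES = ("height-for-age", "weight-for-age", "weight-for-height")

#: Class cut-points on the cumulative index: AH above the first,
#: SM at or below the second, BL in between (boundaries fall downward:
#: an index of exactly -6 is BL, exactly -9 is SM).
CLASS_CUTPOINTS = (-6.0, -9.0)

_L_EPS = 1e-9


class OutOfRangeError(ValueError):
    """Lookup key outside the span of the growth reference (no extrapolation)."""


def compute_z_score(measurement: float, L: float, M: float, S: float) -> float:
    """LMS z-score of a measurement given skewness L, median M and CV S.

    Uses ``((X/M)**L - 1) / (L*S)`` and the log-limit ``ln(X/M)/S`` when
    ``|L|`` is numerically zero.
    """
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be strictly positive")
    if measurement <= 0:
        raise ValueError("measurement must be strictly positive")
    if abs(L) > _L_EPS:
        return ((measurement / M) ** L - 1.0) / (L * S)
    return float(np.log(measurement / M) / S)


def invert_z_score(z: float, L: float, M: float, S: float) -> float:
    """Measurement whose LMS z-score equals ``z`` (inverse of compute_z_score)."""
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be strictly positive")
    if abs(L) > _L_EPS:
        base = 1.0 + L * S * z
        if base <= 0:
            raise ValueError(f"z={z} outside the domain of the LMS inverse")
        return float(M * base ** (1.0 / L))
    return float(M * np.exp(S * z))


def cumulative_index(z1: float, z2: float, z3: float) -> float:
    """Sum of the three z-scores (height-for-age, weight-for-age, weight-for-height)."""
    total = z1 + z2 + z3
    if not np.isfinite(total):
        raise ValueError("z-scores must be finite")
    return float(total)


def classify_nutrition(index: float) -> str:
    """AH / BL / SM class of a cumulative nutritional index.

    AH strictly above -6, SM at or below -9, BL in between. The two
    boundary values close downward so the classes partition the line.
    """
    if not np.isfinite(index):
        raise ValueError("index must be finite")
    lo_ah, lo_bl = CLASS_CUTPOINTS
    if index > lo_ah:
        return "AH"
    if index > lo_bl:
        return "BL"
    return "SM"


@dataclass
class GrowthReference:
    """LMS growth reference: rows keyed by (sex, axis, key) carrying L, M, S.

    ``key`` is age in months for the *-for-age axes and height in cm for
    weight-for-height. L, M and S are linearly interpolated between the
    bracketing keys; lookups outside the key span raise OutOfRangeError.
    """

    table: pd.DataFrame
    _grids: dict = field(init=False, repr=False, default_factory=dict)

    REQUIRED_COLUMNS = ("sex", "axis", "key", "L", "M", "S")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"growth reference missing columns: {sorted(missing)}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("M and S must be strictly positive everywhere")
        for (sex, axis), grp in self.table.groupby(["sex", "axis"], sort=True):
            grp = grp.sort_values("key")
            keys = grp["key"].to_numpy(float)
            if np.any(np.diff(keys) <= 0):
                raise ValueError(f"keys not strictly increasing for {(sex, axis)}")
            self._grids[(sex, axis)] = (
                keys,
                grp["L"].to_numpy(float),
                grp["M"].to_numpy(float),
                grp["S"].to_numpy(float),
            )

    def lookup(self, sex: str, axis: str, key: float) -> tuple[float, float, float]:
        """Interpolated (L, M, S) at ``key`` for the given sex and axis."""
        if axis not in AXES:
            raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
        try:
            keys, L, M, S = self._grids[(sex, axis)]
        except KeyError:
            raise KeyError(f"no reference rows for sex={sex!r}, axis={axis!r}") from None
        if key < keys[0] or key > keys[-1]:
            raise OutOfRangeError(
                f"key {key} outside reference range [{keys[0]}, {keys[-1]}] "
                f"for {(sex, axis)}"
            )
        return (
            float(np.interp(key, keys, L)),
            float(np.interp(key, keys, M)),
            float(np.interp(key, keys, S)),
        )

    def z_score(self, sex: str, axis: str, key: float, measurement: float) -> float:
        """z-score of a measurement on an axis at the interpolated reference row."""
        L, M, S = self.lookup(sex, axis, key)
        return compute_z_score(measurement, L, M, S)

    def measurement_for_z(self, sex: str, axis: str, key: float, z: float) -> float:
        """Measurement achieving z-score ``z`` on an axis (LMS inverse)."""
        L, M, S = self.lookup(sex, axis, key)
        return invert_z_score(z, L, M, S)

    @classmethod
    def from_tsv(cls, path) -> "GrowthReference":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def score_metadata(metadata: pd.DataFrame, reference: GrowthReference) -> pd.DataFrame:
    """Attach the three z-scores, cumulative index and class to a metadata table.

    ``metadata`` needs columns sample_id, age_months, sex, height_cm,
    weight_kg. Returns a copy with z_height_age, z_weight_age,
    z_weight_height, cumulative_index and nutrition_class columns.
    """
    required = {"sample_id", "age_months", "sex", "height_cm", "weight_kg"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    out = metadata.copy()
    z1, z2, z3 = [], [], []
    for row in metadata.itertuples(index=False):
        z1.append(reference.z_score(row.sex, "height-for-age", row.age_months, row.height_cm))
        z2.append(reference.z_score(row.sex, "weight-for-age", row.age_months, row.weight_kg))
        z3.append(reference.z_score(row.sex, "weight-for-height", row.height_cm, row.weight_kg))
    out["z_height_age"] = z1
    out["z_weight_age"] = z2
    out["z_weight_height"] = z3
    out["cumulative_index"] = out["z_height_age"] + out["z_weight_age"] + out["z_weight_height"]
    out["nutrition_class"] = [classify_nutrition(v) for v in out["cumulative_index"]]
    return out


def _toy_median_height(age_months: np.ndarray, sex_factor: float) -> np.ndarray:
    return sex_factor * (52.0 + 2.0 * age_months ** 0.78)


def _toy_median_weight_for_height(height_cm: np.ndarray, sex_factor: float) -> np.ndarray:
    return sex_factor * 0.00035 * height_cm ** 2.35


def toy_growth_reference() -> GrowthReference:
    """Small synthetic growth reference bundled for tests and simulations.

    Median curves are smooth and *median-consistent*: the weight-for-age
    median at each age equals the weight-for-height median evaluated at
    that age's median height, so a child at the median of every axis has
    all three z-scores near zero. L and S are axis-wise constants of
    realistic magnitude. This is a stand-in shaped like a WHO LMS table,
    not WHO data.
    """
    ages = np.arange(0.0, 61.0, 2.0)
    heights = np.arange(45.0, 130.1, 2.5)
    frames = []
    for sex, hf, wf in (("M", 1.00, 1.00), ("F", 0.98, 0.97)):
        med_h = _toy_median_height(ages, hf)
        frames.append(pd.DataFrame({
            "sex": sex, "axis": "height-for-age", "key": ages,
            "L": 1.0, "M": med_h, "S": 0.035,
        }))
        frames.append(pd.DataFrame({
            "sex": sex, "axis": "weight-for-age", "key": ages,
            "L": 0.1, "M": _toy_median_weight_for_height(med_h, wf), "S": 0.12,
        }))
        frames.append(pd.DataFrame({
            "sex": sex, "axis": "weight-for-height", "key": heights,
            "L": -0.35, "M": _toy_median_weight_for_height(heights, wf), "S": 0.085,
        }))
    return GrowthReference(pd.concat(frames, ignore_index=True))
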