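"""The 102-dimensional feature vector of one observation window.

Six series are analyzed: the four measured trends (HR, SBP, DBP, MAP) plus
two derived ones — pulse pressure ``PP = SBP - DBP`` and relative cardiac
output ``CO = HR * PP`` (a Windkessel proxy, proportional to true cardiac
output up to arterial compliance). Four feature groups:

* 48 statistical — per series: mean, median, SD, variance, IQR, skewness,
  kurtosis, least-squares slope (units per minute);
* 15 cross-correlation — zero-lag, uncentered: ``R_XY(0) = (1/n) sum x_i y_i``
  over the 15 unordered series pairs;
* 36 wavelet — relative energies of a 5-level discrete Meyer decomposition,
  ``(Er_a5, Er_d1, ..., Er_d5)`` per series;
* 3 clinical — patient age; total raising-group and lowering-group
  medication dose (mcg/kg) delivered during the observation window.

Conventions (the observation-validity check guarantees <= 5% missing data):
statistics use the non-missing values only; cross-correlations average over
the minutes where both pair members are present; wavelet energies are
computed after linear interpolation of interior gaps with nearest-value
extension at the edges. Variance/SD are population (divide by n); skewness
and kurtosis are the third and fourth standardized central moments
(kurtosis non-excess), defined as 0 for a constant series.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from ._dwt import relative_energies
from .records import HemodynamicRecord
from .windows import LabeledExample

__all__ = [
    "SERIES_ORDER",
    "FEATURE_NAMES",
    "derive_series",
    "statistical_features",
    "cross_correlation_features",
    "wavelet_features",
    "clinical_features",
    "extract_features",
    "features_from_slices",
]

SERIES_ORDER = ("hr", "sbp", "dbp", "map", "pp", "co")
STAT_NAMES = ("mean", "median", "sd", "var", "iqr", "skew", "kurt", "slope")
WAVELET_NAMES = ("Er_a5", "Er_d1", "Er_d2", "Er_d3", "Er_d4", "Er_d5")
PAIR_ORDER = tuple(combinations(SERIES_ORDER, 2))

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"{s}_{stat}" for s in SERIES_ORDER for stat in STAT_NAMES)
    + tuple(f"xcorr_{a}_{b}" for a, b in PAIR_ORDER)
    + tuple(f"{s}_{w}" for s in SERIES_ORDER for w in WAVELET_NAMES)
    + ("age", "dose_raising", "dose_lowering")
)
assert len(FEATURE_NAMES) == 102  # 8*6 + C(6,2) + 6*6 + 3


def derive_series(obs_slices: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Add PP and CO to the four measured slices.

    Minutes where any needed input is missing are missing in the derived
    series (NaN propagates through the arithmetic).
    """
    out = {name: np.asarray(obs_slices[name], dtype=float) for name in obs_slices}
    out["pp"] = out["sbp"] - out["dbp"]
    out["co"] = out["hr"] * out["pp"]
    return out


def statistical_features(series: np.ndarray) -> np.ndarray:
    """The eight summary statistics of one series (missing values dropped)."""
    series = np.asarray(series, dtype=float)
    present = ~np.isnan(series)
    values = series[present]
    if len(values) < 2:
        raise ValueError("statistical features need >= 2 non-missing values")
    mean = values.mean()
    centered = values - mean
    var = float(centered @ centered) / len(values)  # population convention
    sd = np.sqrt(var)
    q1, q3 = np.percentile(values, [25.0, 75.0])  # linear interpolation
    if sd > 0:
        skew = float(np.mean(centered**3)) / sd**3
        kurt = float(np.mean(centered**4)) / sd**4
    else:
        skew = kurt = 0.0  # degenerate-distribution convention
    minutes = np.flatnonzero(present).astype(float)
    slope = float(np.polyfit(minutes, values, 1)[0])
    return np.array([mean, float(np.median(values)), sd, var, q3 - q1, skew, kurt, slope])


def cross_correlation_features(six: dict[str, np.ndarray]) -> np.ndarray:
    """Zero-lag uncentered cross-correlation for the 15 unordered pairs.

    For each pair, ``(1/n) sum x_i y_i`` over the n minutes where both are
    present. A pair with no jointly present minute is a contract violation.
    """
    out = np.empty(len(PAIR_ORDER))
    for j, (a, b) in enumerate(PAIR_ORDER):
        x, y = six[a], six[b]
        joint = ~np.isnan(x) & ~np.isnan(y)
        n = int(joint.sum())
        if n == 0:
            raise ValueError(f"no jointly present minutes for pair ({a}, {b})")
        out[j] = float(x[joint] @ y[joint]) / n
    return out


def _fill_missing(series: np.ndarray) -> np.ndarray:
    """Linear interpolation of interior gaps, nearest-value at the edges."""
    series = np.asarray(series, dtype=float)
    missing = np.isnan(series)
    if not missing.any():
        return series
    if missing.all():
        raise ValueError("cannot impute an all-missing series")
    idx = np.arange(len(series))
    filled = series.copy()
    filled[missing] = np.interp(idx[missing], idx[~missing], series[~missing])
    return filled


def wavelet_features(series: np.ndarray) -> np.ndarray:
    """Relative Meyer-band energies ``(Er_a5, Er_d1, ..., Er_d5)`` of one series.

    The series is gap-filled first so the decomposition sees a uniform grid.
    The six values are nonnegative and sum to 1.
    """
    return relative_energies(_fill_missing(series), levels=5)


def clinical_features(record: HemodynamicRecord, example: LabeledExample) -> np.ndarray:
    """(age, raising-group dose, lowering-group dose) for one example.

    Doses are summed over medication events whose minute falls in the
    half-open observation window ``[obs_start, obs_end)``; no events means
    zero dose.
    """
    return _clinical(record.age, record.medications, example.obs_start, example.obs_end)


def _clinical(age, medications, obs_start, obs_end) -> np.ndarray:
    raising = lowering = 0.0
    for ev in medications:
        if obs_start <= ev.minute_index < obs_end:
            if ev.group == "raising":
                raising += ev.dose
            else:
                lowering += ev.dose
    return np.array([float(age), raising, lowering])


def features_from_slices(
    obs_slices: dict[str, np.ndarray],
    age: float,
    medications: list,
    obs_start: int,
    obs_end: int,
) -> np.ndarray:
    """Assemble the full 102-vector from raw observation slices."""
    six = derive_series(obs_slices)
    stats = np.concatenate([statistical_features(six[s]) for s in SERIES_ORDER])
    xcorr = cross_correlation_features(six)
    wavelets = np.concatenate([wavelet_features(six[s]) for s in SERIES_ORDER])
    clinical = _clinical(age, medications, obs_start, obs_end)
    vector = np.concatenate([stats, xcorr, wavelets, clinical])
    assert vector.shape == (102,)
    return vector


def extract_features(example: LabeledExample, record: HemodynamicRecord) -> np.ndarray:
    """The 102-dimensional feature vector of one labeled example.

    A pure function of the observation slices, patient age and medication
    events; ordering follows :data:`FEATURE_NAMES`.
    """
    return features_from_slices(
        example.obs_slices,
        record.age,
        record.medications,
        example.obs_start,
        example.obs_end,
    )
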