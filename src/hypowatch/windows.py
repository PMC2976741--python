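"""Window geometry, episode labeling, and example compilation.

Each labeled example is built from three consecutive intervals of a record
(see the module glossary): an *observation window* (30 or 60 min) whose data
feed the predictors, a *gap* (60 or 120 min) setting the prediction horizon,
and a 30-min *target window* whose label or median MAP is the prediction
target.

Labeling rules (all fractions of the 30-min target window):

* hypotensive — MAP in (10, 60) mmHg for **at least** 90% of minutes;
* control — not hypotensive, and MAP in (10, 200) mmHg for **more than**
  90% of minutes;
* excluded — neither; the window never becomes an example.

The 10/200 bounds are a crude physiologic-plausibility filter; missing
minutes count against every fraction. The observation window must itself
hold in-bound values for more than 95% of minutes, in all four series, or
the candidate is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import HemodynamicRecord

__all__ = [
    "WindowSpec",
    "LabeledExample",
    "label_target_window",
    "check_observation_validity",
    "compile_multiple",
    "compile_single",
]

TARGET_MINUTES = 30

#: Plausibility bounds (mmHg / bpm) used by every in-bound check.
LOWER_BOUND = 10.0
UPPER_BOUND = 200.0

SERIES_NAMES = ("hr", "sbp", "dbp", "map")


@dataclass(frozen=True)
class WindowSpec:
    """Observation/gap geometry. Target length is fixed at 30 minutes."""

    obs_minutes: int = 30
    gap_minutes: int = 60
    target_minutes: int = TARGET_MINUTES

    def __post_init__(self) -> None:
        if self.obs_minutes not in (30, 60):
            raise ValueError(f"obs_minutes must be 30 or 60, got {self.obs_minutes}")
        if self.gap_minutes not in (60, 120):
            raise ValueError(f"gap_minutes must be 60 or 120, got {self.gap_minutes}")
        if self.target_minutes != TARGET_MINUTES:
            raise ValueError("target window length is fixed at 30 minutes")

    @property
    def lead_minutes(self) -> int:
        """Minutes of record needed before a target can start (obs + gap)."""
        return self.obs_minutes + self.gap_minutes


@dataclass
class LabeledExample:
    """One observation-window slice plus its target-window label.

    ``obs_slices`` maps each of hr/sbp/dbp/map to the raw values on
    ``[target_start - gap - obs, target_start - gap)``.
    """

    record_id: str
    target_start: int
    label: str  # "control" | "hypotensive"
    target_median_map: float
    obs_slices: dict[str, np.ndarray]
    spec: WindowSpec = field(default_factory=WindowSpec)

    @property
    def obs_start(self) -> int:
        return self.target_start - self.spec.gap_minutes - self.spec.obs_minutes

    @property
    def obs_end(self) -> int:
        return self.target_start - self.spec.gap_minutes

    @property
    def is_hypotensive(self) -> bool:
        return self.label == "hypotensive"


def _in_bounds(values: np.ndarray, low: float, high: float) -> np.ndarray:
    """Strict in-bound mask; missing (NaN) values fail."""
    with np.errstate(invalid="ignore"):
        return (values > low) & (values < high)


def label_target_window(map_segment: np.ndarray) -> str:
    """Label one 30-minute MAP segment: "hypotensive", "control" or "excluded".

    Hypotensive requires >= 90% of minutes in (10, 60) mmHg; control requires
    > 90% of minutes in (10, 200) mmHg. Missing minutes fail both.
    """
    seg = np.asarray(map_segment, dtype=float)
    if seg.shape != (TARGET_MINUTES,):
        raise ValueError(
            f"target segment must have exactly {TARGET_MINUTES} minutes, got {seg.shape}"
        )
    frac_hypo = _in_bounds(seg, LOWER_BOUND, 60.0).mean()
    if frac_hypo >= 0.90:
        return "hypotensive"
    frac_inbound = _in_bounds(seg, LOWER_BOUND, UPPER_BOUND).mean()
    if frac_inbound > 0.90:
        return "control"
    return "excluded"


def check_observation_validity(obs_slices: dict[str, np.ndarray]) -> bool:
    """True iff all four series are in (10, 200) for > 95% of the window.

    Missing minutes count as out of bounds. All four slices must share one
    length (the observation-window length).
    """
    lengths = {name: len(np.asarray(obs_slices[name])) for name in SERIES_NAMES}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"observation slices differ in length: {lengths}")
    for name in SERIES_NAMES:
        values = np.asarray(obs_slices[name], dtype=float)
        if _in_bounds(values, LOWER_BOUND, UPPER_BOUND).mean() <= 0.95:
            return False
    return True


def _slices(record: HemodynamicRecord, start: int, stop: int) -> dict[str, np.ndarray]:
    return {name: record.series(name)[start:stop].copy() for name in SERIES_NAMES}


def _candidate(
    record: HemodynamicRecord, spec: WindowSpec, target_start: int
) -> LabeledExample | None:
    """Build the example at ``target_start``, or None if any check fails."""
    target = record.map[target_start : target_start + TARGET_MINUTES]
    label = label_target_window(target)
    if label == "excluded":
        return None
    obs = _slices(record, target_start - spec.lead_minutes, target_start - spec.gap_minutes)
    if not check_observation_validity(obs):
        return None
    present = target[~np.isnan(target)]
    return LabeledExample(
        record_id=record.record_id,
        target_start=target_start,
        label=label,
        target_median_map=float(np.median(present)),
        obs_slices=obs,
        spec=spec,
    )


def compile_multiple(record: HemodynamicRecord, spec: WindowSpec) -> list[LabeledExample]:
    """All valid examples from non-overlapping target windows tiling the record.

    Candidate targets start at minutes 0, 30, 60, ...; a candidate survives
    iff the full observation window fits before it (``target_start >= obs +
    gap``), the target fits inside the record, the observation window passes
    validity, and the target labels control or hypotensive.
    """
    n = record.n_minutes
    examples = []
    first = int(np.ceil(spec.lead_minutes / TARGET_MINUTES)) * TARGET_MINUTES
    for target_start in range(first, n - TARGET_MINUTES + 1, TARGET_MINUTES):
        example = _candidate(record, spec, target_start)
        if example is not None:
            examples.append(example)
    return examples


def compile_single(
    record: HemodynamicRecord, spec: WindowSpec, seed: int
) -> LabeledExample | None:
    """At most one example per record, hypotensive-first.

    If the record yields any hypotensive candidate, one is drawn uniformly
    from those; otherwise one control candidate is drawn uniformly; otherwise
    None. The draw is a pure function of ``seed``.
    """
    candidates = compile_multiple(record, spec)
    hypo = [ex for ex in candidates if ex.is_hypotensive]
    pool = hypo if hypo else candidates
    if not pool:
        return None
    rng = np.random.default_rng(seed)
    return pool[int(rng.integers(len(pool)))]
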