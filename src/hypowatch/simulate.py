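"""Seeded synthetic ICU cohorts with controllable hypotensive episodes.

Stands in for the real minute-by-minute bedside-monitor data: each record is
an AR(1) process around a slowly drifting baseline for MAP, pulse pressure
and HR, with SBP/DBP reconstructed from MAP and PP (``SBP = MAP + 2 PP / 3``,
``DBP = SBP - PP``) so the four pressures are mutually consistent.

Hypotensive episodes are imposed deterministically: onsets from a Poisson
count per record, the MAP level ramped down to a sub-60 mmHg plateau and
back. Optional *precursor* signatures — a linear MAP drift, progressive
pulse-pressure narrowing, and inflated noise variance — are injected during
the window immediately preceding each onset, which is what makes the
prediction task solvable in principle (and makes a null cohort, all effects
zero, a genuine no-signal control). Missing minutes, out-of-bound artifact
spikes, and post-onset pressor doses are optional corruptions.

Determinism: record ``i`` of a cohort is a pure function of
``(config, config.seed, i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import RAISING_DRUGS, HemodynamicRecord, MedicationEvent
from .windows import WindowSpec, compile_multiple, label_target_window

__all__ = ["SimulationConfig", "Cohort", "simulate_record", "simulate_cohort"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults emulate the real data.

    Durations are lognormal (median ~79.8 h, shape sigma 0.9 reproducing the
    skewed IQR of real ICU stays); baselines are typical adult ICU values;
    ``episode_rate`` is the expected episode count per record (Poisson).
    Precursor effect sizes of zero yield a null cohort.
    """

    n_records: int = 100
    duration_median_minutes: float = 4788.0  # 79.8 h
    duration_sigma: float = 0.9
    min_duration_minutes: int = 300
    baseline_map: float = 80.0  # mmHg
    baseline_hr: float = 85.0  # beats/min
    baseline_pp: float = 45.0  # mmHg
    ar_coef: float = 0.9
    map_noise_sd: float = 0.8  # AR(1) innovation SDs
    pp_noise_sd: float = 0.7
    hr_noise_sd: float = 1.0
    drift_sd: float = 0.05  # random-walk baseline drift, units/min
    episode_rate: float = 3.6  # expected HEs per record
    episode_depth: float = 50.0  # plateau MAP, mmHg
    episode_ramp_minutes: int = 10
    episode_plateau_minutes: int = 60
    precursor_map_slope: float = 0.0  # mmHg/min (negative = downward drift)
    precursor_pp_narrow: float = 0.0  # fractional PP narrowing reached at onset
    precursor_var_mult: float = 1.0  # innovation-SD multiplier at onset
    precursor_minutes: int = 90  # obs + gap horizon before onset
    missing_rate: float = 0.0
    artifact_rate: float = 0.0
    med_response: bool = False
    baseline_map_between_sd: float = 7.0  # between-record baseline spread, mmHg
    baseline_pp_between_sd: float = 6.0
    baseline_hr_between_sd: float = 9.0
    age_low: float = 18.0
    age_high: float = 95.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "artifact_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.episode_rate < 0 or self.precursor_var_mult <= 0:
            raise ValueError("episode_rate must be >= 0 and precursor_var_mult > 0")
        min_needed = 30 + 120 + 60  # target + max gap + max obs
        if self.min_duration_minutes < min_needed:
            raise ValueError(
                f"min_duration_minutes must be >= {min_needed} "
                "(observation + gap + target)"
            )
        if not 0 <= self.episode_depth < 60:
            raise ValueError("episode_depth must lie below the 60 mmHg threshold")

    @property
    def episode_span(self) -> int:
        return 2 * self.episode_ramp_minutes + self.episode_plateau_minutes


def _record_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), int(index)])


def _ar1(rng, n: int, coef: float, sd_path: np.ndarray) -> np.ndarray:
    """AR(1) noise with a time-varying innovation SD."""
    innovations = rng.normal(0.0, 1.0, n) * sd_path
    out = np.empty(n)
    prev = innovations[0] / np.sqrt(max(1.0 - coef**2, 1e-12))
    for t in range(n):
        prev = coef * prev + innovations[t]
        out[t] = prev
    return out


def _draw_onsets(rng, config: SimulationConfig, duration: int) -> list[int]:
    """Poisson-count episode onsets, non-overlapping, full episode in-record."""
    lead = config.precursor_minutes + 30
    last = duration - config.episode_span - 30
    if last <= lead:
        return []
    n_ep = rng.poisson(config.episode_rate)
    onsets: list[int] = []
    spacing = config.episode_span + config.precursor_minutes + 60
    for _ in range(200):
        if len(onsets) >= n_ep:
            break
        cand = int(rng.integers(lead, last + 1))
        if all(abs(cand - o) >= spacing for o in onsets):
            onsets.append(cand)
    return sorted(onsets)


def simulate_record_with_truth(
    config: SimulationConfig, record_index: int
) -> tuple[HemodynamicRecord, dict]:
    """Generate one record plus its ground truth (episode onsets/intervals)."""
    rng = _record_rng(config, record_index)

    # between-patient heterogeneity: each record gets its own resting levels
    map0 = config.baseline_map + rng.normal(0.0, config.baseline_map_between_sd)
    map0 = float(np.clip(map0, 68.0, 100.0))
    pp0 = float(np.clip(config.baseline_pp + rng.normal(0.0, config.baseline_pp_between_sd), 25.0, 60.0))
    hr0 = float(np.clip(config.baseline_hr + rng.normal(0.0, config.baseline_hr_between_sd), 55.0, 115.0))

    duration = int(
        round(config.duration_median_minutes * np.exp(config.duration_sigma * rng.normal()))
    )
    duration = max(duration, config.min_duration_minutes)
    t = np.arange(duration)

    onsets = _draw_onsets(rng, config, duration)
    episodes = [(o, o + config.episode_span) for o in onsets]

    # episode weight (0 -> 1 -> 0 over ramp/plateau/ramp) and precursor progress
    w = np.zeros(duration)
    progress = np.zeros(duration)
    ramp, plateau = config.episode_ramp_minutes, config.episode_plateau_minutes
    for onset, end in episodes:
        seg = np.arange(onset, end)
        rel = seg - onset
        w_seg = np.where(
            rel < ramp,
            rel / ramp,
            np.where(rel < ramp + plateau, 1.0, (config.episode_span - rel) / ramp),
        )
        w[seg] = np.maximum(w[seg], w_seg)
        pre = np.arange(max(onset - config.precursor_minutes, 0), onset)
        progress[pre] = (pre - (onset - config.precursor_minutes)) / config.precursor_minutes
        # hold the accumulated precursor drift through the episode itself
        progress[onset:end] = 1.0

    sd_scale = 1.0 + (config.precursor_var_mult - 1.0) * np.where(w > 0, 0.0, progress)

    # random-walk baselines, clipped so normotensive stretches stay normotensive
    map_base = np.clip(
        map0 + np.cumsum(rng.normal(0.0, config.drift_sd, duration)), 65.0, 105.0
    )
    pp_base = np.clip(
        pp0 + np.cumsum(rng.normal(0.0, config.drift_sd, duration)), 22.0, 65.0
    )
    hr_base = np.clip(
        hr0 + np.cumsum(rng.normal(0.0, config.drift_sd, duration)), 50.0, 120.0
    )

    prec_drop = config.precursor_map_slope * config.precursor_minutes * progress
    map_level = (1.0 - w) * (map_base + prec_drop) + w * config.episode_depth
    pp_level = pp_base * (1.0 - config.precursor_pp_narrow * progress)
    hr_level = hr_base + 10.0 * w  # mild compensatory tachycardia

    map_sig = map_level + _ar1(rng, duration, config.ar_coef, config.map_noise_sd * sd_scale)
    pp_sig = pp_level + _ar1(rng, duration, config.ar_coef, config.pp_noise_sd * sd_scale)
    hr_sig = hr_level + _ar1(rng, duration, config.ar_coef, config.hr_noise_sd * sd_scale)
    pp_sig = np.maximum(pp_sig, 5.0)

    sbp = map_sig + 2.0 * pp_sig / 3.0
    dbp = sbp - pp_sig

    # out-of-bound artifact spikes on HR or MAP (keeps SBP >= DBP intact)
    if config.artifact_rate > 0:
        spikes = np.flatnonzero(rng.random(duration) < config.artifact_rate)
        for minute in spikes:
            target = hr_sig if rng.random() < 0.5 else map_sig
            target[minute] = float(rng.uniform(205.0, 280.0) if rng.random() < 0.5 else rng.uniform(0.0, 9.0))

    if config.missing_rate > 0:
        gone = rng.random(duration) < config.missing_rate
        for arr in (hr_sig, sbp, dbp, map_sig):
            arr[gone] = np.nan

    medications: list[MedicationEvent] = []
    if config.med_response:
        pressors = sorted(RAISING_DRUGS)
        for onset, _ in episodes:
            minute = onset + int(rng.integers(3, 12))
            if minute < duration:
                medications.append(
                    MedicationEvent(
                        minute_index=minute,
                        drug_name=pressors[int(rng.integers(len(pressors)))],
                        dose=float(np.round(rng.uniform(0.5, 5.0), 3)),
                    )
                )

    record = HemodynamicRecord(
        record_id=f"sim{record_index:05d}",
        hr=hr_sig,
        sbp=sbp,
        dbp=dbp,
        map=map_sig,
        age=float(np.round(rng.uniform(config.age_low, config.age_high), 1)),
        medications=medications,
    )
    truth = {"onsets": onsets, "episodes": episodes, "duration": duration}
    return record, truth


def simulate_record(config: SimulationConfig, record_index: int) -> HemodynamicRecord:
    """Generate record ``record_index`` of the cohort defined by ``config``."""
    return simulate_record_with_truth(config, record_index)[0]


@dataclass
class Cohort:
    """A simulated cohort plus per-record ground truth and HE prevalence.

    ``prevalence`` is the empirical fraction of hypotensive target windows
    under multiple compilation with the default 30/60 window geometry.
    """

    records: list[HemodynamicRecord]
    truths: list[dict]
    config: SimulationConfig
    prevalence: float = field(init=False)

    def __post_init__(self) -> None:
        spec = WindowSpec(30, 60)
        n_hypo = n_total = 0
        for record in self.records:
            for ex in compile_multiple(record, spec):
                n_total += 1
                n_hypo += ex.is_hypotensive
        self.prevalence = n_hypo / n_total if n_total else float("nan")


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full cohort; records are independent across indices."""
    pairs = [simulate_record_with_truth(config, i) for i in range(config.n_records)]
    return Cohort(
        records=[r for r, _ in pairs],
        truths=[t for _, t in pairs],
        config=config,
    )


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The matched no-signal control: same cohort, all precursor effects zero."""
    return replace(
        config,
        precursor_map_slope=0.0,
        precursor_pp_narrow=0.0,
        precursor_var_mult=1.0,
    )


def target_window_label(map_segment: np.ndarray) -> str:
    """Re-export of the labeling rule for cross-module contract checks."""
    return label_target_window(map_segment)
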