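"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* :func:`generate_paired_accel` emulates a pair of body-worn tri-axial
  accelerometer recordings (wrist of the intact hand, upper residual arm)
  during daily routine: a constant per-axis gravity offset, Gaussian
  sensor noise, limb-specific movement bursts at Poisson-like rates, and
  whole-body co-movements that appear on both limbs at shared times.  The
  true event intervals are returned as the detector's recovery target.

* :func:`generate_cohort` draws schema-valid participant records with the
  statistical structure the analysis plan assumes: group-specific
  laterality-index and questionnaire distributions, group × limb
  activation (β) cell means, and bivariate-normal correlations between
  residual-arm usage and intact-hand β, and between phantom-pain score
  and usage.

Both generators take one explicit seed and draw from a single
``numpy.random.Generator``; no global random state is touched, and
identical parameters + seed give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AccelTrace, CohortRecord, ValidationError

__all__ = [
    "AccelSimParams",
    "GroundTruth",
    "CohortSimParams",
    "generate_paired_accel",
    "generate_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AccelSimParams:
    """Paired-trace generator parameters.

    Rates are events per minute.  ``burst_amp`` is the peak-to-peak burst
    amplitude in m/s²; bursts are single-cycle sinusoids of duration
    ``burst_dur_ms`` on one randomly chosen axis.  ``min_gap_ms`` is the
    enforced quiet gap between consecutive burst intervals on the same
    limb; the default (3000 ms) leaves room for the detector's smoothing
    smear plus its quiescence requirement, so that well-separated bursts
    stay individually recoverable.
    """

    duration_s: float = 120.0
    rate_intact: float = 6.0
    rate_residual: float = 2.0
    coupled_rate: float = 1.0
    burst_amp: float = 0.5
    burst_dur_ms: float = 1000.0
    noise_sd: float = 0.02
    gravity_offset: tuple[float, float, float] = (0.0, 0.0, 9.81)
    sample_rate: float = 100.0
    min_gap_ms: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        for name in ("rate_intact", "rate_residual", "coupled_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.burst_amp < 0 or self.burst_dur_ms <= 0 or self.sample_rate <= 0:
            raise ValidationError("burst_amp >= 0 and burst_dur_ms, sample_rate > 0 required")
        total_rate = self.rate_intact + self.rate_residual + self.coupled_rate
        if total_rate > 0:
            spacing_ms = 60000.0 / total_rate
            if spacing_ms < 3 * self.burst_dur_ms:
                logger.warning(
                    "expected event spacing (%.0f ms) is not much larger than "
                    "burst duration (%.0f ms); events may be hard to identify",
                    spacing_ms, self.burst_dur_ms,
                )


@dataclass(frozen=True)
class GroundTruth:
    """True event intervals per limb (half-open sample intervals) and the
    generating parameters.  Coupled events appear in both lists."""

    events_intact: tuple[tuple[int, int], ...]
    events_residual: tuple[tuple[int, int], ...]
    params: AccelSimParams


def _place_onsets(rng: np.random.Generator, n_wanted: int, existing: list[tuple[int, int]],
                  lo: int, hi: int, burst_n: int, gap_n: int) -> list[int]:
    """Uniformly place up to n_wanted burst onsets in [lo, hi), keeping every
    burst interval at least gap_n samples away from accepted intervals."""
    onsets: list[int] = []
    intervals = list(existing)
    attempts = 0
    while len(onsets) < n_wanted and attempts < 200 * max(1, n_wanted):
        attempts += 1
        s = int(rng.integers(lo, hi))
        e = s + burst_n
        if all(s - gap_n >= ie or e + gap_n <= is_ for is_, ie in intervals):
            onsets.append(s)
            intervals.append((s, e))
    if len(onsets) < n_wanted:
        logger.warning("placed only %d of %d requested bursts (trace too crowded)",
                       len(onsets), n_wanted)
    return onsets


def generate_paired_accel(params: AccelSimParams) -> tuple[AccelTrace, AccelTrace, GroundTruth]:
    """Simulate one participant's paired recordings plus ground truth."""
    fs = params.sample_rate
    n = int(round(params.duration_s * fs))
    burst_n = max(2, int(round(params.burst_dur_ms * fs / 1000.0)))
    gap_n = int(round(params.min_gap_ms * fs / 1000.0))
    # edge margin so the first/last events keep room for quiescence
    margin = gap_n // 2 + burst_n
    rng = np.random.default_rng(params.seed)

    minutes = params.duration_s / 60.0
    counts = {
        "coupled": rng.poisson(params.coupled_rate * minutes),
        "intact": rng.poisson(params.rate_intact * minutes),
        "residual": rng.poisson(params.rate_residual * minutes),
    }
    lo, hi = margin, max(margin + 1, n - margin - burst_n)

    coupled = _place_onsets(rng, counts["coupled"], [], lo, hi, burst_n, gap_n)
    coupled_iv = [(s, s + burst_n) for s in coupled]
    own = {
        "intact": _place_onsets(rng, counts["intact"], coupled_iv, lo, hi, burst_n, gap_n),
        "residual": _place_onsets(rng, counts["residual"], coupled_iv, lo, hi, burst_n, gap_n),
    }

    waveform = 0.5 * params.burst_amp * np.sin(2 * np.pi * np.arange(burst_n) / burst_n)
    offset = np.asarray(params.gravity_offset, dtype=float)
    traces = {}
    truth = {}
    for limb in ("intact", "residual"):
        data = offset + rng.normal(0.0, params.noise_sd, size=(n, 3))
        onsets = sorted(coupled + own[limb])
        for s in onsets:
            axis = int(rng.integers(0, 3))  # independent axis per limb & event
            data[s : s + burst_n, axis] += waveform
        traces[limb] = AccelTrace(data=data, sample_rate=fs, limb_label=limb)
        truth[limb] = tuple((s, s + burst_n) for s in onsets)

    gt = GroundTruth(events_intact=truth["intact"], events_residual=truth["residual"],
                     params=params)
    return traces["intact"], traces["residual"], gt


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort generator parameters.

    Group sizes default to 11 congenital, 18 acquired and 21 controls.
    Laterality-index and questionnaire (MAL) means/SDs are per one-handed
    group; controls carry neither score.  ``beta_cell_means`` gives the
    group × limb activation means; ``usage_beta_rho`` is the generating
    correlation between MAL score and intact-hand β within the one-handed
    groups, ``pain_usage_rho`` the correlation between chronic-pain score
    and MAL within the acquired group.  Bounded scores are clipped to
    their scales with a logged count; at the defaults clipping affects
    ≈1% of draws.
    """

    n_congenital: int = 11
    n_acquired: int = 18
    n_control: int = 21
    li_means: dict = field(default_factory=lambda: {"congenital": 0.40, "acquired": 0.65})
    li_sd: dict = field(default_factory=lambda: {"congenital": 0.22, "acquired": 0.15})
    mal_means: dict = field(default_factory=lambda: {"congenital": 0.65, "acquired": 0.43})
    mal_sd: dict = field(default_factory=lambda: {"congenital": 0.15, "acquired": 0.15})
    pain_mean: float = 3.0
    pain_sd: float = 2.0
    beta_cell_means: dict = field(
        default_factory=lambda: {
            ("congenital", "residual"): 1.0,
            ("congenital", "intact"): 0.3,
            ("acquired", "residual"): 0.2,
            ("acquired", "intact"): 1.0,
            ("control", "residual"): 0.5,
            ("control", "intact"): 0.5,
        }
    )
    beta_sd: float = 0.8
    usage_beta_rho: float = -0.43
    pain_usage_rho: float = -0.40
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("n_congenital", "n_acquired", "n_control"):
            if getattr(self, nm) < 2:
                raise ValidationError(f"{nm} must be >= 2")
        for rho in (self.usage_beta_rho, self.pain_usage_rho):
            if not abs(rho) < 1:
                raise ValidationError("|rho| must be < 1")
        for sd in (*self.li_sd.values(), *self.mal_sd.values(), self.beta_sd, self.pain_sd):
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")
        if 1.0 - self.usage_beta_rho**2 - self.pain_usage_rho**2 <= 0:
            raise ValidationError(
                "correlation structure not positive definite: "
                "usage_beta_rho^2 + pain_usage_rho^2 must be < 1"
            )


def _clip(values: np.ndarray, lo: float, hi: float, label: str) -> np.ndarray:
    n_clip = int(((values < lo) | (values > hi)).sum())
    if n_clip:
        logger.info("clipped %d %s draw(s) to [%g, %g]", n_clip, label, lo, hi)
    return np.clip(values, lo, hi)


def generate_cohort(params: CohortSimParams) -> list[CohortRecord]:
    """Draw a schema-valid synthetic cohort.

    Within each one-handed group the MAL score, intact-hand β and (for the
    acquired group) the chronic-pain score are drawn from a trivariate
    normal whose off-diagonal entries are ``usage_beta_rho`` (MAL ↔ β) and
    ``pain_usage_rho`` (pain ↔ MAL); pain and β are conditionally
    independent given usage.  All other fields are independent per-group
    draws.  Pain intensity/frequency codes are derived from the continuous
    pain score so that ``intensity / frequency`` reproduces it as closely
    as the coded scales allow.
    """
    rng = np.random.default_rng(params.seed)
    records: list[CohortRecord] = []
    sizes = {"congenital": params.n_congenital, "acquired": params.n_acquired,
             "control": params.n_control}
    counter = 0
    for group, n_g in sizes.items():
        for i in range(n_g):
            counter += 1
            pid = f"S{counter:03d}"
            if group == "control":
                beta_r = rng.normal(params.beta_cell_means[(group, "residual")], params.beta_sd)
                beta_i = rng.normal(params.beta_cell_means[(group, "intact")], params.beta_sd)
                records.append(CohortRecord(
                    participant_id=pid, group=group,
                    beta_intact_hand=float(beta_i), beta_residual_arm=float(beta_r),
                ))
                continue
            # correlated standard-normal triple (usage, beta_intact, pain)
            r1, r2 = params.usage_beta_rho, params.pain_usage_rho
            cov = np.array([[1.0, r1, r2], [r1, 1.0, r1 * r2], [r2, r1 * r2, 1.0]])
            u, v, w = rng.multivariate_normal(np.zeros(3), cov, method="cholesky")
            mal = float(_clip(np.array([params.mal_means[group] + params.mal_sd[group] * u]),
                              0.0, 1.0, "mal_score")[0])
            beta_i = params.beta_cell_means[(group, "intact")] + params.beta_sd * v
            beta_r = rng.normal(params.beta_cell_means[(group, "residual")], params.beta_sd)
            li = float(_clip(np.array([rng.normal(params.li_means[group], params.li_sd[group])]),
                             -1.0, 1.0, "laterality_index")[0])
            # encode the continuous pain score into intensity/frequency codes
            # so that intensity / frequency ≈ the drawn score
            pain_raw = float(np.clip(params.pain_mean + params.pain_sd * w, 0.0, 10.0))
            feasible = [f for f in (1, 2, 3, 4, 5) if pain_raw * f <= 10.0]
            frequency = int(rng.choice(feasible)) if feasible else 1
            intensity = float(np.clip(round(pain_raw * frequency), 0, 10))
            if group == "congenital":
                # congenital absence: no amputation event, no phantom pain
                deprivation_age = 0.0
                intensity, frequency = 0.0, 5
                level = int(rng.choice([2, 4, 5], p=[0.1, 0.7, 0.2]))
            else:
                deprivation_age = float(rng.integers(11, 49))
                level = int(rng.choice([1, 2, 4, 5], p=[0.1, 0.2, 0.55, 0.15]))
            records.append(CohortRecord(
                participant_id=pid, group=group,
                amputation_level=level,
                side=str(rng.choice(["L", "R"])),
                deprivation_age=deprivation_age,
                cosmetic_prosthesis_usage=int(rng.integers(0, 6)),
                functional_prosthesis_usage=int(rng.integers(0, 6)),
                mal_score=mal,
                pain_intensity=intensity,
                pain_frequency=frequency,
                laterality_index=li,
                beta_intact_hand=float(beta_i),
                beta_residual_arm=float(beta_r),
            ))
    return records
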