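"""Synthetic multichannel cyclic signals and cohorts.

Four single-run regimes exercise the lead-matrix machinery:

1. phase-shifted sinusoids with additive white noise at a requested SNR;
2. two sets of sinusoids with different amplitudes and an inter-set offset;
3. a two-harmonic signal, where channels carrying the second harmonic are
   invisible to the leading eigenvector (they appear at the origin) and
   need the second eigenvector pair;
4. a cyclic but aperiodic signal, obtained by evaluating the periodic
   signal at monotonically warped times.

``gen_cohort`` builds a two-group, two-session cohort emulating a
resting-state study: every subject has a persistent phase template (group
template plus a subject-specific offset), and every run perturbs it with
group-dependent jitter.  The group contrast is carried purely by the
jitter magnitude — amplitudes are identical across groups — so any
downstream discrimination must come from lead-matrix structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import TimeCourse

__all__ = [
    "SinusoidSpec",
    "CohortSpec",
    "SubjectRecord",
    "gen_phase_shifted_sinusoids",
    "gen_two_set_offset",
    "gen_two_harmonics",
    "gen_cyclic_aperiodic",
    "gen_cohort",
]


class SpecificationError(ValueError):
    """Raised when a generator spec violates its invariants."""


def _as_array(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise SpecificationError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr


@dataclass
class SinusoidSpec:
    """Parameters of a bank of phase-shifted (possibly multi-harmonic) sinusoids.

    ``snr`` is the signal-to-noise *power* ratio per channel; ``np.inf``
    means noiseless.
    """

    n_channels: int
    amplitudes: Sequence[float] | float = 1.0
    phases: Sequence[float] | None = None
    n_periods: int = 4
    n_samples: int = 600
    snr: float = np.inf
    harmonic_multiplier: Sequence[int] | int = 1

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise SpecificationError("n_channels must be positive")
        self.amplitudes = _as_array(self.amplitudes, self.n_channels, "amplitudes")
        if np.any(self.amplitudes <= 0):
            raise SpecificationError("amplitudes must be positive")
        if self.phases is None:
            # evenly spread phases over the circle by default
            self.phases = 2.0 * np.pi * np.arange(self.n_channels) / self.n_channels
        self.phases = np.mod(_as_array(self.phases, self.n_channels, "phases"), 2 * np.pi)
        self.harmonic_multiplier = _as_array(
            self.harmonic_multiplier, self.n_channels, "harmonic_multiplier"
        ).astype(int)
        if np.any(self.harmonic_multiplier < 1):
            raise SpecificationError("harmonic multipliers must be positive integers")
        if self.n_periods < 1 or self.n_samples < 2:
            raise SpecificationError("n_periods and n_samples must be positive")
        if self.n_samples < 4 * self.n_periods * int(self.harmonic_multiplier.max()):
            raise SpecificationError(
                "n_samples must be at least 4 x n_periods x max harmonic"
            )
        if not (self.snr > 0):
            raise SpecificationError("snr must be positive (np.inf for noiseless)")


def _eval_signal(spec: SinusoidSpec, t: np.ndarray) -> np.ndarray:
    amp = np.asarray(spec.amplitudes)[:, None]
    mult = np.asarray(spec.harmonic_multiplier)[:, None]
    ph = np.asarray(spec.phases)[:, None]
    return amp * np.sin(mult * t[None, :] + ph)


def _add_noise(signal: np.ndarray, snr: float, rng: np.random.Generator) -> np.ndarray:
    if np.isinf(snr):
        return signal
    power = np.mean(signal**2, axis=1, keepdims=True)
    sigma = np.sqrt(power / snr)
    return signal + sigma * rng.standard_normal(signal.shape)


def _grid(spec: SinusoidSpec) -> np.ndarray:
    # endpoint-exclusive grid over whole periods, so the noiseless path closes;
    # composed as scale * unit-fraction so warped grids share the rounding
    return (2.0 * np.pi * spec.n_periods) * (np.arange(spec.n_samples) / spec.n_samples)


def gen_phase_shifted_sinusoids(spec: SinusoidSpec, seed: int) -> TimeCourse:
    """Bank of phase-shifted sinusoids with white Gaussian noise at ``spec.snr``."""
    rng = np.random.default_rng(seed)
    sig = _eval_signal(spec, _grid(spec))
    return TimeCourse(_add_noise(sig, spec.snr, rng))


def gen_two_set_offset(
    spec_a: SinusoidSpec, spec_b: SinusoidSpec, inter_set_offset: float, seed: int
) -> TimeCourse:
    """Two stacked sinusoid sets; set b's phases shifted by ``inter_set_offset``."""
    if spec_a.n_periods != spec_b.n_periods or spec_a.n_samples != spec_b.n_samples:
        raise SpecificationError("both sets must share n_periods and n_samples")
    rng = np.random.default_rng(seed)
    t = _grid(spec_a)
    shifted = SinusoidSpec(
        spec_b.n_channels,
        spec_b.amplitudes,
        np.mod(np.asarray(spec_b.phases) + inter_set_offset, 2 * np.pi),
        spec_b.n_periods,
        spec_b.n_samples,
        spec_b.snr,
        spec_b.harmonic_multiplier,
    )
    sig = np.vstack([_eval_signal(spec_a, t), _eval_signal(shifted, t)])
    snr = spec_a.snr  # noise level follows set a's request, applied channelwise
    out = _add_noise(sig, snr, rng)
    labels = [f"a{k}" for k in range(spec_a.n_channels)] + [
        f"b{k}" for k in range(spec_b.n_channels)
    ]
    return TimeCourse(out, labels)


def gen_two_harmonics(base_spec: SinusoidSpec, seed: int) -> TimeCourse:
    """Signal mixing first and second harmonics across channels.

    Channels carrying only the second harmonic contribute nothing to the
    leading eigenvector (their component sits at the origin); recovering
    their phases requires the second eigenvector pair.
    """
    mult = np.asarray(base_spec.harmonic_multiplier)
    if len(set(mult.tolist())) < 2:
        raise SpecificationError(
            "two-harmonic regime needs at least two distinct harmonic multipliers"
        )
    return gen_phase_shifted_sinusoids(base_spec, seed)


def gen_cyclic_aperiodic(
    spec: SinusoidSpec, warp: Callable[[np.ndarray], np.ndarray], seed: int
) -> TimeCourse:
    """Aperiodic version of the periodic signal via a monotone time warp.

    The analytic signal is evaluated at warped times (no resampling), so
    with the identity warp the output equals the periodic generator's.
    """
    rng = np.random.default_rng(seed)
    u = np.arange(spec.n_samples) / spec.n_samples
    w = np.asarray(warp(u), dtype=float)
    if w.shape != u.shape or np.any(np.diff(w) <= 0):
        raise SpecificationError("warp must be strictly increasing on [0, 1)")
    if abs(float(warp(np.array([0.0]))[0])) > 1e-12 or abs(float(warp(np.array([1.0]))[0]) - 1.0) > 1e-12:
        raise SpecificationError("warp must fix the endpoints warp(0)=0, warp(1)=1")
    t = (2.0 * np.pi * spec.n_periods) * w
    sig = _eval_signal(spec, t)
    return TimeCourse(_add_noise(sig, spec.snr, rng))


@dataclass
class CohortSpec:
    """Two-group, multi-session cohort layout and noise/jitter levels.

    Defaults mirror a two-group resting-state design: 15 vs 32 subjects,
    33 channels x 300 samples per run, 2 sessions x 2 runs.  Group phase
    templates are identical; groups differ only in the per-run phase jitter
    (``ordering_jitter_a`` vs ``ordering_jitter_b``).  ``subject_jitter``
    is the std of each subject's persistent offset from the group template,
    the structure that makes cross-session fingerprinting possible.

    If ``contrast_channels`` is set, group b's larger jitter applies only to
    those channel indices (its other channels keep group a's jitter) —
    emulating a contrast in which one group's phase ordering around a few
    designated regions is consistent while the other group's is variable.
    With the default ``None`` the group-b jitter applies to every channel.
    """

    n_group_a: int = 15
    n_group_b: int = 32
    n_channels: int = 33
    n_samples: int = 300
    n_sessions: int = 2
    runs_per_session: int = 2
    n_periods: int = 6
    ordering_jitter_a: float = 0.1
    ordering_jitter_b: float = 0.4
    subject_jitter: float = 0.5
    snr: float = 20.0
    seed: int = 0
    group_names: tuple[str, str] = ("control", "patient")
    contrast_channels: tuple[int, ...] | None = None
    amplitudes: Sequence[float] | float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "n_group_a", "n_group_b", "n_channels", "n_samples",
            "n_sessions", "runs_per_session", "n_periods",
        ):
            if getattr(self, name) < 1:
                raise SpecificationError(f"{name} must be positive")
        for name in ("ordering_jitter_a", "ordering_jitter_b", "subject_jitter"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise SpecificationError(f"{name} must be finite and nonnegative")
        if not (self.snr > 0):
            raise SpecificationError("snr must be positive")
        if self.contrast_channels is not None:
            self.contrast_channels = tuple(int(c) for c in self.contrast_channels)
            if any(c < 0 or c >= self.n_channels for c in self.contrast_channels):
                raise SpecificationError("contrast_channels indices out of range")
        self.amplitudes = _as_array(self.amplitudes, self.n_channels, "amplitudes")
        if np.any(self.amplitudes <= 0):
            raise SpecificationError("amplitudes must be positive")


@dataclass
class SubjectRecord:
    """One run of one subject: identity keys plus the raw time course."""

    subject_id: str
    group: str
    session: int
    run: int
    timecourse: TimeCourse = field(repr=False)


def gen_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate all runs of a two-group cohort, fully seeded.

    Subject phase template = group template + N(0, subject_jitter) per
    channel; each run's phases = subject template + N(0, group run jitter).
    """
    root = np.random.SeedSequence(spec.seed)
    template = 2.0 * np.pi * np.arange(spec.n_channels) / spec.n_channels
    records: list[SubjectRecord] = []
    jitter_a = np.full(spec.n_channels, spec.ordering_jitter_a)
    if spec.contrast_channels is None:
        jitter_b = np.full(spec.n_channels, spec.ordering_jitter_b)
    else:
        jitter_b = jitter_a.copy()
        jitter_b[list(spec.contrast_channels)] = spec.ordering_jitter_b
    groups = [(spec.group_names[0], spec.n_group_a, jitter_a),
              (spec.group_names[1], spec.n_group_b, jitter_b)]
    subject_seeds = root.spawn(spec.n_group_a + spec.n_group_b)
    idx = 0
    for gname, gsize, run_jitter in groups:
        for s in range(gsize):
            sid = f"{gname}_{s:02d}"
            srng = np.random.default_rng(subject_seeds[idx])
            idx += 1
            subj_phases = template + spec.subject_jitter * srng.standard_normal(
                spec.n_channels
            )
            for session in range(1, spec.n_sessions + 1):
                for run in range(1, spec.runs_per_session + 1):
                    run_phases = subj_phases + run_jitter * srng.standard_normal(
                        spec.n_channels
                    )
                    run_spec = SinusoidSpec(
                        n_channels=spec.n_channels,
                        amplitudes=spec.amplitudes,
                        phases=np.mod(run_phases, 2 * np.pi),
                        n_periods=spec.n_periods,
                        n_samples=spec.n_samples,
                        snr=spec.snr,
                    )
                    run_seed = int(srng.integers(0, 2**31 - 1))
                    tc = gen_phase_shifted_sinusoids(run_spec, run_seed)
                    records.append(SubjectRecord(sid, gname, session, run, tc))
    return records
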