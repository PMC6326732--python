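"""Lead-matrix construction and spectral phase analysis.

A multichannel time course is treated as a path in d dimensions.  After
mean-centering and a per-channel linear adjustment that closes the path,
the antisymmetric part of the second-order iterated integral — the *lead
matrix* — records, for every channel pair, the signed area enclosed by the
projection of the path onto that coordinate plane.  A positive entry
``A[i, j]`` means channel ``j`` (column) follows channel ``i`` (row).

Because the construction uses only iterated integrals it is invariant
under translation of the path and under monotone reparameterization of
time, which is what makes it applicable to cyclic-but-aperiodic signals.

The spectrum of the (real, antisymmetric) lead matrix comes in conjugate
pure-imaginary pairs ±iμ.  The eigenvector of the leading +iμ carries one
complex component per channel: its modulus is the channel's cyclic
*strength*, its argument the channel's position in the common cycle.  The
direction of the cycle is not identifiable — phases are defined only up to
one global rotation and one global sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeCourse",
    "LeadMatrix",
    "SpectralSummary",
    "center_and_close",
    "lead_matrix",
    "spectral_decomposition",
    "recover_phase_offsets",
    "circular_rmse",
]


class DataError(ValueError):
    """Raised when an input violates a data contract (non-finite, too short...)."""


def _default_labels(n: int) -> list[str]:
    return [f"ch{k}" for k in range(n)]


@dataclass
class TimeCourse:
    """Channels x samples real matrix with unique channel labels.

    ``sample_spacing`` is nominal and unitless: every quantity computed here
    is invariant under monotone reparameterization of the time axis.
    """

    values: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    sample_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("time course must be a 2-D channels x samples array")
        if not self.channel_labels:
            self.channel_labels = _default_labels(self.values.shape[0])
        if len(self.channel_labels) != self.values.shape[0]:
            raise DataError(
                f"{len(self.channel_labels)} labels for {self.values.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError("channel labels must be unique")
        if self.values.shape[1] < 2:
            raise DataError("time course needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise DataError("time course contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class LeadMatrix:
    """Antisymmetric channels x channels matrix of pairwise signed areas."""

    values: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise DataError("lead matrix must be square")
        if not self.channel_labels:
            self.channel_labels = _default_labels(n)
        if len(self.channel_labels) != n:
            raise DataError("label count does not match matrix size")
        scale = max(np.abs(self.values).max(), 1.0)
        if np.abs(self.values + self.values.T).max() > 1e-9 * scale:
            raise DataError("lead matrix must be antisymmetric")
        # enforce exact antisymmetry so downstream spectra see a clean input
        self.values = 0.5 * (self.values - self.values.T)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class SpectralSummary:
    """Eigen-structure of a lead matrix.

    ``eigen_magnitudes`` lists the μ of the conjugate eigenvalue pairs ±iμ in
    descending order.  Strengths/phases are moduli/arguments of the
    eigenvector belonging to +iμ of the leading (and second) pair.  When the
    leading magnitude is (numerically) zero the phases are undefined and
    ``defined`` is False.
    """

    channel_labels: list[str]
    eigen_magnitudes: np.ndarray
    leading_strengths: np.ndarray
    leading_phases: np.ndarray
    second_strengths: np.ndarray
    second_phases: np.ndarray
    defined: bool = True


def center_and_close(tc: TimeCourse) -> TimeCourse:
    """Close each channel with a linear ramp, then remove its mean.

    The returned channels have equal first and last samples (to floating
    tolerance) and zero mean, as required for the path-closure assumption of
    the lead matrix.  Idempotent.
    """
    x = tc.values
    n = tc.n_samples
    ramp = np.linspace(0.0, 1.0, n)
    closed = x - np.outer(x[:, -1] - x[:, 0], ramp)
    closed -= closed.mean(axis=1, keepdims=True)
    return TimeCourse(closed, list(tc.channel_labels), tc.sample_spacing)


def lead_matrix(tc: TimeCourse, *, normalize: bool = False, close: bool = True) -> LeadMatrix:
    """Pairwise signed areas of the closed path (the lead matrix).

    ``A[i, j] = 1/2 * sum_k (x_i(k) dx_j(k) - x_j(k) dx_i(k))`` over
    consecutive samples with wraparound — the shoelace signed area of each
    two-channel projection, exact for the piecewise-linear interpolant.

    Parameters
    ----------
    normalize
        If True, scale each channel to unit standard deviation after closing
        (useful when channel amplitudes are not comparable).  Off by default.
    close
        Apply :func:`center_and_close` first.  Disable only for inputs that
        are already closed.
    """
    if tc.n_samples < 3:
        raise DataError("need at least 3 samples to enclose area")
    if tc.n_channels < 2:
        raise DataError("need at least 2 channels for pairwise areas")
    work = center_and_close(tc) if close else tc
    x = work.values
    if normalize:
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
    dx = np.roll(x, -1, axis=1) - x
    m = x @ dx.T
    a = 0.5 * (m - m.T)
    return LeadMatrix(a, list(tc.channel_labels))


def _rotate_leading(vec: np.ndarray) -> np.ndarray:
    """Fix the global phase: largest-modulus component rotated to argument 0."""
    mod = np.abs(vec)
    k = int(np.argmax(mod))  # argmax = first occurrence, deterministic tie-break
    if mod[k] == 0:
        return vec
    return vec * np.exp(-1j * np.angle(vec[k]))


def spectral_decomposition(lm: LeadMatrix, *, tol: float = 1e-12) -> SpectralSummary:
    """Eigen-decomposition of the antisymmetric lead matrix.

    ``iA`` is Hermitian, so its eigenvalues are real and symmetric about 0;
    the pair magnitudes μ come out exactly paired.  The eigenvector reported
    for each pair is the one belonging to the eigenvalue ``+iμ`` of ``A``.
    """
    a = lm.values
    n = a.shape[0]
    evals, evecs = np.linalg.eigh(1j * a)  # ascending; A-eigenvalue is -i*lambda
    # +i*mu of A  <->  lambda = -mu (most negative end of the eigh spectrum)
    n_pairs = n // 2
    magnitudes = -evals[:n_pairs]  # descending mu >= 0
    magnitudes = np.clip(magnitudes, 0.0, None)
    scale = max(np.abs(a).max(), 1.0)
    defined = bool(len(magnitudes) > 0 and magnitudes[0] > tol * scale)

    def pair_vec(i: int) -> np.ndarray:
        if i >= n_pairs or magnitudes[i] <= tol * scale:
            return np.zeros(n, dtype=complex)
        return _rotate_leading(evecs[:, i])

    v1 = pair_vec(0)
    v2 = pair_vec(1)
    phases1 = np.where(np.abs(v1) > 0, np.angle(v1), np.nan)
    phases2 = np.where(np.abs(v2) > 0, np.angle(v2), np.nan)
    if not defined:
        phases1 = np.full(n, np.nan)
        phases2 = np.full(n, np.nan)
    return SpectralSummary(
        channel_labels=list(lm.channel_labels),
        eigen_magnitudes=magnitudes,
        leading_strengths=np.abs(v1),
        leading_phases=phases1,
        second_strengths=np.abs(v2),
        second_phases=phases2,
        defined=defined,
    )


class UndefinedPhaseError(ValueError):
    """Phases requested from a spectrally degenerate (zero) lead matrix."""


def recover_phase_offsets(ss: SpectralSummary, reference_channel: str) -> np.ndarray:
    """Per-channel phase offsets from the leading eigenvector, in [0, 2π).

    Rotated so the reference channel sits at 0.  The global *sign* remains
    undetermined: the analysis cannot tell the direction of the cycle, so a
    caller comparing against known phases must accept either orientation.
    """
    if not ss.defined:
        raise UndefinedPhaseError("leading eigenvalue is zero; phases undefined")
    try:
        ref = ss.channel_labels.index(reference_channel)
    except ValueError as exc:
        raise KeyError(f"unknown channel {reference_channel!r}") from exc
    offsets = ss.leading_phases - ss.leading_phases[ref]
    return np.mod(offsets, 2.0 * np.pi)


def circular_rmse(recovered: Sequence[float], truth: Sequence[float]) -> float:
    """Circular RMSE between phase sets, minimised over global rotation and sign.

    Both the rotation of the whole phase set and its reflection are gauge
    freedoms of the lead-matrix spectrum, so the error is reported after
    removing them.
    """
    rec = np.asarray(recovered, dtype=float)
    tru = np.asarray(truth, dtype=float)
    best = np.inf
    for signed in (rec, -rec):
        d = signed - tru
        # optimal global rotation = circular mean of the residuals
        rot = np.angle(np.mean(np.exp(1j * d)))
        resid = np.angle(np.exp(1j * (d - rot)))
        best = min(best, float(np.sqrt(np.mean(resid**2))))
    return best
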