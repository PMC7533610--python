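"""Truncated Fourier representation of pressure waveforms.

A signal u(t_m) sampled at n_t uniform points over a window (0, T) is
represented by real trigonometric coefficients [a_0..a_M, b_1..b_M] in the
convention

    u(t_m) = a_0/2 + sum_{j=1..M} [a_j cos(j w t_m) + b_j sin(j w t_m)],

with fundamental w = 2 pi / T.  At M = n_t/2 this is (samplewise) exact; the
default truncation M = 5 keeps 11 coefficients per signal, i.e. the lowest
5% of the modes of a 220-point window, discarding high-frequency content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

SIGNAL_ORDER = ("sap", "pap")
DEFAULT_M = 5


@dataclass(frozen=True)
class PressureSignal:
    """Uniformly sampled pressure trace over a window of length n_t * dt."""

    values: np.ndarray  # mmHg
    dt: float           # s

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("signal must be a 1-D array with n_t >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_t(self) -> int:
        return self.values.size

    @property
    def window(self) -> float:
        return self.n_t * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt


@dataclass(frozen=True)
class FourierFeatures:
    """c = [a_0..a_M, b_1..b_M] (mmHg) with fundamental omega = 2 pi / T."""

    coefficients: np.ndarray
    M: int
    omega: float  # rad/s

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", c)
        if c.size != 2 * self.M + 1:
            raise ValueError("coefficient vector must have length 2M+1")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite Fourier coefficient")

    @property
    def a(self) -> np.ndarray:
        return self.coefficients[: self.M + 1]

    @property
    def b(self) -> np.ndarray:
        return self.coefficients[self.M + 1:]


def dfft_coefficients(signal: PressureSignal, M: int = DEFAULT_M) -> FourierFeatures:
    """Real Fourier coefficients of the lowest M modes (via the FFT)."""
    n = signal.n_t
    if not 1 <= M <= n // 2:
        raise ValueError("require 1 <= M <= n_t/2")
    spec = np.fft.rfft(signal.values)
    a = 2.0 * spec.real[: M + 1] / n
    b = -2.0 * spec.imag[1: M + 1] / n
    if n % 2 == 0 and M == n // 2:
        a[-1] *= 0.5  # Nyquist mode carries half weight on an even grid
    omega = 2.0 * np.pi / signal.window
    return FourierFeatures(np.concatenate([a, b]), M, omega)


def reconstruct(f: FourierFeatures, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate the truncated series on a time grid."""
    t = np.asarray(t_grid, dtype=float)
    j = np.arange(1, f.M + 1)
    phase = np.outer(t, j) * f.omega
    return (f.a[0] / 2.0
            + np.cos(phase) @ f.a[1:]
            + np.sin(phase) @ f.b)


def resample_window(time: np.ndarray, values: np.ndarray, window: float,
                    n_t: int) -> PressureSignal:
    """Linearly resample the trailing ``window`` seconds onto n_t points.

    The resampled grid spans [t_end - window, t_end) half-open, so that the
    implied periodic extension has period ``window``.
    """
    t_end = time[-1]
    dt = window / n_t
    grid = t_end - window + dt * np.arange(n_t)
    return PressureSignal(np.interp(grid, time, values), dt)


def assemble_tensor(per_sample_features: list[tuple[FourierFeatures, FourierFeatures]]
                    ) -> xr.DataArray:
    """Stack per-sample (SAP, PAP) coefficient vectors into X[l, m, n].

    Axis order (sample, signal, coefficient), signal order fixed as
    ``SIGNAL_ORDER``.  Raises on ragged inputs (inconsistent M or omega).
    """
    if not per_sample_features:
        raise ValueError("no samples")
    m0 = per_sample_features[0][0].M
    om0 = per_sample_features[0][0].omega
    rows = []
    for pair in per_sample_features:
        if len(pair) != len(SIGNAL_ORDER):
            raise ValueError("each sample must supply exactly (SAP, PAP)")
        for f in pair:
            if f.M != m0 or not np.isclose(f.omega, om0):
                raise ValueError("ragged inputs: inconsistent truncation/grid")
        rows.append([f.coefficients for f in pair])
    x = np.asarray(rows)
    names = ([f"a{j}" for j in range(m0 + 1)] + [f"b{j}" for j in range(1, m0 + 1)])
    return xr.DataArray(
        x,
        dims=("sample", "signal", "coefficient"),
        coords={"signal": list(SIGNAL_ORDER), "coefficient": names},
        attrs={"M": m0, "omega": om0, "signal_order": ",".join(SIGNAL_ORDER)},
    )


def beat_aligned_window(out, window: float, n_t: int
                        ) -> tuple[PressureSignal, PressureSignal]:
    """Resample (SAP, PAP) onto n_t points starting at a beat onset.

    The window starts at the latest beat onset that leaves ``window`` seconds
    of signal, so every sample's feature window begins at the same cardiac
    phase.  Without this alignment the accumulated phase at the window start
    varies quasi-chaotically with the model parameters and scrambles the
    coefficients.
    """
    t_end = out.time[-1]
    onsets = out.time[out.beat_starts]
    eligible = onsets[onsets <= t_end - window]
    if eligible.size == 0:
        raise ValueError("no beat onset leaves a full feature window")
    t0 = eligible[-1]
    dt = window / n_t
    grid = t0 + dt * np.arange(n_t)
    return (PressureSignal(np.interp(grid, out.time, out.sap), dt),
            PressureSignal(np.interp(grid, out.time, out.pap), dt))


def featurize_simulation(out, window: float, n_t: int, M: int = DEFAULT_M
                         ) -> tuple[FourierFeatures, FourierFeatures]:
    """SAP and PAP features of one simulation (beat-onset-aligned window)."""
    sap, pap = beat_aligned_window(out, window, n_t)
    return dfft_coefficients(sap, M), dfft_coefficients(pap, M)


def align_to_onset(time: np.ndarray, values: np.ndarray, window: float,
                   n_t: int, min_period: float = 0.4) -> PressureSignal:
    """Beat-align a measured pressure trace by detecting its diastolic feet.

    The foot (local minimum preceding the systolic upstroke) is the most
    robust fiducial of an arterial waveform; the window starts at the latest
    foot that leaves ``window`` seconds of signal.
    """
    from scipy.signal import find_peaks

    time = np.asarray(time, float)
    values = np.asarray(values, float)
    dt_in = np.median(np.diff(time))
    feet, _ = find_peaks(-values, distance=max(int(min_period / dt_in), 1))
    t_feet = time[feet]
    eligible = t_feet[t_feet <= time[-1] - window]
    if eligible.size == 0:
        raise ValueError("no diastolic foot leaves a full feature window")
    t0 = eligible[-1]
    dt = window / n_t
    grid = t0 + dt * np.arange(n_t)
    return PressureSignal(np.interp(grid, time, values), dt)


def truncation_sweep(signal: PressureSignal, orders=range(2, 21)) -> dict[int, float]:
    """Relative L2 reconstruction error as a function of truncation order."""
    energy = float(np.linalg.norm(signal.values))
    out = {}
    for M in orders:
        f = dfft_coefficients(signal, M)
        err = signal.values - reconstruct(f, signal.time)
        out[int(M)] = float(np.linalg.norm(err) / energy)
    return out
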