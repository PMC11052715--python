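"""Transient signal processing: Hilbert envelopes, Gaussian fits,
penetration depth, depth/time conversion and time-gated spectra.

The envelope of a transient is the modulus of the analytic signal of the
mean-removed trace, so it tracks signal energy independent of the
oscillation phase of the band-limited transducer response.  The maximum
probed depth is read off a Gaussian fit to that envelope as the deep-side
1/e^2 point (center + 2 sigma relative to the surface arrival).  Gates
are half-open [start, end) windows in time or depth; a per-gate spectrum
collects the envelope peak within the gate at every wavenumber.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import hilbert

from .errors import FitError, GateOverlapError

__all__ = [
    "Transient",
    "Envelope",
    "Gate",
    "GaussianFit",
    "Spectrum",
    "hilbert_envelope",
    "fit_gaussian",
    "estimate_surface_time",
    "penetration_depth",
    "depth_to_time",
    "time_to_depth",
    "depth_time",
    "gated_peak",
    "spectrum_from_record",
    "record_envelopes",
]

# fraction of samples trimmed at each end before fitting, to avoid
# analytic-signal edge artifacts
_EDGE_FRACTION = 0.05


@dataclass(frozen=True)
class Transient:
    """One digitized pressure trace at one wavenumber."""

    samples: np.ndarray
    dt: float  # s
    t0: float = 0.0  # time of the first sample, s
    wavenumber: float | None = None  # cm^-1

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 16:
            raise ValueError("transient needs at least 16 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("transient contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)


@dataclass(frozen=True)
class Envelope:
    """Nonnegative amplitude envelope on the parent transient's time base."""

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("envelope values must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)


@dataclass(frozen=True)
class Gate:
    """Half-open window [start, end) in seconds or micrometres."""

    start: float
    end: float
    unit: str = "s"  # "s" or "um"

    def __post_init__(self):
        if self.unit not in ("s", "um"):
            raise ValueError(f"gate unit must be 's' or 'um', got {self.unit!r}")
        if not self.start < self.end:
            raise ValueError(f"gate start ({self.start}) must precede end ({self.end})")
        if self.unit == "um" and self.start < 0:
            raise ValueError("depth gates must start at >= 0 um")

    def in_time(self, c_m_s: float | None = None, surface_time_s: float = 0.0) -> "Gate":
        if self.unit == "s":
            return self
        if c_m_s is None:
            raise ValueError("speed of sound required to convert a depth gate to time")
        return Gate(
            start=depth_to_time(self.start, c_m_s, surface_time_s),
            end=depth_to_time(self.end, c_m_s, surface_time_s),
            unit="s",
        )


@dataclass(frozen=True)
class GaussianFit:
    """amplitude * exp(-(t-center)^2 / (2 sigma^2)) + baseline."""

    amplitude: float
    center: float
    sigma: float
    baseline: float
    rss: float
    converged: bool

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((t - self.center) / self.sigma) ** 2) + self.baseline


@dataclass(frozen=True)
class Spectrum:
    """Gated envelope-peak intensity per wavenumber at one timestamp."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    timestamp_min: float | None = None
    gate: Gate | None = None


def hilbert_envelope(t: Transient) -> Envelope:
    """Modulus of the analytic signal of the mean-removed trace."""
    x = t.samples - t.samples.mean()
    return Envelope(values=np.abs(hilbert(x)), dt=t.dt, t0=t.t0)


def record_envelopes(transients: np.ndarray) -> np.ndarray:
    """Vectorized envelope of a (n_traces, n_samples) stack."""
    x = transients - transients.mean(axis=-1, keepdims=True)
    return np.abs(hilbert(x, axis=-1))


def _gauss(t, a, c, s, b):
    return a * np.exp(-0.5 * ((t - c) / s) ** 2) + b


def fit_gaussian(env: Envelope, window: Gate | None = None) -> GaussianFit:
    """Bounded least-squares Gaussian fit to the envelope.

    The first/last 5% of samples are excluded to avoid analytic-signal
    edge artifacts.  On non-convergence the initial-guess parameters are
    returned with ``converged=False`` rather than raising.
    """
    times = env.times
    n = env.values.size
    trim = int(np.floor(n * _EDGE_FRACTION))
    mask = np.zeros(n, dtype=bool)
    mask[trim : n - trim] = True
    if window is not None:
        w = window.in_time() if window.unit == "s" else None
        if w is None:
            raise ValueError("fit window must be a time gate; convert depth gates first")
        mask &= (times >= w.start) & (times < w.end)
    if mask.sum() < 8:
        raise ValueError("fit window must contain at least 8 samples")
    t, v = times[mask], env.values[mask]

    a0 = float(v.max() - v.min())
    c0 = float(t[np.argmax(v)])
    b0 = float(np.median(v[: max(1, v.size // 10)]))
    half = v.min() + 0.5 * (v.max() - v.min())
    above = np.flatnonzero(v >= half)
    fwhm = (t[above[-1]] - t[above[0]]) if above.size >= 2 else (t[-1] - t[0]) / 4
    s0 = max(fwhm / 2.355, env.dt)
    p0 = (max(a0, 1e-30), c0, s0, b0)

    span = t[-1] - t[0]
    bounds = (
        [0.0, t[0] - span, env.dt / 10.0, -np.inf],
        [np.inf, t[-1] + span, 10.0 * span, np.inf],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss, t, v, p0=p0, bounds=bounds, maxfev=2000, xtol=1e-12, ftol=1e-12
            )
        converged = True
    except (RuntimeError, ValueError):
        popt, converged = p0, False
    rss = float(np.sum((v - _gauss(t, *popt)) ** 2))
    # a sigma pinned at a bound signals a degenerate (e.g. flat) input
    if converged and (popt[2] <= bounds[0][2] * 1.001 or popt[2] >= bounds[1][2] * 0.999):
        converged = False
    return GaussianFit(
        amplitude=float(popt[0]),
        center=float(popt[1]),
        sigma=float(popt[2]),
        baseline=float(popt[3]),
        rss=rss,
        converged=converged,
    )


def estimate_surface_time(env: Envelope, k: float = 5.0, noise_samples: int | None = None) -> float:
    """First time at which the envelope exceeds ``k`` x the pre-signal noise s.d.

    The noise floor is estimated from the leading samples (default: the
    first 5% of the trace).  This is the configurable fallback used when
    the instrument trigger-to-surface delay is unknown.
    """
    n = env.values.size
    m = noise_samples if noise_samples is not None else max(4, int(n * _EDGE_FRACTION))
    floor = float(np.std(env.values[:m]))
    thresh = k * floor if floor > 0 else np.finfo(float).tiny
    idx = np.flatnonzero(env.values > thresh)
    if idx.size == 0:
        raise FitError("no sample exceeds the surface-detection threshold")
    return float(env.times[idx[0]])


def penetration_depth(
    env: Envelope,
    surface_time: float,
    c_m_s: float,
    fit: GaussianFit | None = None,
) -> float:
    """1/e^2 penetration depth in micrometres.

    The fitted envelope falls to peak * e^-2 at center + 2 sigma; the
    depth is that time converted to distance past the surface arrival:
    ``c * (center + 2 sigma - surface_time)``.
    """
    if fit is None:
        fit = fit_gaussian(env)
    if not fit.converged:
        raise FitError("Gaussian fit did not converge; penetration depth undefined")
    depth_um = time_to_depth(fit.center + 2.0 * fit.sigma, c_m_s, surface_time)
    if depth_um < 0:
        raise ValueError(
            "negative penetration depth; surface_time is inconsistent with the fit"
        )
    return depth_um


def depth_to_time(z_um: float, c_m_s: float, surface_time_s: float = 0.0) -> float:
    """t = surface_time + z / c."""
    if not c_m_s > 0:
        raise ValueError("speed of sound must be > 0")
    return surface_time_s + (z_um * 1e-6) / c_m_s


def time_to_depth(t_s: float, c_m_s: float, surface_time_s: float = 0.0) -> float:
    """z (um) = c * (t - surface_time)."""
    if not c_m_s > 0:
        raise ValueError("speed of sound must be > 0")
    return (t_s - surface_time_s) * c_m_s * 1e6


def depth_time(x: float, direction: str, c_m_s: float, surface_time_s: float = 0.0) -> float:
    """Convert depth->time ('to_time') or time->depth ('to_depth')."""
    if direction == "to_time":
        return depth_to_time(x, c_m_s, surface_time_s)
    if direction == "to_depth":
        return time_to_depth(x, c_m_s, surface_time_s)
    raise ValueError("direction must be 'to_time' or 'to_depth'")


def _gate_mask(times: np.ndarray, gate: Gate, c_m_s=None, surface_time_s=0.0) -> np.ndarray:
    g = gate.in_time(c_m_s, surface_time_s)
    return (times >= g.start) & (times < g.end)


def gated_peak(
    env: Envelope,
    gate: Gate,
    c_m_s: float | None = None,
    surface_time_s: float = 0.0,
) -> float:
    """Maximum envelope value over samples with gate.start <= t < gate.end."""
    mask = _gate_mask(env.times, gate, c_m_s, surface_time_s)
    if mask.sum() < 2:
        raise GateOverlapError(
            f"gate [{gate.start}, {gate.end}) {gate.unit} overlaps the envelope "
            f"support [{env.times[0]:.3g}, {env.times[-1]:.3g}] s by "
            f"{int(mask.sum())} sample(s); at least 2 required"
        )
    return float(env.values[mask].max())


def spectrum_from_record(
    record,
    gate: Gate,
    envelopes: np.ndarray | None = None,
    expected_grid: np.ndarray | None = None,
) -> Spectrum:
    """One gated envelope peak per wavenumber, ordered by the grid.

    ``record`` is any object with ``wavenumbers``, ``transients``,
    ``dt_s``, ``t0_s``, ``surface_time_s``, ``speed_of_sound_m_s`` and
    ``timestamp_min`` attributes (e.g. a simulated SpectrumRecord).
    Precomputed ``envelopes`` may be passed to avoid repeated Hilbert
    transforms across gates.
    """
    wn = np.asarray(record.wavenumbers, dtype=float)
    if expected_grid is not None:
        missing = sorted(set(np.asarray(expected_grid, float)) - set(wn))
        if missing:
            raise ValueError(f"record is missing wavenumbers: {missing}")
    order = np.argsort(wn)
    if envelopes is None:
        envelopes = record_envelopes(np.asarray(record.transients, dtype=float))
    n_samples = envelopes.shape[-1]
    times = record.t0_s + record.dt_s * np.arange(n_samples)
    mask = _gate_mask(times, gate, record.speed_of_sound_m_s, record.surface_time_s)
    if mask.sum() < 2:
        raise GateOverlapError(
            f"gate [{gate.start}, {gate.end}) {gate.unit} overlaps the record's "
            f"time support by {int(mask.sum())} sample(s); at least 2 required"
        )
    intensities = envelopes[:, mask].max(axis=1)
    return Spectrum(
        wavenumbers=wn[order],
        intensities=intensities[order],
        timestamp_min=getattr(record, "timestamp_min", None),
        gate=gate,
    )
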