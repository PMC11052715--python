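"""Forward simulation of depth-resolved mid-IR optoacoustic experiments.

The forward model is deliberately one-dimensional: per wavenumber the
initial pressure follows Beer-Lambert attenuation through the layer
stack,

    p0(z) = Gamma * mu_a(z) * exp(-integral_0^z mu_a dz'),

is mapped to arrival time via the speed of sound, convolved with a
zero-phase Gaussian band-pass emulating the transducer (default -6 dB
edges at 6 and 36 MHz), and perturbed with additive white Gaussian noise
at a configurable fraction of the peak clean signal (default 1.4%,
reduced by sqrt(N) for N-pulse averaging).

`simulate_experiment` wraps this into a full glucose tolerance test:
spectra timestamps per the acquisition protocol at alternating
measurement locations (vascular P1 / avascular P2), glucose states
interpolated from the GTT curve, a slow bounded random walk on the
superficial water/lipid fractions (skin humidity / sebum drift), and a
noisy reference glucometer series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .bands import ChromophoreLibrary, default_library
from .errors import ResolutionError
from .gtt import GTTCurve, GTTParams, gtt_curve
from .skin import Layer, SkinModel, make_default_skin

__all__ = [
    "AcquisitionConfig",
    "LocationConfig",
    "ProtocolConfig",
    "SpectrumRecord",
    "ReferenceSeries",
    "SyntheticDataset",
    "absorption_profile",
    "simulate_transient",
    "simulate_experiment",
    "raster_positions",
    "GENERATOR_VERSION",
]

GENERATOR_VERSION = "1.0"

# minimum gate width the time base must resolve (two samples per 7.5 um)
_MIN_GATE_UM = 7.5


class AcquisitionConfig(BaseModel):
    """Digitizer and transducer settings."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    dt_s: float = Field(default=1e-9, gt=0)
    n_samples: int = Field(default=512, ge=16)
    band_low_hz: float = Field(default=6e6, gt=0)
    band_high_hz: float = Field(default=36e6, gt=0)
    noise_frac: float = Field(default=0.014, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if not self.band_high_hz > self.band_low_hz:
            raise ValueError("band_high_hz must exceed band_low_hz")
        return self


class LocationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    vascular: bool


class ProtocolConfig(BaseModel):
    """Acquisition protocol of one glucose tolerance test."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_baseline_spectra: int = Field(default=5, ge=1)
    baseline_window_min: float = Field(default=10.0, gt=0)
    n_post_spectra: int = Field(default=45, ge=1)
    post_window_min: float = Field(default=150.0, gt=0)
    wavenumber_low_cm1: float = 900.0
    wavenumber_high_cm1: float = 1300.0
    wavenumber_step_cm1: float = Field(default=4.0, gt=0)
    n_signal_averages: int = Field(default=1000, ge=1)
    spectrum_time_min: float = Field(default=1.5, gt=0)
    reference_interval_min: float = Field(default=3.0, gt=0)
    locations: list[LocationConfig] = Field(
        default_factory=lambda: [
            LocationConfig(name="P1", vascular=True),
            LocationConfig(name="P2", vascular=False),
        ]
    )

    @property
    def wavenumber_grid(self) -> np.ndarray:
        """Half-open grid [low, high) — exactly floor((high-low)/step) points."""
        return np.arange(
            self.wavenumber_low_cm1, self.wavenumber_high_cm1, self.wavenumber_step_cm1
        )

    @property
    def n_spectra_per_point(self) -> int:
        return self.n_baseline_spectra + self.n_post_spectra


@dataclass
class SpectrumRecord:
    """All averaged transients of one spectrum acquisition at one location."""

    location: str
    timestamp_min: float
    wavenumbers: np.ndarray  # (n_wn,)
    transients: np.ndarray  # (n_wn, n_samples)
    dt_s: float
    t0_s: float  # time of the first sample on the digitizer axis
    surface_time_s: float  # arrival time of the skin-surface signal
    speed_of_sound_m_s: float
    blood_mgdl: float  # generator truth, carried for validation
    isf_mgdl: float


@dataclass
class ReferenceSeries:
    """Glucometer reference time series."""

    times_min: np.ndarray
    glucose_mgdl: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("reference times must be strictly increasing")
        if len(self.times_min) != len(self.glucose_mgdl):
            raise ValueError("reference times/values length mismatch")


@dataclass
class SyntheticDataset:
    """One simulated glucose tolerance test at one or more locations."""

    records: dict[str, list[SpectrumRecord]]
    reference: ReferenceSeries
    gtt: GTTCurve
    provenance: dict = field(default_factory=dict)

    @property
    def locations(self) -> list[str]:
        return list(self.records)


def _amplitude_matrix(
    lib: ChromophoreLibrary, names: list[str], wavenumbers: np.ndarray
) -> np.ndarray:
    """(n_chrom, n_wn) absorption per unit concentration."""
    return np.stack([lib.absorption(n, wavenumbers) for n in names])


def absorption_profile(
    skin: SkinModel,
    lib: ChromophoreLibrary,
    wavenumber: float,
    glucose_state: dict,
    z_um: np.ndarray,
) -> np.ndarray:
    """Absorption coefficient mu_a(z) in cm^-1 on a depth grid (um).

    mu_a is the concentration-weighted sum of the library spectra over
    all chromophores present in the model, with the glucose concentration
    substituted per layer from ``glucose_state``.
    """
    if not lib.in_support(wavenumber):
        raise ValueError(
            f"wavenumber {wavenumber} cm^-1 outside library support {lib.support}"
        )
    names = skin.chromophore_names()
    amps = _amplitude_matrix(lib, names, np.asarray([float(wavenumber)]))[:, 0]
    z = np.asarray(z_um, dtype=float)
    mu = np.zeros_like(z)
    for name, a in zip(names, amps):
        mu += a * skin.concentration_profile(name, z, glucose_state)
    return mu


def _bandpass_gain(freqs_hz: np.ndarray, low: float, high: float) -> np.ndarray:
    """Zero-phase Gaussian band-pass with -6 dB (amplitude 0.5) edges."""
    f0 = 0.5 * (low + high)
    sigma = (f0 - low) / np.sqrt(2.0 * np.log(2.0))
    return np.exp(-0.5 * ((np.abs(freqs_hz) - f0) / sigma) ** 2)


def _initial_pressure(
    skin: SkinModel,
    lib: ChromophoreLibrary,
    wavenumbers: np.ndarray,
    glucose_state: dict,
    acq: AcquisitionConfig,
) -> np.ndarray:
    """(n_wn, n_samples) clean pressure traces before transducer filtering."""
    c_um_per_s = skin.speed_of_sound_m_s * 1e6
    dz_um = c_um_per_s * acq.dt_s
    i0 = int(round(skin.surface_offset_time_s / acq.dt_s))
    if i0 >= acq.n_samples:
        raise ValueError("surface offset lies beyond the acquisition window")
    n_z = acq.n_samples - i0
    z = np.arange(n_z) * dz_um

    names = skin.chromophore_names()
    if not names:
        return np.zeros((wavenumbers.size, acq.n_samples))
    amps = _amplitude_matrix(lib, names, wavenumbers)  # (n_chrom, n_wn)
    conc = np.stack(
        [skin.concentration_profile(n, z, glucose_state) for n in names]
    )  # (n_chrom, n_z)
    if skin.boundary_smoothing_um > 0:
        # spot-averaged layer undulation: blur profiles in depth; zero
        # padding lets the surface transition smear realistically
        from scipy.ndimage import gaussian_filter1d

        conc = gaussian_filter1d(
            conc, skin.boundary_smoothing_um / dz_um, axis=1, mode="constant", cval=0.0
        )
    mu = amps.T @ conc  # (n_wn, n_z), cm^-1

    dz_cm = dz_um * 1e-4
    # fluence at depth z uses the absorption accumulated above z
    tau = np.concatenate(
        [np.zeros((mu.shape[0], 1)), np.cumsum(0.5 * (mu[:, 1:] + mu[:, :-1]) * dz_cm, axis=1)],
        axis=1,
    )
    p0 = skin.gruneisen * mu * np.exp(-tau)
    out = np.zeros((mu.shape[0], acq.n_samples))
    out[:, i0:] = p0
    return out


def _filter_record(traces: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    freqs = np.fft.rfftfreq(acq.n_samples, acq.dt_s)
    gain = _bandpass_gain(freqs, acq.band_low_hz, acq.band_high_hz)
    return np.fft.irfft(np.fft.rfft(traces, axis=-1) * gain, n=acq.n_samples, axis=-1)


def _check_resolution(skin: SkinModel, acq: AcquisitionConfig):
    dz_um = skin.speed_of_sound_m_s * 1e6 * acq.dt_s
    if dz_um * 2 > _MIN_GATE_UM:
        raise ResolutionError(
            f"dt = {acq.dt_s} s gives a depth sample of {dz_um:.2f} um; a "
            f"{_MIN_GATE_UM} um gate must span at least 2 samples"
        )


def simulate_record(
    skin: SkinModel,
    lib: ChromophoreLibrary,
    wavenumbers: np.ndarray,
    glucose_state: dict,
    acq: AcquisitionConfig,
    noise_frac: float,
    rng: np.random.Generator,
    n_averages: int = 1,
    explicit_averaging: bool = False,
) -> np.ndarray:
    """Simulate the averaged transients of one spectrum, all wavenumbers at once.

    Noise is white Gaussian with s.d. ``noise_frac`` x the record's peak
    clean amplitude; N-pulse averaging is emulated by scaling the s.d. by
    1/sqrt(N) (or by drawing N pulses explicitly when requested).
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    _check_resolution(skin, acq)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    for wn in (wavenumbers.min(), wavenumbers.max()):
        if not lib.in_support(wn):
            raise ValueError(f"wavenumber {wn} cm^-1 outside library support {lib.support}")
    clean = _filter_record(
        _initial_pressure(skin, lib, wavenumbers, glucose_state, acq), acq
    )
    scale = np.max(np.abs(clean))
    if noise_frac == 0 or scale == 0:
        return clean
    sd = noise_frac * scale
    if explicit_averaging:
        noise = rng.normal(0.0, sd, size=(n_averages, *clean.shape)).mean(axis=0)
    else:
        noise = rng.normal(0.0, sd / np.sqrt(n_averages), size=clean.shape)
    return clean + noise


def simulate_transient(
    skin: SkinModel,
    lib: ChromophoreLibrary,
    wavenumber: float,
    glucose_state: dict,
    acq: AcquisitionConfig | None = None,
    noise_frac: float = 0.014,
    seed: int = 0,
    n_averages: int = 1,
    explicit_averaging: bool = False,
):
    """Simulate one averaged transient at a single wavenumber.

    Returns a :class:`glucogate.signals.Transient`; the identical seed
    yields a bit-identical trace.
    """
    from .signals import Transient  # local import to avoid a cycle

    acq = acq or AcquisitionConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    samples = simulate_record(
        skin,
        lib,
        np.asarray([float(wavenumber)]),
        glucose_state,
        acq,
        noise_frac,
        rng,
        n_averages=n_averages,
        explicit_averaging=explicit_averaging,
    )[0]
    return Transient(samples=samples, dt=acq.dt_s, t0=0.0, wavenumber=float(wavenumber))


def _avascular_variant(skin: SkinModel) -> SkinModel:
    """Replace blood-pool layers with the neighbouring dermis composition."""
    dermis = next(
        (la for la in skin.layers if la.glucose_pool == "isf"), None
    )
    layers = []
    for la in skin.layers:
        if la.glucose_pool == "blood":
            layers.append(
                Layer(
                    name=la.name,
                    z_top_um=la.z_top_um,
                    z_bottom_um=la.z_bottom_um,
                    chromophores=dict(dermis.chromophores) if dermis else dict(la.chromophores),
                    glucose_pool="isf",
                )
            )
        else:
            layers.append(la)
    return skin.model_copy(update={"layers": layers})


def _drift_walk(
    rng: np.random.Generator, n: int, amplitude: float, step_frac: float = 0.2
) -> np.ndarray:
    """Bounded random walk in [-amplitude, amplitude], starting at 0."""
    x = np.empty(n)
    cur = 0.0
    for k in range(n):
        x[k] = cur
        cur = float(np.clip(cur + rng.normal(0.0, amplitude * step_frac), -amplitude, amplitude))
    return x


def _drifted(skin: SkinModel, water_frac: float, lipid_frac: float) -> SkinModel:
    """Scale the top layer's water/lipid fractions by (1 + drift)."""
    top = skin.layers[0]
    chrom = dict(top.chromophores)
    if "water" in chrom:
        chrom["water"] = chrom["water"] * (1.0 + water_frac)
    if "lipid" in chrom:
        chrom["lipid"] = chrom["lipid"] * (1.0 + lipid_frac)
    layers = [top.model_copy(update={"chromophores": chrom})] + list(skin.layers[1:])
    return skin.model_copy(update={"layers": layers})


def simulate_experiment(
    skin: SkinModel | None = None,
    lib: ChromophoreLibrary | None = None,
    protocol: ProtocolConfig | None = None,
    gtt_params: GTTParams | None = None,
    acq: AcquisitionConfig | None = None,
    seed: int = 0,
    drift_amplitude: float = 0.10,
    reference_cv: float = 0.03,
) -> SyntheticDataset:
    """Simulate a full glucose tolerance test per the acquisition protocol.

    Spectra are acquired alternately at the configured locations
    (baseline spectra before injection, post spectra after), each built
    from pulse-averaged transients with the glucose state interpolated
    from the GTT curve at the spectrum timestamp.  The reference
    glucometer samples blood glucose at the configured interval with
    multiplicative noise.  The same (seed, config) pair regenerates the
    dataset bit-identically.
    """
    skin = skin or make_default_skin()
    lib = lib or default_library()
    protocol = protocol or ProtocolConfig()
    gtt_params = gtt_params or GTTParams()
    acq = acq or AcquisitionConfig()
    _check_resolution(skin, acq)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    wn = protocol.wavenumber_grid
    nb, npost = protocol.n_baseline_spectra, protocol.n_post_spectra
    n_loc = len(protocol.locations)
    max_offset = (n_loc - 1) * protocol.spectrum_time_min

    dense_t = np.arange(
        -protocol.baseline_window_min - 1.0,
        protocol.post_window_min + max_offset + 1.0,
        0.25,
    )
    curve = gtt_curve(gtt_params, dense_t)
    # ISF in avascular tissue lags behind blood far more (diffusion from
    # distant capillaries) than perivascular ISF
    curve_avascular = gtt_curve(
        gtt_params.model_copy(update={"isf_lag_min": gtt_params.isf_lag_avascular_min}),
        dense_t,
    )

    records: dict[str, list[SpectrumRecord]] = {}
    for j, loc in enumerate(protocol.locations):
        offset = j * protocol.spectrum_time_min
        t_base = -protocol.baseline_window_min + np.arange(nb) * (
            protocol.baseline_window_min / nb
        )
        t_post = np.arange(npost) * (protocol.post_window_min / npost)
        times = np.concatenate([t_base, t_post]) + offset

        loc_skin = skin if loc.vascular else _avascular_variant(skin)
        loc_curve = curve if loc.vascular else curve_avascular
        dw = _drift_walk(rng, times.size, drift_amplitude)
        dl = _drift_walk(rng, times.size, drift_amplitude)

        recs = []
        for k, t in enumerate(times):
            state = loc_curve.state_at(t)
            traces = simulate_record(
                _drifted(loc_skin, dw[k], dl[k]),
                lib,
                wn,
                state,
                acq,
                acq.noise_frac,
                rng,
                n_averages=protocol.n_signal_averages,
            )
            recs.append(
                SpectrumRecord(
                    location=loc.name,
                    timestamp_min=float(t),
                    wavenumbers=wn.copy(),
                    transients=traces,
                    dt_s=acq.dt_s,
                    t0_s=0.0,
                    surface_time_s=skin.surface_offset_time_s,
                    speed_of_sound_m_s=skin.speed_of_sound_m_s,
                    blood_mgdl=state["blood_mgdl"],
                    isf_mgdl=state["isf_mgdl"],
                )
            )
        records[loc.name] = recs

    # one glucometer draw per acquisition slot, taken while the sensor
    # moves between locations (nominal cadence: reference_interval_min)
    slot_times = np.concatenate(
        [
            -protocol.baseline_window_min
            + np.arange(nb) * (protocol.baseline_window_min / nb),
            np.arange(npost) * (protocol.post_window_min / npost),
        ]
    )
    ref_times = slot_times + protocol.spectrum_time_min
    ref_curve = gtt_curve(gtt_params, ref_times)
    ref_values = ref_curve.blood_mgdl * (
        1.0 + reference_cv * rng.standard_normal(ref_times.size)
    )

    provenance = {
        "seed": int(seed),
        "generator_version": GENERATOR_VERSION,
        "skin": skin.model_dump(),
        "protocol": protocol.model_dump(),
        "gtt_params": gtt_params.model_dump(),
        "acquisition": acq.model_dump(),
        "drift_amplitude": drift_amplitude,
        "reference_cv": reference_cv,
    }
    return SyntheticDataset(
        records=records,
        reference=ReferenceSeries(times_min=ref_times, glucose_mgdl=ref_values),
        gtt=curve,
        provenance=provenance,
    )


def raster_positions(nx: int, ny: int) -> list[tuple[int, int]]:
    """Row-major (x, y) grid positions: y is the row index, x varies fastest."""
    if nx < 1 or ny < 1:
        raise ValueError(f"grid dimensions must be >= 1, got ({nx}, {ny})")
    return [(x, y) for y in range(ny) for x in range(nx)]
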