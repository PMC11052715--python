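"""Chromophore absorption spectra in the mid-infrared fingerprint region.

Each chromophore is modelled as a sum of Gaussian bands plus an optional
slowly varying linear baseline, all expressed as absorption coefficient
(cm^-1) per unit concentration.  Solute concentrations are in mg dl^-1;
structural components (water, keratin, lipid) are volume fractions.

The default library places the glucose fingerprint bands at 994, 1036,
1080 and 1109 cm^-1 and the lactate bands at 1040 and 1125 cm^-1; water,
serum albumin, keratin and superficial lipid provide the background and
interference terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Band",
    "ChromophoreSpectrum",
    "ChromophoreLibrary",
    "default_library",
    "GLUCOSE_BAND_CENTERS",
    "LACTATE_BAND_CENTERS",
]

GLUCOSE_BAND_CENTERS = (994.0, 1036.0, 1080.0, 1109.0)
LACTATE_BAND_CENTERS = (1040.0, 1125.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    Parameters
    ----------
    center : float
        Band center in cm^-1.
    fwhm : float
        Full width at half maximum in cm^-1 (> 0).
    amplitude : float
        Peak absorption (cm^-1) contributed per unit concentration (>= 0).
    """

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self):
        if not self.fwhm > 0:
            raise ValueError(f"band fwhm must be > 0, got {self.fwhm}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")

    def __call__(self, wavenumber) -> np.ndarray:
        nu = np.asarray(wavenumber, dtype=float)
        sigma = self.fwhm * _FWHM_TO_SIGMA
        return self.amplitude * np.exp(-0.5 * ((nu - self.center) / sigma) ** 2)


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Absorption per unit concentration: Gaussian bands + linear baseline.

    The baseline is ``b0 + b1 * (nu - 1100) / 400`` so that ``b0`` is the
    mid-region value and ``b1`` the total drop/rise across a 400 cm^-1 span.
    """

    bands: tuple[Band, ...] = ()
    baseline: tuple[float, float] = (0.0, 0.0)

    def absorption(self, wavenumber) -> np.ndarray:
        nu = np.asarray(wavenumber, dtype=float)
        out = self.baseline[0] + self.baseline[1] * (nu - 1100.0) / 400.0
        out = np.broadcast_to(np.asarray(out, dtype=float), nu.shape).copy()
        for band in self.bands:
            out += band(nu)
        return np.maximum(out, 0.0)

    def band_centers(self) -> tuple[float, ...]:
        return tuple(b.center for b in self.bands)


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Named chromophore spectra with a common wavenumber support."""

    entries: dict[str, ChromophoreSpectrum] = field(default_factory=dict)
    support: tuple[float, float] = (880.0, 1320.0)

    def __post_init__(self):
        if "glucose" in self.entries:
            centers = set(self.entries["glucose"].band_centers())
            missing = [c for c in GLUCOSE_BAND_CENTERS if c not in centers]
            if missing:
                raise ValueError(f"glucose entry missing bands at {missing} cm^-1")
        if "lactate" in self.entries:
            centers = set(self.entries["lactate"].band_centers())
            missing = [c for c in LACTATE_BAND_CENTERS if c not in centers]
            if missing:
                raise ValueError(f"lactate entry missing bands at {missing} cm^-1")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> ChromophoreSpectrum:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(
                f"unknown chromophore {name!r}; known: {sorted(self.entries)}"
            ) from None

    def in_support(self, wavenumber: float) -> bool:
        return self.support[0] <= wavenumber <= self.support[1]

    def absorption(self, name: str, wavenumber) -> np.ndarray:
        return self[name].absorption(wavenumber)


def default_library() -> ChromophoreLibrary:
    """Default mid-IR fingerprint-region library (900-1300 cm^-1).

    Magnitudes are stylized: water dominates the background at a level
    that yields an effective penetration of order 150 um, glucose adds a
    percent-level perturbation at physiological concentration, and the
    keratin/lipid bands of the superficial skin overlap the 1080/1109
    glucose bands far more than the 994 band.
    """
    return ChromophoreLibrary(
        entries={
            # per volume fraction; broad, slowly varying in this region
            "water": ChromophoreSpectrum(baseline=(100.0, -8.0)),
            # per mg/dl
            "glucose": ChromophoreSpectrum(
                bands=(
                    Band(994.0, 25.0, 0.020),
                    Band(1036.0, 25.0, 0.018),
                    Band(1080.0, 25.0, 0.020),
                    Band(1109.0, 25.0, 0.012),
                )
            ),
            # per mg/dl; physiological 6-12 mg/dl, so a minor contributor
            "lactate": ChromophoreSpectrum(
                bands=(Band(1040.0, 25.0, 0.020), Band(1125.0, 25.0, 0.016))
            ),
            # per mg/dl; serum protein: featureless sloping background
            "albumin": ChromophoreSpectrum(baseline=(2.0e-5, 5.0e-6)),
            # per volume fraction; amide III / C-O features of the epidermis
            "keratin": ChromophoreSpectrum(
                bands=(Band(1078.0, 40.0, 20.0), Band(1240.0, 50.0, 16.0)),
                baseline=(7.5, 1.0),
            ),
            # per volume fraction; superficial sebum/lipid esters
            "lipid": ChromophoreSpectrum(
                bands=(Band(1165.0, 30.0, 15.0), Band(1100.0, 30.0, 7.5)),
                baseline=(2.5, 0.0),
            ),
        }
    )
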