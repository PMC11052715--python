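"""Evaluation of glucose predictions against reference values.

Implements the Parkes consensus error grid (PCEG) for type-1 diabetes —
zones A (clinically accurate) through E (dangerous) over the 0-550 mg/dl
domain — plus RMSE, Pearson correlation, difference spectra, and the
area-under-curve / single-peak linearity analyses used to examine how
directly the gated spectra track glucose.

The grid geometry is a versioned JSON asset of published boundary
vertices; zone membership uses polygon containment, testing zones in
increasing risk order so that points exactly on a boundary are assigned
the lower-risk zone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .errors import GridDomainError

__all__ = [
    "PCEGGeometry",
    "PCEGReport",
    "LinearityResult",
    "load_geometry",
    "parkes_zone",
    "pceg_report",
    "pearson",
    "rmse",
    "difference_spectra",
    "auc_linearity",
    "peak_linearity",
]

ZONE_ORDER = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class PCEGGeometry:
    """Zone polygons of one error-grid variant, lowest risk first."""

    name: str
    diabetes_type: int
    domain: tuple[float, float]
    source: str
    polygons: tuple[tuple[str, Polygon], ...]

    def zones_present(self) -> list[str]:
        present = {label for label, _ in self.polygons}
        return [z for z in ZONE_ORDER if z in present]


_GEOMETRY_CACHE: dict[str, PCEGGeometry] = {}


def load_geometry(variant: str = "parkes-t1") -> PCEGGeometry:
    """Load an embedded error-grid geometry by name.

    Only the type-1 Parkes grid ships with the package; other variants
    are a documented extension point.
    """
    if variant in _GEOMETRY_CACHE:
        return _GEOMETRY_CACHE[variant]
    if variant != "parkes-t1":
        raise NotImplementedError(
            f"error-grid variant {variant!r} is not bundled; available: ['parkes-t1']"
        )
    raw = json.loads(
        resources.files("glucogate.data").joinpath("parkes_t1.json").read_text()
    )
    polys = []
    for key, coords in raw["zones"].items():
        label = key.split("_")[0]
        polys.append((label, Polygon(coords)))
    polys.sort(key=lambda kv: ZONE_ORDER.index(kv[0]))
    geom = PCEGGeometry(
        name=raw["name"],
        diabetes_type=raw["diabetes_type"],
        domain=tuple(raw["domain"]),
        source=raw["source"],
        polygons=tuple(polys),
    )
    _GEOMETRY_CACHE[variant] = geom
    return geom


def _zone_labels(refs: np.ndarray, preds: np.ndarray, geometry: PCEGGeometry) -> np.ndarray:
    lo, hi = geometry.domain
    bad = (refs < lo) | (refs > hi) | (preds < lo) | (preds > hi)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise GridDomainError(
            f"point (ref={refs[i]}, pred={preds[i]}) outside the grid domain "
            f"[{lo}, {hi}] mg/dl"
        )
    pts = shapely.points(refs, preds)
    labels = np.full(refs.shape, "", dtype="<U1")
    remaining = np.ones(refs.shape, dtype=bool)
    for label, poly in geometry.polygons:
        if not remaining.any():
            break
        hit = remaining & shapely.covers(poly, pts)
        labels[hit] = label
        remaining &= ~hit
    if remaining.any():
        i = int(np.flatnonzero(remaining)[0])
        raise GridDomainError(
            f"point (ref={refs[i]}, pred={preds[i]}) not covered by any zone polygon"
        )
    return labels


def parkes_zone(ref: float, pred: float, geometry: PCEGGeometry | None = None) -> str:
    """Zone label A-E of one (reference, predicted) pair in mg/dl.

    Boundary points go to the lower-risk zone.
    """
    geometry = geometry or load_geometry()
    return str(_zone_labels(np.asarray([ref], float), np.asarray([pred], float), geometry)[0])


@dataclass(frozen=True)
class PCEGReport:
    """Zone tabulation and error summary of a prediction series."""

    labels: np.ndarray
    counts: dict[str, int]
    percentages: dict[str, float]
    rmse_mgdl: float
    n: int
    geometry_name: str

    def summary(self) -> str:
        lines = [f"Parkes error grid ({self.geometry_name}), n = {self.n}"]
        for z in ZONE_ORDER:
            if z in self.counts:
                lines.append(f"  zone {z}: {self.counts[z]:4d}  ({self.percentages[z]:6.2f}%)")
        lines.append(f"  RMSE: {self.rmse_mgdl:.2f} mg/dl")
        return "\n".join(lines)


def rmse(refs, preds) -> float:
    refs = np.asarray(refs, float)
    preds = np.asarray(preds, float)
    if refs.shape != preds.shape:
        raise ValueError("reference/prediction length mismatch")
    return float(np.sqrt(np.mean((preds - refs) ** 2)))


def pceg_report(refs, preds, geometry: PCEGGeometry | None = None) -> PCEGReport:
    """Per-point zones, per-zone counts/percentages, and RMSE."""
    geometry = geometry or load_geometry()
    refs = np.asarray(refs, float)
    preds = np.asarray(preds, float)
    if refs.shape != preds.shape or refs.size < 1:
        raise ValueError("need equal-length, non-empty reference and prediction arrays")
    labels = _zone_labels(refs, preds, geometry)
    counts = {z: int(np.sum(labels == z)) for z in geometry.zones_present()}
    n = refs.size
    percentages = {z: 100.0 * c / n for z, c in counts.items()}
    return PCEGReport(
        labels=labels,
        counts=counts,
        percentages=percentages,
        rmse_mgdl=rmse(refs, preds),
        n=n,
        geometry_name=geometry.name,
    )


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("pearson needs two equal-length arrays with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def difference_spectra(spectra: np.ndarray, baseline_spectrum: np.ndarray,
                       wavenumbers: np.ndarray | None = None,
                       baseline_wavenumbers: np.ndarray | None = None) -> np.ndarray:
    """Per-timepoint difference spectra relative to one baseline spectrum."""
    S = np.atleast_2d(np.asarray(spectra, float))
    b = np.asarray(baseline_spectrum, float)
    if wavenumbers is not None and baseline_wavenumbers is not None:
        if not np.array_equal(np.asarray(wavenumbers), np.asarray(baseline_wavenumbers)):
            raise ValueError("wavenumber grids of spectra and baseline differ")
    if S.shape[1] != b.shape[0]:
        raise ValueError("baseline spectrum length does not match the spectra")
    return S - b


@dataclass(frozen=True)
class LinearityResult:
    """Per-spectrum statistic regressed against reference glucose."""

    statistic: np.ndarray
    refs: np.ndarray
    pearson_r: float
    slope: float
    intercept: float
    label: str = ""

    @property
    def r(self) -> float:
        return self.pearson_r


def _linearity(stat: np.ndarray, refs: np.ndarray, label: str) -> LinearityResult:
    res = stats.linregress(refs, stat)
    return LinearityResult(
        statistic=stat,
        refs=refs,
        pearson_r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        label=label,
    )


def auc_linearity(delta_spectra: np.ndarray, wavenumbers: np.ndarray, refs) -> LinearityResult:
    """Trapezoidal area of each difference spectrum versus reference glucose."""
    D = np.atleast_2d(np.asarray(delta_spectra, float))
    refs = np.asarray(refs, float)
    if D.shape[0] < 3:
        raise ValueError("area-under-curve linearity needs at least 3 timepoints")
    if refs.shape[0] != D.shape[0]:
        raise ValueError("reference length does not match the number of spectra")
    aucs = np.trapezoid(D, np.asarray(wavenumbers, float), axis=1)
    return _linearity(aucs, refs, "auc")


def peak_linearity(
    spectra: np.ndarray, wavenumbers: np.ndarray, refs, peaks_cm1
) -> dict[float, LinearityResult]:
    """Single-peak intensity versus reference glucose, per requested peak.

    Each requested peak is mapped to the nearest grid point (within one
    grid step; equidistant requests map to the lower wavenumber); the
    mapped grid value is recorded in the result label.
    """
    S = np.atleast_2d(np.asarray(spectra, float))
    wn = np.asarray(wavenumbers, float)
    refs = np.asarray(refs, float)
    step = float(np.median(np.diff(np.sort(wn))))
    out: dict[float, LinearityResult] = {}
    for peak in peaks_cm1:
        d = np.abs(wn - peak)
        j = int(np.flatnonzero(d == d.min())[0])  # first (lower) on ties
        if d[j] > step:
            raise ValueError(
                f"requested peak {peak} cm^-1 is more than one grid step from the grid"
            )
        out[float(peak)] = _linearity(S[:, j], refs, label=f"peak@{wn[j]:g}")
    return out
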