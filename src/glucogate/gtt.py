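"""Glucose-tolerance-test dynamics: blood bolus response and ISF lag.

Blood glucose follows a baseline plus a Bateman (double-exponential)
bolus response scaled by the administered dose.  Interstitial-fluid (ISF)
glucose follows blood through a first-order exchange

    dG_i/dt = (G_b(t) - G_i(t)) / tau_lag,   G_i(0) = baseline,

and is then multiplied by a dilution factor in (0, 1], so the ISF curve
is delayed and attenuated relative to blood — the reason an avascular
measurement location tracks the glucometer less faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["GTTParams", "GTTCurve", "gtt_curve"]


class GTTParams(BaseModel):
    """Parameters of the glucose-tolerance-test curve (times in minutes)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    baseline_mgdl: float = Field(default=100.0, gt=0)
    dose_g_kg: float = Field(default=2.0, ge=0)
    # peak blood excursion above baseline per unit dose (mg/dl per g/kg)
    dose_gain_mgdl_per_g_kg: float = Field(default=60.0, ge=0)
    tau_rise_min: float = Field(default=15.0, gt=0)
    tau_decay_min: float = Field(default=60.0, gt=0)
    # perivascular ISF (well-vascularized tissue) equilibrates quickly;
    # ISF in capillary-poor tissue lags behind blood by diffusion from
    # distant vessels, hence the much longer avascular time constant
    isf_lag_min: float = Field(default=8.0, gt=0)
    isf_lag_avascular_min: float = Field(default=25.0, gt=0)
    isf_dilution: float = Field(default=0.8, gt=0, le=1.0)

    @model_validator(mode="after")
    def _check(self):
        if not self.tau_decay_min > self.tau_rise_min:
            raise ValueError("tau_decay_min must exceed tau_rise_min")
        for name, v in self.model_dump().items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite GTT parameter {name}")
        return self


@dataclass(frozen=True)
class GTTCurve:
    """Blood and ISF glucose (mg/dl) on a time grid (min since injection)."""

    times_min: np.ndarray
    blood_mgdl: np.ndarray
    isf_mgdl: np.ndarray
    params: GTTParams

    def state_at(self, t_min: float) -> dict:
        """Glucose state interpolated at one timestamp."""
        return {
            "blood_mgdl": float(np.interp(t_min, self.times_min, self.blood_mgdl)),
            "isf_mgdl": float(np.interp(t_min, self.times_min, self.isf_mgdl)),
        }


def _bateman_shape(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Double-exponential bolus shape normalized to unit peak; 0 for t <= 0."""
    s = np.where(t > 0, np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return s / peak


def blood_curve(params: GTTParams, times_min: np.ndarray) -> np.ndarray:
    t = np.asarray(times_min, dtype=float)
    excursion = params.dose_g_kg * params.dose_gain_mgdl_per_g_kg
    return params.baseline_mgdl + excursion * _bateman_shape(
        t, params.tau_rise_min, params.tau_decay_min
    )


def gtt_curve(params: GTTParams, times_min) -> GTTCurve:
    """Evaluate blood and ISF glucose on a sorted time grid.

    The ISF ODE is integrated with an exact exponential step assuming
    blood glucose piecewise linear on an internal fine grid, which is
    stable for any ratio of lag to step size (including the lag -> 0
    limit, where ISF tends to dilution * blood pointwise).
    """
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("time grid must be a non-empty 1-D array")
    if np.any(np.diff(t) < 0):
        raise ValueError("time grid must be sorted")
    blood = blood_curve(params, t)

    t_end = max(t[-1], 0.0)
    h = min(params.isf_lag_min, params.tau_rise_min) / 20.0
    h = float(np.clip(h, 1e-3, 0.25))
    n_fine = int(np.ceil(t_end / h)) + 1
    tf = np.linspace(0.0, t_end, max(n_fine, 2))
    bf = blood_curve(params, tf)
    lag = params.isf_lag_min
    g = np.empty_like(tf)
    g[0] = params.baseline_mgdl
    decay = np.exp(-np.diff(tf) / lag)
    for k in range(tf.size - 1):
        hk = tf[k + 1] - tf[k]
        slope = (bf[k + 1] - bf[k]) / hk
        g[k + 1] = (
            bf[k + 1]
            - slope * lag * (1.0 - decay[k])
            + (g[k] - bf[k]) * decay[k]
        )
    # times <= 0: ISF in equilibrium with the constant baseline
    isf_undiluted = np.where(t <= 0, params.baseline_mgdl, np.interp(t, tf, g))
    isf = params.isf_dilution * isf_undiluted
    return GTTCurve(times_min=t, blood_mgdl=blood, isf_mgdl=isf, params=params)
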