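"""Layered skin model for the one-dimensional optoacoustic forward problem.

The model is a stack of contiguous plane-parallel layers, each carrying a
chromophore composition.  Glucose is handled specially: a layer declares
which glucose pool it samples ("blood" for the capillary layer, "isf" for
dermal interstitial fluid, "none" for the glucose-poor superficial
layers), and the actual concentration is substituted at simulation time
from the glucose-tolerance-test state.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["Layer", "SkinModel", "make_default_skin"]


class Layer(BaseModel):
    """One plane-parallel tissue layer, depths in micrometres from the surface."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    z_top_um: float = Field(ge=0)
    z_bottom_um: float
    # chromophore name -> concentration (mg/dl for solutes, volume fraction
    # for water/keratin/lipid)
    chromophores: dict[str, float] = Field(default_factory=dict)
    glucose_pool: Literal["blood", "isf", "none"] = "none"

    @model_validator(mode="after")
    def _check(self):
        if not self.z_bottom_um > self.z_top_um:
            raise ValueError(
                f"layer {self.name!r}: z_bottom_um ({self.z_bottom_um}) must exceed "
                f"z_top_um ({self.z_top_um})"
            )
        for k, v in self.chromophores.items():
            if v < 0:
                raise ValueError(f"layer {self.name!r}: concentration of {k!r} is negative")
        return self

    @property
    def thickness_um(self) -> float:
        return self.z_bottom_um - self.z_top_um


class SkinModel(BaseModel):
    """Contiguous layer stack plus acoustic constants.

    ``surface_offset_time_s`` is the arrival time of the skin-surface
    signal on the digitizer time axis (acoustic transit from surface to
    transducer relative to the trigger).

    ``boundary_smoothing_um`` models the lateral undulation of skin
    layers (rete ridges, uneven stratum corneum) averaged over the
    excitation spot: concentration profiles are blurred in depth with a
    Gaussian kernel of this sigma (default 18 um), so layer transitions are gradual
    rather than ideal planes.  Set to 0 for sharp slab boundaries.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    layers: list[Layer]
    speed_of_sound_m_s: float = 1500.0
    gruneisen: float = 0.2
    surface_offset_time_s: float = 50e-9
    boundary_smoothing_um: float = 18.0

    @model_validator(mode="after")
    def _check(self):
        if not self.layers:
            raise ValueError("skin model needs at least one layer")
        if not self.speed_of_sound_m_s > 0:
            raise ValueError("speed_of_sound_m_s must be > 0")
        if self.boundary_smoothing_um < 0:
            raise ValueError("boundary_smoothing_um must be >= 0")
        if self.layers[0].z_top_um != 0:
            raise ValueError("first layer must start at the surface (z_top_um = 0)")
        for a, b in zip(self.layers, self.layers[1:]):
            if not np.isclose(a.z_bottom_um, b.z_top_um):
                raise ValueError(
                    f"layers {a.name!r} and {b.name!r} are not contiguous: "
                    f"{a.z_bottom_um} != {b.z_top_um}"
                )
        return self

    @property
    def total_depth_um(self) -> float:
        return self.layers[-1].z_bottom_um

    def concentration_profile(
        self, name: str, z_um: np.ndarray, glucose_state: dict | None = None
    ) -> np.ndarray:
        """Concentration of one chromophore on a depth grid.

        ``glucose_state`` is a mapping with keys ``blood_mgdl`` and
        ``isf_mgdl``; it is required when ``name == 'glucose'`` and any
        layer declares a glucose pool.
        """
        z = np.asarray(z_um, dtype=float)
        out = np.zeros_like(z)
        for layer in self.layers:
            mask = (z >= layer.z_top_um) & (z < layer.z_bottom_um)
            if name == "glucose" and layer.glucose_pool != "none":
                if glucose_state is None:
                    raise ValueError("glucose_state required for glucose profile")
                key = "blood_mgdl" if layer.glucose_pool == "blood" else "isf_mgdl"
                out[mask] = float(glucose_state[key])
            else:
                out[mask] = layer.chromophores.get(name, 0.0)
        return out

    def chromophore_names(self) -> list[str]:
        names: set[str] = set()
        for layer in self.layers:
            names.update(layer.chromophores)
            if layer.glucose_pool != "none":
                names.add("glucose")
        return sorted(names)


# default layer compositions (volume fractions / mg/dl); see docs/methods.md
_EPIDERMIS = {"water": 0.22, "keratin": 0.55, "lipid": 0.15}
_DERMIS = {"water": 0.65, "albumin": 2500.0, "lactate": 9.0}
_CAPILLARY = {"water": 0.90, "albumin": 4000.0, "lactate": 9.0}


def make_default_skin(
    capillary_depth_um: float = 97.5,
    capillary_thickness_um: float = 15.0,
    epidermis_thickness_um: float = 20.0,
    total_depth_um: float = 300.0,
    vascular: bool = True,
    **acoustics,
) -> SkinModel:
    """Stratum corneum/epidermis + dermis + capillary layer stack.

    The capillary layer is centred at ``capillary_depth_um`` and spans
    ``capillary_depth_um +/- capillary_thickness_um / 2``; it carries the
    blood-glucose pool, while the dermis bulk carries the interstitial
    (ISF) pool.  With ``vascular=False`` the capillary layer keeps the
    dermis composition and ISF pool, emulating an avascular location.
    """
    if not capillary_depth_um > 0:
        raise ValueError("capillary_depth_um must be > 0")
    if not capillary_thickness_um > 0:
        raise ValueError("capillary_thickness_um must be > 0")
    cap_top = capillary_depth_um - capillary_thickness_um / 2.0
    cap_bottom = capillary_depth_um + capillary_thickness_um / 2.0
    if cap_top <= epidermis_thickness_um:
        raise ValueError(
            "capillary layer overlaps the epidermis: "
            f"top at {cap_top} um vs epidermis down to {epidermis_thickness_um} um"
        )
    if cap_bottom >= total_depth_um:
        raise ValueError("capillary layer extends beyond the model depth")
    cap_comp = _CAPILLARY if vascular else _DERMIS
    cap_pool = "blood" if vascular else "isf"
    layers = [
        Layer(
            name="epidermis",
            z_top_um=0.0,
            z_bottom_um=epidermis_thickness_um,
            chromophores=dict(_EPIDERMIS),
            glucose_pool="none",
        ),
        Layer(
            name="dermis_upper",
            z_top_um=epidermis_thickness_um,
            z_bottom_um=cap_top,
            chromophores=dict(_DERMIS),
            glucose_pool="isf",
        ),
        Layer(
            name="capillary",
            z_top_um=cap_top,
            z_bottom_um=cap_bottom,
            chromophores=dict(cap_comp),
            glucose_pool=cap_pool,
        ),
        Layer(
            name="dermis_lower",
            z_top_um=cap_bottom,
            z_bottom_um=total_depth_um,
            chromophores=dict(_DERMIS),
            glucose_pool="isf",
        ),
    ]
    return SkinModel(layers=layers, **acoustics)
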