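"""Run configuration and on-disk dataset layout.

A dataset directory holds one delimited numeric table per spectrum
acquisition (columns: ``time_s`` plus one pressure column per
wavenumber) and a single ``meta.json`` sidecar with the schema version,
provenance (seed, generator version, skin and protocol configs), the
reference glucometer series and per-record metadata.  Values are written
with full double precision so a write/read round trip is lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import DatasetFormatError
from .gtt import GTTParams, gtt_curve
from .simulate import (
    AcquisitionConfig,
    ProtocolConfig,
    ReferenceSeries,
    SpectrumRecord,
    SyntheticDataset,
)
from .skin import SkinModel, make_default_skin

__all__ = [
    "ChemoOptions",
    "GatingOptions",
    "EvalOptions",
    "RunConfig",
    "write_dataset",
    "read_dataset",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.1"
_LEGACY_VERSIONS = ("1.0",)


class ChemoOptions(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    max_lv: int = Field(default=10, ge=1)
    autoscale: bool = False
    alignment_tolerance_min: float = Field(default=1.5, gt=0)
    interpolate_reference: bool = False


class GatingOptions(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    window_um: float = Field(default=7.5, gt=0)
    step_um: float = Field(default=7.5, gt=0)
    range_mode: Literal["auto", "fixed"] = "auto"
    depth_range_um: float | None = None
    gap_frac: float = Field(default=0.05, ge=0)


class EvalOptions(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    grid_variant: str = "parkes-t1"


class RunConfig(BaseModel):
    """Fully serializable configuration of one end-to-end run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    skin: SkinModel = Field(default_factory=make_default_skin)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    gtt: GTTParams = Field(default_factory=GTTParams)
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    chemo: ChemoOptions = Field(default_factory=ChemoOptions)
    gating: GatingOptions = Field(default_factory=GatingOptions)
    evaluation: EvalOptions = Field(default_factory=EvalOptions)
    drift_amplitude: float = Field(default=0.10, ge=0)
    reference_cv: float = Field(default=0.03, ge=0)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path=None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode("utf8")
        return hashlib.sha256(payload).hexdigest()[:16]


def _record_filename(location: str, index: int) -> str:
    return f"{location}_{index:03d}.csv"


def write_dataset(ds: SyntheticDataset, path) -> Path:
    """Write a dataset directory (meta.json + one CSV per record)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "schema_version": SCHEMA_VERSION,
        "provenance": ds.provenance,
        "reference": {
            "times_min": ds.reference.times_min.tolist(),
            "glucose_mgdl": ds.reference.glucose_mgdl.tolist(),
        },
        "records": {},
    }
    for loc, recs in ds.records.items():
        entries = []
        for k, rec in enumerate(recs):
            fname = _record_filename(loc, k)
            times = rec.t0_s + rec.dt_s * np.arange(rec.transients.shape[1])
            cols = ["time_s"] + [f"wn_{w:g}" for w in rec.wavenumbers]
            table = np.column_stack([times, rec.transients.T])
            np.savetxt(
                path / fname,
                table,
                delimiter=",",
                header=",".join(cols),
                comments="",
                fmt="%.17g",
            )
            entries.append(
                {
                    "file": fname,
                    "timestamp_min": rec.timestamp_min,
                    "dt_s": rec.dt_s,
                    "t0_s": rec.t0_s,
                    "surface_time_s": rec.surface_time_s,
                    "speed_of_sound_m_s": rec.speed_of_sound_m_s,
                    "blood_mgdl": rec.blood_mgdl,
                    "isf_mgdl": rec.isf_mgdl,
                    "n_samples": int(rec.transients.shape[1]),
                }
            )
        meta["records"][loc] = entries
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _upgrade_legacy(meta: dict, logger=None) -> dict:
    """Adapt an older sidecar schema in place; logs an upgrade note."""
    version = meta.get("schema_version")
    if version == "1.0":
        # 1.0 stored the glucometer series under 'reference_series' with
        # short field names
        rs = meta.pop("reference_series", None)
        if rs is None:
            raise DatasetFormatError("legacy 1.0 sidecar missing 'reference_series'")
        meta["reference"] = {"times_min": rs["t_min"], "glucose_mgdl": rs["values"]}
        meta["schema_version"] = SCHEMA_VERSION
        if logger is not None:
            logger.info("upgraded dataset sidecar from schema 1.0 to %s", SCHEMA_VERSION)
    return meta


def read_dataset(path, logger=None) -> SyntheticDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Older schema versions with an adapter are upgraded on the fly (with
    a logged note); unknown versions raise a helpful error.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise DatasetFormatError(f"missing sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as err:
        raise DatasetFormatError(f"corrupt sidecar {meta_path}: {err}") from err
    version = meta.get("schema_version")
    if version in _LEGACY_VERSIONS:
        meta = _upgrade_legacy(meta, logger)
    elif version != SCHEMA_VERSION:
        raise DatasetFormatError(
            f"unknown dataset schema version {version!r}; this package reads "
            f"{SCHEMA_VERSION} (and upgrades {list(_LEGACY_VERSIONS)})"
        )
    for section in ("provenance", "reference", "records"):
        if section not in meta:
            raise DatasetFormatError(f"sidecar {meta_path} missing section {section!r}")

    records: dict[str, list[SpectrumRecord]] = {}
    for loc, entries in meta["records"].items():
        recs = []
        for entry in entries:
            fpath = path / entry["file"]
            if not fpath.exists():
                raise DatasetFormatError(f"missing record table {fpath}")
            try:
                df = pd.read_csv(fpath, float_precision="round_trip")
            except Exception as err:
                raise DatasetFormatError(f"corrupt record table {fpath}: {err}") from err
            if len(df) != entry["n_samples"]:
                raise DatasetFormatError(
                    f"truncated record table {fpath}: expected {entry['n_samples']} "
                    f"rows, found {len(df)} (first bad row: {len(df) + 1})"
                )
            wn_cols = [c for c in df.columns if c.startswith("wn_")]
            wavenumbers = np.asarray([float(c[3:]) for c in wn_cols])
            recs.append(
                SpectrumRecord(
                    location=loc,
                    timestamp_min=entry["timestamp_min"],
                    wavenumbers=wavenumbers,
                    transients=df[wn_cols].to_numpy().T.copy(),
                    dt_s=entry["dt_s"],
                    t0_s=entry["t0_s"],
                    surface_time_s=entry["surface_time_s"],
                    speed_of_sound_m_s=entry["speed_of_sound_m_s"],
                    blood_mgdl=entry["blood_mgdl"],
                    isf_mgdl=entry["isf_mgdl"],
                )
            )
        records[loc] = recs

    reference = ReferenceSeries(
        times_min=np.asarray(meta["reference"]["times_min"], float),
        glucose_mgdl=np.asarray(meta["reference"]["glucose_mgdl"], float),
    )
    prov = meta["provenance"]
    gtt = None
    if "gtt_params" in prov and "protocol" in prov:
        params = GTTParams.model_validate(prov["gtt_params"])
        protocol = ProtocolConfig.model_validate(prov["protocol"])
        n_loc = len(protocol.locations)
        dense_t = np.arange(
            -protocol.baseline_window_min - 1.0,
            protocol.post_window_min + (n_loc - 1) * protocol.spectrum_time_min + 1.0,
            0.25,
        )
        gtt = gtt_curve(params, dense_t)
    return SyntheticDataset(records=records, reference=reference, gtt=gtt, provenance=prov)
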