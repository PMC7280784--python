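"""Plain-text readers and writers for shapes, flows, profiles and traces.

All file interfaces are diffable text formats: TSV for shapes
(``s_um, x_um, y_um``), profiles (``position_um, intensity[, channel]``) and
traces (``time_s, intensity``); JSON for uniform flow fields and fit
results; CSV for bending series and event tables.  Round trips are stable
to float precision.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import BendingSeries
from .intensity import IntensityProfile, IntensityTrace
from .mechanics import FilamentShape, FlowField, GridFlow, UniformFlow

__all__ = [
    "FormatError",
    "read_shape_tsv",
    "write_shape_tsv",
    "read_flow",
    "write_flow_json",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_trace_tsv",
    "write_trace_tsv",
    "read_bending_series_csv",
    "RunConfig",
]

_FLOAT_FMT = "%.9g"


class FormatError(ValueError):
    """Raised for malformed input files; carries the offending line if known."""


def read_shape_tsv(path, rtol: float = 1e-6) -> FilamentShape:
    """Read one filament shape from a TSV with columns s_um, x_um, y_um.

    Non-uniform arc spacing is resampled to a uniform grid with a warning;
    a non-monotone s column is a format error.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"s_um", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) < 3:
        raise FormatError(f"{path}: need at least 3 rows")
    s = df["s_um"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(s) <= 0)[0]
    if bad.size:
        raise FormatError(
            f"{path}: s_um not strictly increasing at data line {bad[0] + 2}"
        )
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    ds = np.diff(s)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    uniform = np.allclose(ds, ds[0], rtol=1e-6) and np.allclose(
        seg, seg[0], rtol=rtol
    )
    if uniform:
        return FilamentShape(pts, float(seg.mean()), rtol=max(rtol, 1e-5))
    warnings.warn(
        f"{path}: non-uniform arc spacing; resampling to uniform grid",
        RuntimeWarning,
    )
    return FilamentShape.from_points_resampled(pts, n_points=len(df))


def write_shape_tsv(path, shape: FilamentShape) -> None:
    df = pd.DataFrame(
        {
            "s_um": shape.arc_lengths,
            "x_um": shape.points[:, 0],
            "y_um": shape.points[:, 1],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_flow(path) -> FlowField:
    """Read a flow field: JSON for uniform flow, TSV grid otherwise.

    Uniform: ``{"vx": ..., "vy": ...}``.  Grid TSV columns:
    x_um, y_um, vx, vy on a full rectangular grid.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        try:
            return UniformFlow(float(data["vx"]), float(data["vy"]))
        except KeyError as exc:
            raise FormatError(f"{path}: uniform flow needs key {exc}")
    df = pd.read_csv(path, sep="\t")
    missing = {"x_um", "y_um", "vx", "vy"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    x = np.unique(df["x_um"])
    y = np.unique(df["y_um"])
    if len(df) != x.size * y.size:
        raise FormatError(f"{path}: flow grid is not a full rectangle")
    piv_x = df.pivot(index="x_um", columns="y_um", values="vx")
    piv_y = df.pivot(index="x_um", columns="y_um", values="vy")
    return GridFlow(x, y, piv_x.to_numpy(), piv_y.to_numpy())


def write_flow_json(path, flow: UniformFlow) -> None:
    Path(path).write_text(json.dumps({"vx": flow.vx, "vy": flow.vy}))


def read_profile_tsv(path) -> IntensityProfile:
    df = pd.read_csv(path, sep="\t")
    missing = {"position_um", "intensity"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    channel = ""
    if "channel" in df.columns and len(df):
        channel = str(df["channel"].iloc[0])
    return IntensityProfile(
        df["position_um"].to_numpy(dtype=float),
        df["intensity"].to_numpy(dtype=float),
        channel=channel,
    )


def write_profile_tsv(path, profile: IntensityProfile) -> None:
    df = pd.DataFrame(
        {"position_um": profile.positions, "intensity": profile.intensities}
    )
    if profile.channel:
        df["channel"] = profile.channel
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_trace_tsv(path, t_damage: float) -> IntensityTrace:
    df = pd.read_csv(path, sep="\t")
    missing = {"time_s", "intensity"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return IntensityTrace(
        df["time_s"].to_numpy(dtype=float),
        df["intensity"].to_numpy(dtype=float),
        t_damage=t_damage,
    )


def write_trace_tsv(path, trace: IntensityTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "intensity": trace.intensities}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_bending_series_csv(path, temperature: float = 308.15) -> list:
    """Read per-cycle replicate persistence lengths for several filaments.

    Columns: filament_id, cycle, replicate, and either lp_um or
    kappa_pnum2 (converted via Lp = kappa / (k_B T)).
    """
    from .inference import persistence_length

    df = pd.read_csv(path)
    need = {"filament_id", "cycle", "replicate"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "lp_um" in df.columns:
        df["_lp"] = df["lp_um"].astype(float)
    elif "kappa_pnum2" in df.columns:
        df["_lp"] = [
            persistence_length(k, temperature)
            for k in df["kappa_pnum2"].astype(float)
        ]
    else:
        raise FormatError(f"{path}: need an lp_um or kappa_pnum2 column")
    out = []
    for fid, grp in df.groupby("filament_id", sort=True):
        cycles = []
        for _, cgrp in sorted(grp.groupby("cycle"), key=lambda kv: kv[0]):
            cycles.append(list(cgrp["_lp"]))
        out.append(BendingSeries(filament_id=str(fid), cycles=cycles))
    return out


@dataclass
class RunConfig:
    """Configuration of a reproducible pipeline run.

    Unknown keys in a YAML config are rejected; the effective configuration
    and its hash are echoed into the output directory of every run.
    """

    seed: int = 0
    out_dir: str = "mtrepair_run"
    log_level: str = "INFO"
    # synthetic-stage parameters
    n_filaments: int = 3
    cycles: int = 6
    replicates: int = 3
    kappa0: float = 50.0
    kappa_decline: float = 0.9
    length_um: float = 10.0
    n_nodes: int = 41
    flow_vx: float = 0.0
    flow_vy: float = 100.0
    mu: float = 1e-3
    g: float = 1.0
    temperature: float = 308.15
    pixel_size: float = 0.063
    noise_sigma_px: float = 1.0
    # analysis parameters
    fit_origin: bool = True
    alpha: float = 0.05
    bend_threshold_deg: float = 10.0
    drop_threshold: float = 0.1
    gap_threshold: float = 0.5
    min_gap_length_um: float = 1.0
    n_tip_profiles: int = 10
    tip_noise_sd: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
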