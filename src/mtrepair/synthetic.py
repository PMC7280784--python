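"""Seeded synthetic-data generators with machine-readable ground truth.

Every input the analysis pipeline consumes can be generated here with known
truth, emulating the corresponding experiment:

* flow-bent filament shapes over repeated bending cycles, with a per-cycle
  rigidity schedule (softening), Gaussian digitization noise and a random
  seed-origin offset;
* erfc-shaped microtubule tip intensity profiles;
* damage-site intensity time traces (flat pre-damage level, instantaneous
  drop at the damage frame, linear recovery to a plateau);
* dual-channel lattice profiles: a red (original lattice) profile with
  intensity wells at defect gaps and a green (fresh tubulin) profile filled
  per gap-specific pattern (full fill, edges only, or an interior hole).

All generators are deterministic functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intensity import IntensityProfile, IntensityTrace, TipFit, erfc_tip_model
from .mechanics import (
    FilamentShape,
    FlowField,
    MechanicalParams,
    UniformFlow,
    equilibrium_shape,
)

__all__ = [
    "SyntheticConfig",
    "ShapeRecord",
    "BentShapeSet",
    "GapSpec",
    "generate_bent_shapes",
    "generate_tip_profiles",
    "generate_damage_trace",
    "generate_lattice_pair",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the bent-shape generator.

    The defaults emulate the bending-cycle protocol: filaments of ~10 um
    bent by an orthogonal flow, six 10 s flow-on / 10 s flow-off cycles,
    five replicate shape measurements per cycle, and a 10% per-cycle
    rigidity decline for softening filaments.  Coordinate noise defaults to
    one camera pixel (0.063 um) per axis; the seed-origin error is uniform
    within +-1 pixel.
    """

    seed: int = 0
    n_filaments: int = 5
    cycles: int = 6
    replicates: int = 5
    kappa0: float = 50.0
    kappa_decline: float = 0.9
    kappa_schedule: tuple | None = None
    length_um: float = 10.0
    n_nodes: int = 61
    flow: FlowField = field(default_factory=lambda: UniformFlow(0.0, 100.0))
    mu: float = 1e-3
    g: float = 1.0
    temperature: float = 308.15
    pixel_size: float = 0.063
    noise_sigma_px: float = 1.0
    origin_error_px: float = 1.0
    kappa0_scatter: float = 0.1

    def __post_init__(self):
        if self.kappa_schedule is not None:
            if any(k <= 0 for k in self.kappa_schedule):
                raise ValueError("kappa_schedule values must be positive")
        if self.kappa0 <= 0 or self.kappa_decline <= 0:
            raise ValueError("rigidity schedule must be positive")

    def schedule(self, kappa0: float) -> np.ndarray:
        """Per-cycle kappa values for a filament with first-cycle kappa0."""
        if self.kappa_schedule is not None:
            return np.asarray(self.kappa_schedule, dtype=float)
        return kappa0 * self.kappa_decline ** np.arange(self.cycles)


@dataclass(frozen=True)
class ShapeRecord:
    """One synthetic measured shape with its generation truth."""

    filament_id: str
    cycle: int
    replicate: int
    kappa_true: float
    origin_offset: np.ndarray
    points: np.ndarray  # raw noisy coordinates (um)
    shape: FilamentShape  # resampled, fit-ready


@dataclass(frozen=True)
class BentShapeSet:
    """Generated shape records plus the ground-truth table."""

    records: list
    truth: pd.DataFrame
    config: SyntheticConfig


def generate_bent_shapes(config: SyntheticConfig) -> BentShapeSet:
    """Equilibrium bent shapes over cycles with known per-cycle rigidity.

    For each filament and cycle the forward elastica model is solved at the
    scheduled kappa; each replicate adds fresh Gaussian coordinate noise
    (``noise_sigma_px * pixel_size`` per axis) and the filament's fixed
    origin offset.  Raw noisy points and a smoothing-spline-resampled,
    fit-ready :class:`FilamentShape` are both returned.
    """
    rng = np.random.default_rng(config.seed)
    sigma = config.noise_sigma_px * config.pixel_size
    smoothing = 2.0 * config.n_nodes * sigma**2 if sigma > 0 else 0.0
    records = []
    rows = []
    for fi in range(config.n_filaments):
        fid = f"mt{fi:03d}"
        k0 = config.kappa0 * float(
            np.exp(rng.normal(0.0, config.kappa0_scatter))
        )
        offset = rng.uniform(
            -config.origin_error_px, config.origin_error_px, size=2
        ) * config.pixel_size
        theta_prev = None
        for ci, kappa in enumerate(config.schedule(k0)):
            params = MechanicalParams(
                kappa=kappa,
                mu=config.mu,
                g=config.g,
                temperature=config.temperature,
            )
            try:
                sol = equilibrium_shape(
                    params,
                    config.length_um,
                    config.flow,
                    n_nodes=config.n_nodes,
                    theta_init=theta_prev,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"forward solve failed for {fid} cycle {ci + 1}: {exc}"
                )
            theta_prev = sol.tangent_angles
            clean = sol.shape.points
            for ri in range(config.replicates):
                noisy = clean + offset + rng.normal(0.0, sigma, clean.shape)
                if sigma > 0:
                    shape = FilamentShape.from_points_resampled(
                        noisy, n_points=config.n_nodes, smoothing=smoothing
                    )
                else:
                    shape = sol.shape
                records.append(
                    ShapeRecord(
                        filament_id=fid,
                        cycle=ci + 1,
                        replicate=ri + 1,
                        kappa_true=float(kappa),
                        origin_offset=offset,
                        points=noisy,
                        shape=shape,
                    )
                )
                rows.append(
                    {
                        "filament_id": fid,
                        "cycle": ci + 1,
                        "replicate": ri + 1,
                        "kappa_true": float(kappa),
                        "origin_dx_um": float(offset[0]),
                        "origin_dy_um": float(offset[1]),
                    }
                )
    return BentShapeSet(records, pd.DataFrame(rows), config)


def generate_tip_profiles(
    n: int,
    seed: int = 0,
    x_span: tuple = (0.0, 10.0),
    step: float = 0.065,
    i_mt_range: tuple = (80.0, 120.0),
    i_bg_range: tuple = (5.0, 15.0),
    x_pf_range: tuple = (4.0, 6.0),
    sigma_range: tuple = (0.2, 0.4),
    noise_sd: float = 5.0,
) -> list:
    """erfc tip profiles with additive Gaussian noise and truth parameters.

    Returns a list of ``(IntensityProfile, TipFit)`` pairs, the second
    element holding the generating parameters.  A warning is raised if the
    sampling step is coarser than the smallest tip width.
    """
    if step > min(sigma_range):
        import warnings

        warnings.warn(
            "sampling step exceeds the tip width; the fit may be degenerate",
            RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    x = np.arange(x_span[0], x_span[1] + 0.5 * step, step)
    out = []
    for _ in range(n):
        i_mt = rng.uniform(*i_mt_range)
        i_bg = rng.uniform(*i_bg_range)
        x_pf = rng.uniform(*x_pf_range)
        sig = rng.uniform(*sigma_range)
        y = erfc_tip_model(x, i_mt, i_bg, x_pf, sig)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, y.shape)
        prof = IntensityProfile(x, y, channel="rh-tubulin", pixel_size=step)
        out.append((prof, TipFit(i_mt, i_bg, x_pf, sig)))
    return out


def generate_damage_trace(
    pre_level: float = 200.0,
    drop_to: float = 50.0,
    rate: float = 220.0 / 45.0,
    plateau: float = 270.0,
    noise_sd: float | None = None,
    t_damage: float = 30.0,
    dt: float = 1.0,
    t_total: float = 150.0,
    seed: int = 0,
) -> tuple:
    """Damage-site intensity trace: drop at t_damage, linear recovery, plateau.

    Returns ``(IntensityTrace, truth)`` where truth records the raw
    recovery rate (a.u./s), the rate and fold change on the
    normalized-to-post-damage scale, and the plateau level.  Noise defaults
    to 5% of the recovery dynamic range.
    """
    if pre_level <= 0 or drop_to <= 0 or plateau <= 0:
        raise ValueError("intensity levels must be positive")
    if drop_to >= plateau:
        raise ValueError("drop_to must lie below the recovery plateau")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_total + 0.5 * dt, dt)
    y = np.where(t < t_damage, pre_level, 0.0)
    rise = drop_to + rate * (t - t_damage)
    y = np.where(t >= t_damage, np.minimum(rise, plateau), y)
    if noise_sd is None:
        noise_sd = 0.05 * (plateau - drop_to)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    trace = IntensityTrace(t, y, t_damage=t_damage)
    truth = {
        "rate_au_per_s": rate,
        "normalized_rate_per_s": rate / drop_to,
        "fold_change": plateau / drop_to,
        "plateau": plateau,
        "t_saturation": t_damage + (plateau - drop_to) / rate,
    }
    return trace, truth


@dataclass(frozen=True)
class GapSpec:
    """One lattice defect: position, extent and green fill pattern.

    ``pattern`` is one of ``full`` (continuous green fill -> complete
    repair), ``edges`` (green only at the gap borders -> partial),
    ``hole`` (green everywhere except an interior hole -> partial) or
    ``none`` (no incorporation).
    """

    start_um: float
    length_um: float
    pattern: str = "full"
    edge_width_um: float = 0.3

    def __post_init__(self):
        if self.length_um <= 0:
            raise ValueError("gap length must be positive")
        if self.pattern not in ("full", "edges", "hole", "none"):
            raise ValueError(f"unknown fill pattern {self.pattern!r}")

    @property
    def end_um(self) -> float:
        return self.start_um + self.length_um


def generate_lattice_pair(
    length_um: float = 20.0,
    gaps: list | None = None,
    step: float = 0.063,
    red_level: float = 100.0,
    red_gap_level: float = 20.0,
    green_level: float = 80.0,
    green_bg: float = 5.0,
    noise_sd: float = 0.0,
    min_length_um: float = 1.0,
    seed: int = 0,
) -> tuple:
    """Red/green lattice profile pair with known defect truth.

    The red channel is the original (eroded) lattice with wells at the
    specified gaps; the green channel is fresh tubulin filled in per gap
    pattern.  Returns ``(red, green, truth)`` where truth is a DataFrame of
    all gaps with their expected detection (given the minimum-length rule)
    and complete/partial label.
    """
    gaps = list(gaps) if gaps is not None else []
    gaps.sort(key=lambda g: g.start_um)
    for a, b in zip(gaps, gaps[1:]):
        if a.end_um > b.start_um:
            raise ValueError("gap specs overlap")
    for gsp in gaps:
        if gsp.start_um < 0 or gsp.end_um > length_um:
            raise ValueError("gaps must lie inside the filament")
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, length_um, step)
    red = np.full_like(x, red_level)
    green = np.full_like(x, green_bg)
    rows = []
    for gsp in gaps:
        inside = (x >= gsp.start_um) & (x < gsp.end_um)
        red[inside] = red_gap_level
        if gsp.pattern == "full":
            green[inside] = green_level
        elif gsp.pattern == "edges":
            edge = inside & (
                (x < gsp.start_um + gsp.edge_width_um)
                | (x >= gsp.end_um - gsp.edge_width_um)
            )
            green[edge] = green_level
        elif gsp.pattern == "hole":
            mid = 0.5 * (gsp.start_um + gsp.end_um)
            hole = inside & (np.abs(x - mid) < 0.5 * gsp.edge_width_um)
            green[inside & ~hole] = green_level
        expected = gsp.length_um >= min_length_um and gsp.pattern != "none"
        rows.append(
            {
                "start_um": gsp.start_um,
                "end_um": gsp.end_um,
                "length_um": gsp.length_um,
                "pattern": gsp.pattern,
                "expected_detected": expected,
                "expected_label": (
                    "complete" if gsp.pattern == "full" else "partial"
                )
                if expected
                else "",
            }
        )
    if noise_sd > 0:
        red = red + rng.normal(0.0, noise_sd, red.shape)
        green = green + rng.normal(0.0, noise_sd, green.shape)
    red_prof = IntensityProfile(x, red, channel="rhodamine", pixel_size=step)
    green_prof = IntensityProfile(x, green, channel="hilyte488",
                                  pixel_size=step)
    return red_prof, green_prof, pd.DataFrame(rows)
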