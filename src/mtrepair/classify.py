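"""Event-level classification of laser-damage and lattice-repair outcomes.

Implements the deterministic decision rules used to score microtubule
damage experiments:

* damage outcomes at an irradiated lattice site — (I) bending at the site,
  (II) local reduction of tubulin intensity, (III) severing, recognized by
  the direct appearance of two new microtubule ends, with precedence
  III > I > II;
* the fate of a bent (outcome I) site — breakage vs straightening;
* the fate of a freshly severed plus end — immediate regrowth at the
  ablation site, depolymerization all the way to the seed, or
  depolymerization followed by a rescue along the lattice;
* detection of tubulin-incorporation sites on eroded Taxol lattices from a
  red (original lattice) / green (fresh tubulin) profile pair, with the
  1 um minimum-defect-length rule and the complete/partial repair labels.

Angles are degrees, positions um; intervals along the filament axis are
half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intensity import IntensityProfile
from .mechanics import FilamentShape

__all__ = [
    "DamageEvent",
    "IncorporationSite",
    "SeveringFate",
    "IncorporationSummary",
    "bend_angle",
    "classify_damage_outcome",
    "classify_outcome1_fate",
    "classify_severing_fate",
    "detect_incorporation_sites",
]

#: Bend angle above which a damage site counts as outcome I (degrees).
DEFAULT_BEND_THRESHOLD_DEG = 10.0
#: Minimum fractional intensity drop for outcome II.
DEFAULT_DROP_THRESHOLD = 0.1


@dataclass
class DamageEvent:
    """One laser-damage event and its measured post-damage features."""

    filament_id: str
    t_damage: float
    bend_angle: float
    end_count_delta: int
    intensity_drop_fraction: float
    outcome: str | None = None
    fate: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.bend_angle <= 180.0:
            raise ValueError("bend_angle must be in [0, 180] degrees")
        if self.end_count_delta not in (0, 2):
            raise ValueError("end_count_delta must be 0 or 2")
        if not 0.0 <= self.intensity_drop_fraction <= 1.0:
            raise ValueError("intensity_drop_fraction must be in [0, 1]")


@dataclass(frozen=True)
class IncorporationSite:
    """A detected lattice gap with fresh-tubulin incorporation."""

    start_um: float
    end_um: float
    label: str  # "complete" | "partial"

    def __post_init__(self):
        if not self.end_um > self.start_um:
            raise ValueError("end_um must exceed start_um")
        if self.label not in ("complete", "partial"):
            raise ValueError("label must be 'complete' or 'partial'")

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


@dataclass(frozen=True)
class SeveringFate:
    """Fate of a freshly severed plus end plus its depolymerization length."""

    label: str
    depolymerization_length: float


@dataclass(frozen=True)
class IncorporationSummary:
    """Detected sites with per-filament frequency and mean length."""

    sites: list
    frequency_per_um: float
    mean_length_um: float


def bend_angle(
    shape: FilamentShape, site_index: int, flank: int = 5
) -> float:
    """Bend angle (degrees) at a node, from mean flank tangents.

    The angle between the average unit tangent of up to ``flank`` segments
    proximal to the site and of up to ``flank`` segments distal to it;
    collinear flanks give 0, a right-angle kink 90.
    """
    n = shape.n_points
    if site_index < 2 or site_index > n - 3:
        raise ValueError("site too close to a filament end for a bend angle")
    pts = shape.points
    seg = np.diff(pts, axis=0)
    seg = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    lo = max(site_index - flank, 0)
    hi = min(site_index + flank, n - 1)
    prox = seg[lo:site_index].mean(axis=0)
    dist = seg[site_index:hi].mean(axis=0)
    prox = prox / np.linalg.norm(prox)
    dist = dist / np.linalg.norm(dist)
    cosang = float(np.clip(np.dot(prox, dist), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def classify_damage_outcome(
    event: DamageEvent,
    bend_threshold_deg: float = DEFAULT_BEND_THRESHOLD_DEG,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
) -> str:
    """Assign outcome I, II or III to a damage event (precedence III > I > II).

    III: two new ends appeared at the site (severing), regardless of angle.
    I:   the filament bent by more than ``bend_threshold_deg`` at the site.
    II:  the tubulin intensity dropped by more than ``drop_threshold``.
    Otherwise the event is labelled "no-event".
    """
    if event.end_count_delta == 2:
        outcome = "III"
    elif event.bend_angle > bend_threshold_deg:
        outcome = "I"
    elif event.intensity_drop_fraction > drop_threshold:
        outcome = "II"
    else:
        outcome = "no-event"
    event.outcome = outcome
    return outcome


def classify_outcome1_fate(
    angle_series: np.ndarray,
    break_signal: np.ndarray,
    bend_threshold_deg: float = DEFAULT_BEND_THRESHOLD_DEG,
) -> str:
    """Fate of a bent damage site: breakage, straightening, or unresolved.

    ``angle_series`` are bend angles (degrees) over time after the damage
    event; ``break_signal`` counts new ends at the site per frame.  Any
    appearance of two ends means breakage; otherwise the site straightened
    if the angle ever returned below the bend threshold.  A series ending
    still bent with no break is unresolved.
    """
    angles = np.asarray(angle_series, dtype=float)
    breaks = np.asarray(break_signal)
    if angles.size == 0 or breaks.size != angles.size:
        raise ValueError("angle and break series must be non-empty, same size")
    if np.any(breaks >= 2):
        return "breakage"
    if np.any(angles < bend_threshold_deg):
        return "straightening"
    return "unresolved"


def classify_severing_fate(
    tip_trajectory: np.ndarray,
    seed_interval: tuple,
    rescue_events: np.ndarray | None = None,
    regrowth_tolerance_um: float = 0.2,
) -> SeveringFate:
    """Fate of a freshly severed plus end from its position trajectory.

    ``tip_trajectory`` is the position of the new plus end along the
    filament axis over time (um, seed-ward decreasing), starting at the
    ablation site.  The fate is

    * ``depol_to_seed`` if the end ever enters the seed interval;
    * ``regrowth_at_site`` if it never shrank more than the tolerance below
      the site and shows net growth;
    * ``rescue_on_lattice`` if it shrank beyond the tolerance and then
      resumed growth before reaching the seed;
    * ``unresolved`` otherwise (monotone shrinkage that the recording did
      not follow to the seed).

    The depolymerization length is the site position minus the minimum
    position reached (0 for immediate regrowth).
    """
    pos = np.asarray(tip_trajectory, dtype=float)
    if pos.size == 0:
        raise ValueError("empty tip trajectory")
    site = pos[0]
    lo, hi = seed_interval
    depol = float(max(site - pos.min(), 0.0))
    if np.any((pos >= lo) & (pos <= hi)):
        return SeveringFate("depol_to_seed", depol)
    if depol <= regrowth_tolerance_um and pos[-1] >= site - regrowth_tolerance_um:
        return SeveringFate("regrowth_at_site", depol)
    imin = int(np.argmin(pos))
    regrew = imin < pos.size - 1 and pos[imin + 1:].max() > pos[imin]
    if rescue_events is not None and np.asarray(rescue_events).size > 0:
        regrew = True
    if regrew:
        return SeveringFate("rescue_on_lattice", depol)
    return SeveringFate("unresolved", depol)


def _gap_runs(mask: np.ndarray):
    """Maximal runs of True in a boolean mask, as (start, stop) index pairs
    with stop exclusive."""
    runs = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_incorporation_sites(
    red: IntensityProfile,
    green: IntensityProfile,
    gap_threshold: float = 0.5,
    min_length_um: float = 1.0,
    green_threshold: float | None = None,
    green_noise_factor: float = 3.0,
) -> IncorporationSummary:
    """Detect lattice gaps in the red channel repaired by green tubulin.

    Gaps are maximal runs where the red (original lattice) intensity falls
    below ``gap_threshold`` times the red median outside gaps (found by
    fixed-point iteration starting from the global median).  A gap counts
    as an incorporation site only if it is at least ``min_length_um`` long
    and green signal is present at both its edges.  The site is labelled
    ``complete`` when the green signal exceeds its threshold at every sample
    inside the gap, ``partial`` otherwise.

    ``green_threshold`` defaults to (green background median) +
    ``green_noise_factor`` * (background SD), estimated outside the gaps.
    Frequency is kept sites per um of filament length.
    """
    if red.positions.shape != green.positions.shape or not np.allclose(
        red.positions, green.positions
    ):
        raise ValueError("red and green profiles must share the same grid")
    if not 0.0 < gap_threshold < 1.0:
        raise ValueError("gap_threshold must be in (0, 1)")
    pos = red.positions
    step = red.step
    r = red.intensities
    gap_mask = np.zeros(r.size, dtype=bool)
    for _ in range(10):
        ref = float(np.median(r[~gap_mask])) if (~gap_mask).any() else float(
            np.median(r)
        )
        new_mask = r < gap_threshold * ref
        if np.array_equal(new_mask, gap_mask):
            break
        gap_mask = new_mask

    g = green.intensities
    if green_threshold is None:
        bg = g[~gap_mask]
        if bg.size == 0:
            raise ValueError("cannot estimate green background: all gap")
        bg_med = float(np.median(bg))
        # noise floor (3 sigma by default) or, for effectively noiseless
        # profiles, 10% of the green dynamic range above background
        margin = max(
            green_noise_factor * float(np.std(bg)),
            0.1 * (float(g.max()) - bg_med),
        )
        green_threshold = bg_med + margin

    sites = []
    for i, j in _gap_runs(gap_mask):
        start = pos[i]
        end = pos[j] if j < pos.size else pos[-1] + step
        if end - start < min_length_um:
            continue
        inside = g[i:j]
        # fresh tubulin must flank the defect on both sides (gap-edge samples)
        if inside[0] <= green_threshold or inside[-1] <= green_threshold:
            continue
        label = "complete" if np.all(inside > green_threshold) else "partial"
        sites.append(IncorporationSite(float(start), float(end), label))

    filament_length = float(pos[-1] - pos[0] + step)
    freq = len(sites) / filament_length
    mean_len = float(np.mean([s.length_um for s in sites])) if sites else 0.0
    return IncorporationSummary(sites, freq, mean_len)
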