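"""Stack-level alignment and rotation profiles.

Two depth profiles are extracted from a confocal z-series:

* the **alignment profile** — the per-slice alignment range ("Δ of angle",
  the angular width holding the top 70% of the orientation-intensity mass)
  plotted against z; lower values mean better-aligned fibers or cells;
* the **rotation profile** — the per-slice dominant orientation tracked
  through depth. Orientations live on the 180°-periodic axial circle, so
  consecutive angles are unwrapped with the minimal axial representative:
  each step is the value of (θ_{i+1} − θ_i) mod 180° mapped into
  (−90°, +90°], which keeps a slow lamellar twist continuous instead of
  jumping by ~180°.

The **rotation range** (max − min of the unwrapped track) summarizes how
much the dominant orientation turns through the construct, and
``detect_rotation_jumps`` flags single large inter-slice reorientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_stack import ImageStack, RunConfig
from .spectral import analyze_slice, PolarProfile


@dataclass
class AlignmentProfile:
    """Per-slice alignment range vs depth; NaN range where a slice is empty."""

    z_um: np.ndarray
    range_deg: np.ndarray
    empty_flags: np.ndarray

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=np.float64)
        self.range_deg = np.asarray(self.range_deg, dtype=np.float64)
        self.empty_flags = np.asarray(self.empty_flags, dtype=bool)
        if not len(self.z_um) == len(self.range_deg) == len(self.empty_flags):
            raise ValueError("profile arrays must share one length per slice")

    @property
    def all_empty(self) -> bool:
        return bool(self.empty_flags.all())

    def mean_range_deg(self) -> float:
        """Mean alignment range over non-empty slices (NaN if none)."""
        ok = ~self.empty_flags
        return float(self.range_deg[ok].mean()) if ok.any() else float("nan")


@dataclass
class RotationProfile:
    """Unwrapped dominant-orientation track vs depth.

    ``angle_deg_unwrapped`` is real-valued (not reduced mod 180°);
    ``step_deltas_deg[i]`` is the signed change arriving at slice i, in
    (−90°, +90°], with ``step_deltas_deg[0] = 0``. Empty slices carry the
    previous defined angle forward (flagged, zero delta) so isolated dark
    planes do not fabricate jumps.
    """

    z_um: np.ndarray
    angle_deg_unwrapped: np.ndarray
    step_deltas_deg: np.ndarray
    empty_flags: np.ndarray

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=np.float64)
        self.angle_deg_unwrapped = np.asarray(self.angle_deg_unwrapped, dtype=np.float64)
        self.step_deltas_deg = np.asarray(self.step_deltas_deg, dtype=np.float64)
        self.empty_flags = np.asarray(self.empty_flags, dtype=bool)

    @property
    def all_empty(self) -> bool:
        return bool(self.empty_flags.all())


def _axial_delta(a: float, b: float) -> float:
    """Minimal axial representative of b - a, in (-90, +90]; ±90 -> +90."""
    d = (b - a) % 180.0
    if d > 90.0:
        d -= 180.0
    return d


def alignment_profile(stack: ImageStack, config: RunConfig | None = None) -> AlignmentProfile:
    """Per-slice alignment range through the stack (Δ of angle vs z)."""
    config = config or RunConfig()
    ranges, flags = [], []
    for sl in stack:
        _, summary = analyze_slice(sl, config)
        ranges.append(summary.range_deg)
        flags.append(summary.empty_flag)
    return AlignmentProfile(stack.z_positions_um, np.array(ranges), np.array(flags))


def rotation_profile(
    stack: ImageStack, config: RunConfig | None = None, angle_stat: str = "median"
) -> RotationProfile:
    """Unwrapped dominant-orientation track through the stack.

    ``angle_stat`` selects the per-slice angle: ``"median"`` (mass median
    of the top-70% arc, the default, consistent with the alignment
    statistic) or ``"peak"`` (the maximal histogram bin centre).
    """
    config = config or RunConfig()
    if angle_stat not in ("median", "peak"):
        raise ValueError(f"angle_stat must be 'median' or 'peak', got {angle_stat!r}")
    n = len(stack)
    raw = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    for i, sl in enumerate(stack):
        prof, summary = analyze_slice(sl, config)
        if summary.empty_flag:
            flags[i] = True
        elif angle_stat == "median":
            raw[i] = summary.median_angle_deg % 180.0
        else:
            raw[i] = prof.angles_deg[int(np.argmax(prof.intensities))]

    unwrapped = np.full(n, np.nan)
    deltas = np.zeros(n)
    defined = np.nonzero(~flags)[0]
    if defined.size:
        first = defined[0]
        unwrapped[: first + 1] = raw[first]  # backfill leading empties, flagged
        last_raw, last_unw = raw[first], raw[first]
        for i in range(first + 1, n):
            if flags[i]:
                unwrapped[i] = last_unw  # carry-forward, no delta
            else:
                d = _axial_delta(last_raw, raw[i])
                deltas[i] = d
                last_unw = last_unw + d
                last_raw = raw[i]
                unwrapped[i] = last_unw
    return RotationProfile(stack.z_positions_um, unwrapped, deltas, flags)


def rotation_range(profile: RotationProfile) -> float:
    """Total angular excursion: max − min of the unwrapped track (non-empty
    slices only); NaN when no slice has a defined orientation."""
    ok = ~profile.empty_flags
    if not ok.any():
        return float("nan")
    vals = profile.angle_deg_unwrapped[ok]
    return float(vals.max() - vals.min())


def rotation_slope(profile: RotationProfile) -> float:
    """Least-squares rotation rate in degrees per slice over defined slices."""
    ok = ~profile.empty_flags & np.isfinite(profile.angle_deg_unwrapped)
    if ok.sum() < 2:
        return float("nan")
    idx = np.nonzero(ok)[0].astype(np.float64)
    return float(np.polyfit(idx, profile.angle_deg_unwrapped[ok], 1)[0])


def detect_rotation_jumps(
    profile: RotationProfile, jump_threshold_deg: float = 30.0
) -> list[tuple[float, float]]:
    """Steps with |delta| >= threshold, as (z_um of the arriving slice, delta),
    ordered by depth."""
    hits = []
    for i in range(1, len(profile.step_deltas_deg)):
        d = profile.step_deltas_deg[i]
        if not profile.empty_flags[i] and abs(d) >= jump_threshold_deg:
            hits.append((float(profile.z_um[i]), float(d)))
    return hits


def analyze_stack(stack: ImageStack, config: RunConfig | None = None) -> dict:
    """Run the full per-slice + stack-level analysis.

    Returns a dict with the per-slice table (z_um, median_angle_deg,
    range_deg, empty), the per-stack summary table, the polar profiles and
    the two profile objects — ready for :func:`fibrospect.io_stack.write_results`.
    """
    config = config or RunConfig()
    profiles: list[PolarProfile] = []
    medians, ranges, flags = [], [], []
    for sl in stack:
        prof, summary = analyze_slice(sl, config)
        profiles.append(prof)
        medians.append(summary.median_angle_deg)
        ranges.append(summary.range_deg)
        flags.append(summary.empty_flag)
    align = AlignmentProfile(stack.z_positions_um, np.array(ranges), np.array(flags))
    rot = rotation_profile(stack, config)
    jumps = detect_rotation_jumps(rot)
    per_slice = pd.DataFrame(
        {
            "z_um": stack.z_positions_um,
            "median_angle_deg": medians,
            "range_deg": ranges,
            "angle_deg_unwrapped": rot.angle_deg_unwrapped,
            "empty": flags,
        }
    )
    summary_tbl = pd.DataFrame(
        {
            "rotation_range_deg": [rotation_range(rot)],
            "slope_deg_per_slice": [rotation_slope(rot)],
            "n_jumps": [len(jumps)],
            "mean_range_deg": [align.mean_range_deg()],
            "n_slices": [len(stack)],
            "n_empty": [int(align.empty_flags.sum())],
        }
    )
    return {
        "per_slice": per_slice,
        "summary": summary_tbl,
        "polar_profiles": profiles,
        "alignment": align,
        "rotation": rot,
        "jumps": jumps,
    }
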