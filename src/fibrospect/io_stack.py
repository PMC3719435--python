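"""Image-stack I/O, run configuration and result export.

A confocal z-series is held as an :class:`ImageStack`: an ordered set of 2D
intensity slices with a physical z-step. Slice ``i=0`` is the top of the
construct (the first TIFF page); the z-position of slice ``i`` is
``i * z_step_um``. All angles downstream are reported in degrees on the
180°-periodic axial circle, 0° along the image x-axis, counter-clockwise
positive (y pointing up).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Rec. 709 luminance weights used for RGB -> grayscale conversion.
LUMINANCE_WEIGHTS = (0.2126, 0.7152, 0.0722)


class FormatError(ValueError):
    """Raised when an input file violates the expected stack format."""


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel image to a single-channel intensity array.

    3-channel input is reduced with fixed Rec. 709 luminance weights
    (0.2126, 0.7152, 0.0722); single-channel input is returned as float64
    unchanged in value.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        return arr[..., 0].astype(np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        w = np.asarray(LUMINANCE_WEIGHTS)
        return arr.astype(np.float64) @ w
    raise ValueError(
        f"expected a 2D image or an image with 1 or 3 channels, got shape {arr.shape}"
    )


@dataclass
class ImageStack:
    """Ordered z-series of 2D intensity slices with physical z spacing.

    Parameters
    ----------
    slices
        Sequence of 2D non-negative intensity arrays, all the same shape,
        ordered by increasing depth.
    z_step_um
        Distance between consecutive optical sections, microns (> 0).
    pixel_size_um
        In-plane pixel pitch, microns. Carried as metadata; the spectral
        math works in pixel units.
    channel
        Free-text stain label, e.g. ``"SMA"`` or ``"ColI"``.
    """

    slices: list[np.ndarray]
    z_step_um: float
    pixel_size_um: float = 1.0
    channel: str = ""

    def __post_init__(self) -> None:
        if self.z_step_um <= 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        slices = [np.asarray(s, dtype=np.float64) for s in self.slices]
        if not slices:
            raise ValueError("stack must contain at least one slice")
        shape = slices[0].shape
        for i, s in enumerate(slices):
            if s.ndim != 2:
                raise FormatError(f"slice {i} is not 2D (shape {s.shape})")
            if s.shape != shape:
                raise FormatError(
                    f"slice {i} has shape {s.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(s)):
                raise ValueError(f"slice {i} contains non-finite intensities")
            if np.any(s < 0):
                raise ValueError(f"slice {i} contains negative intensities")
        self.slices = slices

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.slices[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    @property
    def z_positions_um(self) -> np.ndarray:
        """z-position of each slice; slice i sits at exactly i * z_step_um."""
        return np.arange(len(self.slices)) * self.z_step_um

    def as_array(self) -> np.ndarray:
        """Stack as a (n_slices, H, W) float array."""
        return np.stack(self.slices)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the spectral orientation analysis.

    ``r_max_px`` is the outer radius of the polar integration annulus in
    spectral pixels; ``mass_fraction`` the share of total orientation-
    intensity mass summarized by the alignment range (the "top 70% of the
    population"); ``dc_mask_radius_px`` the radius of the zeroed disc around
    the zero-frequency pixel.
    """

    r_max_px: int = 200
    mass_fraction: float = 0.70
    angular_bin_deg: float = 1.0
    dc_mask_radius_px: int = 3
    window: str = "hann"
    min_signal_fraction: float = 0.001

    def __post_init__(self) -> None:
        if self.r_max_px < self.dc_mask_radius_px + 1:
            raise ValueError("r_max_px must be at least dc_mask_radius_px + 1")
        if not 0.0 < self.mass_fraction <= 1.0:
            raise ValueError("mass_fraction must be in (0, 1]")
        if not 0.0 < self.angular_bin_deg <= 180.0:
            raise ValueError("angular_bin_deg must be in (0, 180]")
        n_bins = 180.0 / self.angular_bin_deg
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("angular_bin_deg must divide 180 evenly")
        if self.window not in ("hann", "none"):
            raise ValueError(f"window must be 'hann' or 'none', got {self.window!r}")
        if not 0.0 <= self.min_signal_fraction < 1.0:
            raise ValueError("min_signal_fraction must be in [0, 1)")
        if self.dc_mask_radius_px < 0:
            raise ValueError("dc_mask_radius_px must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_stack(
    path: str | Path, z_step_um: float, channel: str = ""
) -> ImageStack:
    """Read a multi-page TIFF z-series into an :class:`ImageStack`.

    RGB pages are converted to grayscale with the fixed luminance weights;
    page order is preserved (page 0 = top of the construct). Pages with
    inconsistent dimensions raise :class:`FormatError`.
    """
    path = Path(path)
    if z_step_um <= 0:
        raise ValueError(f"z_step_um must be > 0, got {z_step_um}")
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path} contains no pages")
    slices = [to_grayscale(p) for p in pages]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"{path} pages have inconsistent dimensions: {shapes}")
    return ImageStack(slices=slices, z_step_um=z_step_um, channel=channel)


def write_stack(stack: ImageStack, path: str | Path, dtype=np.uint16) -> None:
    """Write a stack as a multi-page TIFF (values cast, not rescaled)."""
    data = stack.as_array()
    info = np.iinfo(dtype)
    tifffile.imwrite(
        Path(path),
        np.clip(np.round(data), info.min, info.max).astype(dtype),
        photometric="minisblack",
    )


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping | None = None,
    polar_profiles: Sequence | None = None,
) -> list[Path]:
    """Write analysis tables as CSV plus a JSON run manifest.

    ``tables`` maps basename (without extension) to a DataFrame; each is
    written as ``<name>.csv`` with a header row. ``polar_profiles`` is an
    optional sequence of PolarProfile objects, exported one CSV per slice
    as ``polar_0000.csv`` etc. with columns ``angle_deg,intensity``.
    Returns the list of written paths.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if polar_profiles is not None:
        for i, prof in enumerate(polar_profiles):
            p = out / f"polar_{i:04d}.csv"
            pd.DataFrame(
                {"angle_deg": prof.angles_deg, "intensity": prof.intensities}
            ).to_csv(p, index=False)
            written.append(p)
    manifest_out = dict(manifest or {})
    manifest_out.setdefault("package", "fibrospect")
    manifest_out["files"] = [p.name for p in written]
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest_out, indent=2, default=str))
    written.append(mp)
    return written
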