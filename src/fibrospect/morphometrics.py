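"""Z-stack morphometrics: construct thickness, per-slice cell counts and
group-comparison statistics.

Thickness follows the confocal convention of measuring from the first
optical section with visible cells to the last: thickness =
(last − first) × z-step, the fence-post distance between the two planes.
Cell counting is per plane-of-focus (no 3D linking of nuclei across
sections). Group comparison provides Welch's two-sample t-test and
Dunnett's many-to-one multiple comparison against a control group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .io_stack import ImageStack


@dataclass
class ThicknessResult:
    """z-extent of cell visibility. ``thickness_um = (last − first) × z_step``."""

    first_slice_idx: int
    last_slice_idx: int
    thickness_um: float
    threshold_used: float
    empty_flag: bool = False


@dataclass
class CellCountResult:
    """Per-slice object counts with centroid table (z_idx, row, col)."""

    counts_per_slice: np.ndarray
    total_objects: int
    min_area_px: int
    centroids: pd.DataFrame


@dataclass
class GroupComparison:
    """Pairwise Welch t-tests plus Dunnett-adjusted comparisons vs control.

    ``t_statistic``/``p_value`` refer to the control vs the first
    treatment group (the only contrast when there are two groups);
    all pairwise results are in ``pairwise``.
    """

    labels: list[str]
    control_label: str
    means: dict[str, float]
    sds: dict[str, float]
    t_statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], tuple[float, float]]
    dunnett_results: dict[str, float]
    alpha: float = 0.05


def _global_otsu(stack: ImageStack) -> float | None:
    """Otsu threshold over the whole stack's intensity range; None if flat."""
    data = stack.as_array()
    if data.max() <= data.min():
        return None
    return float(threshold_otsu(data))


def measure_thickness(
    stack: ImageStack, occupancy_threshold: float = 0.005
) -> ThicknessResult:
    """Construct thickness from the first to the last cell-visible slice.

    A slice is "cell visible" when its foreground fraction, under a single
    Otsu threshold computed on the stack's global intensity histogram, is
    at least ``occupancy_threshold``. An all-dark (or threshold-free) stack
    yields a flagged empty result.
    """
    if not 0.0 < occupancy_threshold < 1.0:
        raise ValueError("occupancy_threshold must be in (0, 1)")
    thr = _global_otsu(stack)
    if thr is None:
        return ThicknessResult(-1, -1, float("nan"), occupancy_threshold, empty_flag=True)
    fractions = np.array([(sl > thr).mean() for sl in stack])
    visible = np.nonzero(fractions >= occupancy_threshold)[0]
    if visible.size == 0:
        return ThicknessResult(-1, -1, float("nan"), occupancy_threshold, empty_flag=True)
    first, last = int(visible[0]), int(visible[-1])
    return ThicknessResult(first, last, (last - first) * stack.z_step_um, occupancy_threshold)


def _count_slice(
    binary: np.ndarray, min_area_px: int, split_min_distance_px: int
) -> list[tuple[float, float]]:
    """Centroids of objects in one binarized slice; touching pairs split by
    distance-transform watershed."""
    if min_area_px > 1:
        # drop components with area < min_area_px (max_size removes <=)
        binary = remove_small_objects(binary, max_size=min_area_px - 1)
    if not binary.any():
        return []
    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance,
        min_distance=split_min_distance_px,
        labels=cc_label(binary),
        exclude_border=False,
    )
    if len(peaks) == 0:
        labels = cc_label(binary)
    else:
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=binary)
    out = []
    for region in regionprops(labels):
        if region.area >= min_area_px:
            out.append(region.centroid)
    return out


def count_cells(
    stack: ImageStack,
    min_area_px: int = 20,
    smoothing_sigma_px: float = 1.0,
    split_min_distance_px: int = 5,
) -> CellCountResult:
    """Count nucleus-like objects in each plane-of-focus of a z-series.

    Each slice is Gaussian-smoothed and binarized with one Otsu threshold
    from the stack's global histogram; connected components smaller than
    ``min_area_px`` are discarded and touching pairs are split by a
    distance-transform watershed seeded at local distance maxima at least
    ``split_min_distance_px`` apart. Blank slices count zero.
    """
    smoothed = [gaussian(sl, sigma=smoothing_sigma_px, preserve_range=True) for sl in stack]
    sm_stack = np.stack(smoothed)
    if sm_stack.max() <= sm_stack.min():
        thr = np.inf  # flat stack: nothing to count
    else:
        thr = float(threshold_otsu(sm_stack))
    counts = np.zeros(len(stack), dtype=int)
    rows = []
    for z, sm in enumerate(smoothed):
        centroids = _count_slice(sm > thr, min_area_px, split_min_distance_px)
        counts[z] = len(centroids)
        for r, c in centroids:
            rows.append((z, r, c))
    table = pd.DataFrame(rows, columns=["z_idx", "row", "col"])
    return CellCountResult(counts, int(counts.sum()), min_area_px, table)


def compare_groups(
    samples: dict[str, "np.ndarray | list[float]"],
    control_label: str,
    equal_var: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided two-sample t-tests (Welch by default) for all pairwise
    contrasts, plus Dunnett's many-to-one adjusted comparisons of every
    treatment group against ``control_label``.

    ``equal_var=True`` switches the pairwise tests to the classic pooled-
    variance Student form; the Dunnett procedure always pools, as defined.
    """
    if control_label not in samples:
        raise ValueError(f"control label {control_label!r} not among groups")
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    groups = {k: np.asarray(v, dtype=np.float64) for k, v in samples.items()}
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 samples")
    labels = list(groups)
    means = {k: float(v.mean()) for k, v in groups.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in groups.items()}

    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            res = stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
            pairwise[(a, b)] = (float(res.statistic), float(res.pvalue))

    treatments = [k for k in labels if k != control_label]
    dres = stats.dunnett(
        *[groups[k] for k in treatments], control=groups[control_label]
    )
    dunnett = {k: float(p) for k, p in zip(treatments, dres.pvalue)}

    key = next(k for k in pairwise if set(k) == {control_label, treatments[0]})
    t_stat, p_val = pairwise[key]
    return GroupComparison(
        labels=labels,
        control_label=control_label,
        means=means,
        sds=sds,
        t_statistic=t_stat,
        p_value=p_val,
        pairwise=pairwise,
        dunnett_results=dunnett,
        alpha=alpha,
    )


def matrix_per_cell(thickness_um: float, total_cells: int, area_mm2: float) -> float:
    """Matrix volume proxy per cell: thickness × area / cell count
    (µm·mm²/cell). Constant across conditions when cells each deposit the
    same amount of matrix."""
    if total_cells <= 0:
        raise ValueError("total_cells must be positive")
    if thickness_um < 0 or area_mm2 <= 0:
        raise ValueError("thickness must be >= 0 and area > 0")
    return thickness_um * area_mm2 / total_cells
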