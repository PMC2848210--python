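"""Automated nuclear-translocation readout.

Pipeline per field: segment nuclei from the stain channel, erode each
nucleus and place a thin cytoplasmic ring around it, extract per-cell
morphology and GFP intensity features, run the R01→R04 gating cascade and
aggregate per-well percentages of cells with nuclear reporter signal.

Compartment geometry follows a Euclidean distance-transform definition:
the eroded nucleus keeps pixels whose distance to the nucleus background
exceeds ``erosion_px``; the ring takes background pixels whose distance to
the (un-eroded) nucleus lies in ``(ring_distance_px, ring_distance_px +
ring_width_px]``.  Ring pixels claimed by two cells go to the nearer
nucleus, ties to the lower label id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.measure import perimeter_crofton

__all__ = [
    "CompartmentParams",
    "CompartmentMap",
    "CellFeatures",
    "Bounds",
    "GateSpec",
    "WellResult",
    "CELL_LINE_PROFILES",
    "segment_nuclei",
    "define_compartments",
    "extract_features",
    "apply_gates",
    "calibrate_gates",
    "classify_field",
    "well_percentage",
    "ratio_distribution",
]

#: Per-cell-line compartment geometry (erosion, ring distance) in pixels.
CELL_LINE_PROFILES: dict[str, dict[str, int]] = {
    "a549": {"erosion_px": 2, "ring_distance_px": 1, "ring_width_px": 1},
    "ags": {"erosion_px": 2, "ring_distance_px": 1, "ring_width_px": 1},
    "l929": {"erosion_px": 3, "ring_distance_px": 2, "ring_width_px": 1},
}


@dataclass(frozen=True)
class CompartmentParams:
    erosion_px: int = 2
    ring_distance_px: int = 1
    ring_width_px: int = 1

    def __post_init__(self) -> None:
        if min(self.erosion_px, self.ring_distance_px) < 0 or self.ring_width_px < 1:
            raise ValueError("erosion/distance must be >= 0 and ring width >= 1")


#: Pixel set as parallel (rows, cols) index arrays.
PixelSet = tuple[np.ndarray, np.ndarray]


@dataclass
class CompartmentMap:
    nucleus_labels: np.ndarray  # un-eroded label grid, 0 = background
    nuclear_masks: dict[int, PixelSet]  # label -> eroded-nucleus pixels
    ring_masks: dict[int, PixelSet]  # label -> cytoplasmic-ring pixels
    params: CompartmentParams
    excluded: dict[int, str] = field(default_factory=dict)  # label -> reason


@dataclass
class CellFeatures:
    cell_id: int
    nucleus_area_px: int  # un-eroded area
    perimeter_px: float  # Crofton estimate on the un-eroded nucleus
    circularity: float  # 4*pi*A / P^2
    mean_nuc_gfp: float
    mean_cyt_gfp: float
    sd_gfp: float  # over the union of eroded-nucleus and ring pixels
    nc_ratio: float


@dataclass(frozen=True)
class Bounds:
    """Closed interval; infinite ends allowed."""

    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"need lo < hi, got [{self.lo}, {self.hi}]")

    def __contains__(self, v: float) -> bool:
        return self.lo <= v <= self.hi


@dataclass(frozen=True)
class GateSpec:
    """R01 (morphology), R02 (intensity/homogeneity) bounds and the
    nuclear-vs-cytoplasmic decision boundary in the (nuclear, cytoplasmic)
    mean-GFP plane: nuclear iff mean_nuc > theta_nc * mean_cyt + intercept."""

    r01_perimeter: Bounds = field(default_factory=Bounds)
    r01_circularity: Bounds = field(default_factory=Bounds)
    r02_intensity: Bounds = field(default_factory=Bounds)  # mean GFP over nucleus+ring
    r02_sd: Bounds = field(default_factory=Bounds)
    theta_nc: float = 1.5
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.theta_nc <= 0:
            raise ValueError("theta_nc must be > 0")


@dataclass
class WellResult:
    well: str
    n_nuclear: int
    n_cytoplasmic: int
    n_excluded: int
    pct_nuclear: float | None

    @property
    def pct_cytoplasmic(self) -> float | None:
        return None if self.pct_nuclear is None else 100.0 - self.pct_nuclear


def segment_nuclei(
    stain_channel: np.ndarray,
    min_area_px: int = 20,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_contrast: float = 1e-6,
) -> np.ndarray:
    """Label connected bright regions of the nuclear-stain channel.

    Components smaller than ``min_area_px`` are dropped.  A flat image (range
    below ``min_contrast``) yields zero labels rather than an error.
    """
    img = np.asarray(stain_channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite pixels in stain channel")
    if threshold_method == "otsu":
        if float(img.max() - img.min()) < min_contrast:
            return np.zeros(img.shape, dtype=np.int32)
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(img)
    elif threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for method 'fixed'")
        thr = fixed_threshold
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = img > thr
    labels = sk_label(mask, connectivity=2).astype(np.int32)
    if min_area_px > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        kill = np.flatnonzero(sizes < min_area_px)
        if len(kill):
            labels[np.isin(labels, kill)] = 0
        labels = _relabel_consecutive(labels)
    return labels


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    ids, inverse = np.unique(labels, return_inverse=True)
    new_ids = np.zeros(len(ids), dtype=labels.dtype)
    new_ids[ids > 0] = np.arange(1, int((ids > 0).sum()) + 1)
    return new_ids[inverse].reshape(labels.shape)


def define_compartments(
    labels: np.ndarray,
    erosion_px: int = 2,
    ring_distance_px: int = 1,
    ring_width_px: int = 1,
) -> CompartmentMap:
    """Build eroded-nucleus and cytoplasmic-ring masks for every label.

    Nuclei erased entirely by the erosion are dropped and recorded in
    ``excluded``.  Ring pixels always lie in the background of the label
    grid; contested pixels go to the nearest nucleus (ties: lower label).
    """
    params = CompartmentParams(erosion_px, ring_distance_px, ring_width_px)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    h, w = labels.shape
    nuclear_masks: dict[int, PixelSet] = {}
    excluded: dict[int, str] = {}
    # distance from every background pixel to each nearby nucleus, kept sparse
    # via bounding boxes; ownership resolved globally afterwards
    ring_lo, ring_hi = float(ring_distance_px), float(ring_distance_px + ring_width_px)
    best_dist = np.full((h, w), np.inf)
    best_owner = np.zeros((h, w), dtype=np.int64)
    pad = int(math.ceil(ring_hi)) + 1
    objects = ndimage.find_objects(labels)
    for lab in ids:
        sl = objects[lab - 1]
        if sl is None:
            continue
        ys = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, h))
        xs = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, w))
        cell = labels[ys, xs] == lab
        # eroded nucleus: distance to the cell's own background > erosion_px.
        # EDT treats the box edge as foreground continuation, so pad the box
        # by one pixel of background on each side to get true distances.
        d_in = ndimage.distance_transform_edt(np.pad(cell, 1))[1:-1, 1:-1]
        eroded = d_in > erosion_px
        if not eroded.any():
            excluded[int(lab)] = "erased_by_erosion"
            continue
        ey, ex = np.nonzero(eroded)
        nuclear_masks[int(lab)] = (ey + ys.start, ex + xs.start)
        # distance from outside pixels to this nucleus
        d_out = ndimage.distance_transform_edt(~cell)
        cand = (d_out > ring_lo) & (d_out <= ring_hi)
        yy, xx = np.nonzero(cand)
        gy, gx = yy + ys.start, xx + xs.start
        d = d_out[yy, xx]
        closer = d < best_dist[gy, gx]
        tie = (d == best_dist[gy, gx]) & (lab < best_owner[gy, gx])
        take = closer | tie
        best_dist[gy[take], gx[take]] = d[take]
        best_owner[gy[take], gx[take]] = lab
    # rings live strictly in the background of the label grid
    best_owner[labels > 0] = 0
    ry, rx = np.nonzero(best_owner > 0)
    owners = best_owner[ry, rx]
    order = np.argsort(owners, kind="stable")
    ry, rx, owners = ry[order], rx[order], owners[order]
    ring_masks: dict[int, PixelSet] = {}
    for lab in nuclear_masks:
        lo = np.searchsorted(owners, lab, side="left")
        hi_i = np.searchsorted(owners, lab, side="right")
        ring_masks[lab] = (ry[lo:hi_i], rx[lo:hi_i])
    return CompartmentMap(
        nucleus_labels=labels.copy(),
        nuclear_masks=nuclear_masks,
        ring_masks=ring_masks,
        params=params,
        excluded=excluded,
    )


def extract_features(
    compartments: CompartmentMap,
    gfp_channel: np.ndarray,
    exclude_border: bool = True,
) -> tuple[list[CellFeatures], dict[int, str]]:
    """Per-cell morphology and intensity features.

    Perimeter and area are measured on the un-eroded nucleus; intensities on
    the eroded nucleus and the ring.  Cells with an empty ring, a zero
    cytoplasmic mean, or (optionally) touching the image border are excluded
    with a recorded reason.
    """
    gfp = np.asarray(gfp_channel, dtype=float)
    labels = compartments.nucleus_labels
    if gfp.shape != labels.shape:
        raise ValueError("gfp channel dimensions must match the label grid")
    h, w = labels.shape
    feats: list[CellFeatures] = []
    excluded = dict(compartments.excluded)
    objects = ndimage.find_objects(labels)
    for lab, (ny, nx) in compartments.nuclear_masks.items():
        ring_y, ring_x = compartments.ring_masks[lab]
        sl = objects[lab - 1]
        if not len(ring_y):
            excluded[lab] = "empty_ring"
            continue
        ys = np.concatenate([[sl[0].start, sl[0].stop - 1], ring_y])
        xs = np.concatenate([[sl[1].start, sl[1].stop - 1], ring_x])
        if exclude_border and (
            ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1
        ):
            excluded[lab] = "touches_border"
            continue
        cell = labels[sl] == lab
        area = int(cell.sum())
        perim = float(perimeter_crofton(np.pad(cell, 1), directions=4))
        circ = 4.0 * math.pi * area / perim**2 if perim > 0 else 0.0
        mean_nuc = float(gfp[ny, nx].mean())
        mean_cyt = float(gfp[ring_y, ring_x].mean())
        if mean_cyt <= 0:
            excluded[lab] = "zero_cytoplasmic_signal"
            continue
        uy = np.concatenate([ny, ring_y])
        ux = np.concatenate([nx, ring_x])
        sd = float(gfp[uy, ux].std())
        feats.append(
            CellFeatures(
                cell_id=lab,
                nucleus_area_px=area,
                perimeter_px=perim,
                circularity=circ,
                mean_nuc_gfp=mean_nuc,
                mean_cyt_gfp=mean_cyt,
                sd_gfp=sd,
                nc_ratio=mean_nuc / mean_cyt,
            )
        )
    return feats, excluded


def _overall_gfp(f: CellFeatures) -> float:
    # mean GFP over the cell as seen by the assay (nucleus + ring means,
    # weighted equally); used for the R02 intensity gate
    return 0.5 * (f.mean_nuc_gfp + f.mean_cyt_gfp)


def apply_gates(features: Sequence[CellFeatures], gates: GateSpec) -> dict[int, str]:
    """Classify each cell as nuclear / cytoplasmic / excluded.

    R01 filters on (perimeter, circularity); R02 on (overall GFP intensity,
    GFP standard deviation); survivors split on the ratio boundary: nuclear
    iff ``mean_nuc_gfp > theta_nc * mean_cyt_gfp + intercept``.
    """
    out: dict[int, str] = {}
    for f in features:
        if f.perimeter_px not in gates.r01_perimeter or f.circularity not in gates.r01_circularity:
            out[f.cell_id] = "excluded"
        elif _overall_gfp(f) not in gates.r02_intensity or f.sd_gfp not in gates.r02_sd:
            out[f.cell_id] = "excluded"
        elif f.mean_nuc_gfp > gates.theta_nc * f.mean_cyt_gfp + gates.intercept:
            out[f.cell_id] = "nuclear"
        else:
            out[f.cell_id] = "cytoplasmic"
    return out


def calibrate_gates(
    control_features: Sequence[CellFeatures],
    percentiles: tuple[float, float] = (1.0, 99.0),
    theta_nc: float = 1.5,
    intercept: float = 0.0,
) -> GateSpec:
    """Set R01/R02 bounds from an unstimulated control population.

    Bounds are the given percentiles (default 1st-99th) of each gated
    feature over the control cells; the classification boundary itself is
    passed through unchanged.
    """
    if not control_features:
        raise ValueError("need at least one control cell")

    def bounds(vals: Iterable[float]) -> Bounds:
        arr = np.asarray(list(vals), dtype=float)
        lo, hi = np.percentile(arr, percentiles)
        if lo == hi:  # degenerate control: widen so the value passes
            lo, hi = lo - 0.5, hi + 0.5
        return Bounds(float(lo), float(hi))

    return GateSpec(
        r01_perimeter=bounds(f.perimeter_px for f in control_features),
        r01_circularity=bounds(f.circularity for f in control_features),
        r02_intensity=bounds(_overall_gfp(f) for f in control_features),
        r02_sd=bounds(f.sd_gfp for f in control_features),
        theta_nc=theta_nc,
        intercept=intercept,
    )


def classify_field(
    stain_channel: np.ndarray,
    gfp_channel: np.ndarray,
    gates: GateSpec,
    compartment_params: CompartmentParams | None = None,
    min_area_px: int = 20,
) -> tuple[list[CellFeatures], dict[int, str], int]:
    """Full single-field pipeline; returns (features, classification, n_dropped).

    ``n_dropped`` counts cells excluded before gating (border, erased by
    erosion, empty ring).
    """
    cp = compartment_params or CompartmentParams()
    labels = segment_nuclei(stain_channel, min_area_px=min_area_px)
    comp = define_compartments(labels, cp.erosion_px, cp.ring_distance_px, cp.ring_width_px)
    feats, dropped = extract_features(comp, gfp_channel)
    classes = apply_gates(feats, gates)
    return feats, classes, len(dropped)


def well_percentage(
    classifications: Mapping[str, Sequence[str]],
) -> list[WellResult]:
    """Per-well percentage of nuclear cells.

    Input maps well label -> iterable of per-cell classes ("nuclear",
    "cytoplasmic", "excluded").  Excluded cells never enter the denominator;
    wells with zero classified cells report ``pct_nuclear=None``.
    """
    results = []
    for well, classes in classifications.items():
        n_nuc = sum(1 for c in classes if c == "nuclear")
        n_cyt = sum(1 for c in classes if c == "cytoplasmic")
        n_exc = sum(1 for c in classes if c == "excluded")
        denom = n_nuc + n_cyt
        pct = 100.0 * n_nuc / denom if denom > 0 else None
        results.append(WellResult(well, n_nuc, n_cyt, n_exc, pct))
    return results


def ratio_distribution(
    features: Sequence[CellFeatures], bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-cell nuclear:cytoplasmic GFP ratios.

    Returns (counts, bin_edges); counts sum to the number of cells.
    """
    if not features:
        raise ValueError("need at least one cell")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    ratios = np.array([f.nc_ratio for f in features], dtype=float)
    counts, edges = np.histogram(ratios, bins=bins)
    return counts, edges
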