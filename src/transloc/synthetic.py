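"""Synthetic two-channel microscopy fields, plates and single-cell traces.

Generates seeded, ground-truth-labeled stand-ins for the fixed-cell
translocation assay (nuclear-stain channel + GFP channel) and for live-cell
GFP intensity movies, so the whole pipeline is testable without real data.

Nuclei are rasterized disks with per-cell radius drawn uniformly from a
range; the cytoplasm is a surrounding annulus of fixed extent.  Per-cell GFP
is split between nucleus and cytoplasm according to a ground-truth
translocation state, and additive Gaussian noise (clipped at zero) is the
only corruption model.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .oscillator import OscillatorParams, StimulusProfile, Trace, simulate_cell

__all__ = [
    "IntensityParams",
    "FieldSpec",
    "CellTruth",
    "SyntheticField",
    "PlacementError",
    "generate_field",
    "generate_plate",
    "generate_trace",
    "write_field_tiffs",
    "write_truth_csv",
    "well_labels_96",
]

#: Valid 96-well labels A1..H12.
well_labels_96 = tuple(f"{r}{c}" for r in string.ascii_uppercase[:8] for c in range(1, 13))


@dataclass(frozen=True)
class IntensityParams:
    """Noise-free intensity levels, in arbitrary float units."""

    background_stain: float = 100.0
    background_gfp: float = 0.0
    nuclear_stain_level: float = 2000.0
    gfp_total: float = 50000.0  # integrated GFP per cell (sum over its pixels)
    ratio_nuclear_state: float = 4.0  # nuclear:cytoplasmic mean GFP, translocated
    ratio_cytoplasmic_state: float = 0.5  # same ratio for resting cells

    def __post_init__(self) -> None:
        for name in (
            "background_stain",
            "background_gfp",
            "nuclear_stain_level",
            "gfp_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ratio_nuclear_state <= 0 or self.ratio_cytoplasmic_state <= 0:
            raise ValueError("GFP ratios must be > 0")


@dataclass(frozen=True)
class FieldSpec:
    width_px: int = 512
    height_px: int = 512
    n_cells: int = 100
    nucleus_radius_px: tuple[float, float] = (5.0, 8.0)  # uniform (min, max)
    cytoplasm_extent_px: float = 4.0
    fraction_nuclear: float = 0.5
    intensity: IntensityParams = field(default_factory=IntensityParams)
    noise_sd: float = 0.0
    seed: int = 0
    edge_margin_px: float | None = None  # default keeps whole cells inside

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.nucleus_radius_px
        if not 0 < lo <= hi:
            raise ValueError("nucleus_radius_px must satisfy 0 < min <= max")
        if self.cytoplasm_extent_px <= 0:
            raise ValueError("cytoplasm_extent_px must be > 0")
        if not 0.0 <= self.fraction_nuclear <= 1.0:
            raise ValueError("fraction_nuclear must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CellTruth:
    cell_id: int
    x: float
    y: float
    radius_px: float
    state: str  # "nuclear" | "cytoplasmic"


@dataclass
class SyntheticField:
    stain_channel: np.ndarray
    gfp_channel: np.ndarray
    truth: list[CellTruth]

    def __post_init__(self) -> None:
        if self.stain_channel.shape != self.gfp_channel.shape:
            raise ValueError("channel grids must share dimensions")
        h, w = self.stain_channel.shape
        for c in self.truth:
            if not (0 <= c.x < w and 0 <= c.y < h):
                raise ValueError(f"truth centroid of cell {c.cell_id} outside grid")


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement is infeasible."""


def _place_centers(spec: FieldSpec, radii: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping cell centers (cap: 100 * n_cells tries)."""
    margin = (
        spec.edge_margin_px
        if spec.edge_margin_px is not None
        else float(radii.max(initial=0.0)) + spec.cytoplasm_extent_px + 2.0
    )
    centers = np.empty((spec.n_cells, 2))
    # cells must not overlap including their cytoplasmic annuli, so that each
    # ring samples only its own cell
    min_gap = spec.cytoplasm_extent_px + 2.0
    attempts = 0
    cap = 100 * max(spec.n_cells, 1)
    placed = 0
    while placed < spec.n_cells:
        if attempts >= cap:
            raise PlacementError(
                f"placed only {placed}/{spec.n_cells} nuclei after {cap} attempts; "
                "reduce n_cells or enlarge the field"
            )
        attempts += 1
        x = rng.uniform(margin, spec.width_px - margin)
        y = rng.uniform(margin, spec.height_px - margin)
        if placed:
            d = np.hypot(centers[:placed, 0] - x, centers[:placed, 1] - y)
            if np.any(d < radii[:placed] + radii[placed] + min_gap):
                continue
        centers[placed] = (x, y)
        placed += 1
    return centers


def generate_field(spec: FieldSpec) -> SyntheticField:
    """Generate one two-channel field with ground-truth per-cell states.

    Deterministic for a fixed seed.  In the noise-free image, a cell in state
    "nuclear" has mean nuclear GFP = ratio_nuclear_state x its mean
    cytoplasmic GFP (and symmetrically for "cytoplasmic" cells), with the
    integrated GFP over the whole cell equal to ``gfp_total``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.nucleus_radius_px
    radii = rng.uniform(lo, hi, size=spec.n_cells)
    centers = _place_centers(spec, radii, rng)
    states = np.where(rng.random(spec.n_cells) < spec.fraction_nuclear, "nuclear", "cytoplasmic")

    ip = spec.intensity
    stain = np.full((spec.height_px, spec.width_px), ip.background_stain, dtype=float)
    gfp = np.full((spec.height_px, spec.width_px), ip.background_gfp, dtype=float)

    truth: list[CellTruth] = []
    for i in range(spec.n_cells):
        x0, y0 = centers[i]
        r = radii[i]
        r_out = r + spec.cytoplasm_extent_px
        # rasterize inside a local bounding box only
        y_lo = max(int(np.floor(y0 - r_out)) - 1, 0)
        y_hi = min(int(np.ceil(y0 + r_out)) + 2, spec.height_px)
        x_lo = max(int(np.floor(x0 - r_out)) - 1, 0)
        x_hi = min(int(np.ceil(x0 + r_out)) + 2, spec.width_px)
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        d2 = (xx - x0) ** 2 + (yy - y0) ** 2
        nuc = d2 <= r**2
        cyt = (d2 > r**2) & (d2 <= r_out**2)
        stain[y_lo:y_hi, x_lo:x_hi][nuc] += ip.nuclear_stain_level
        ratio = ip.ratio_nuclear_state if states[i] == "nuclear" else ip.ratio_cytoplasmic_state
        a_nuc = int(nuc.sum())
        a_cyt = int(cyt.sum())
        # per-pixel cytoplasm level c solving c * (a_cyt + ratio * a_nuc) = total
        c = ip.gfp_total / (a_cyt + ratio * a_nuc)
        gfp[y_lo:y_hi, x_lo:x_hi][nuc] += ratio * c
        gfp[y_lo:y_hi, x_lo:x_hi][cyt] += c
        truth.append(CellTruth(i + 1, float(x0), float(y0), float(r), str(states[i])))

    if spec.noise_sd > 0:
        stain = stain + rng.normal(0.0, spec.noise_sd, stain.shape)
        gfp = gfp + rng.normal(0.0, spec.noise_sd, gfp.shape)
        stain = np.clip(stain, 0.0, None)
        gfp = np.clip(gfp, 0.0, None)
    return SyntheticField(stain_channel=stain, gfp_channel=gfp, truth=truth)


def _field_seed(plate_seed: int, well: str, field_index: int) -> int:
    """Stable per-field seed derived from (plate seed, well, field)."""
    import zlib

    key = f"{plate_seed}:{well}:{field_index}".encode()
    return zlib.crc32(key) ^ (plate_seed & 0xFFFFFFFF)


def generate_plate(
    plate_spec: Mapping[str, FieldSpec],
    fields_per_well: int = 4,
    plate_seed: int = 0,
) -> dict[tuple[str, int], SyntheticField]:
    """Generate ``fields_per_well`` fields for every well of a plate layout.

    Well keys must be valid 96-well labels (A1..H12); per-field seeds are
    derived deterministically from (plate_seed, well, field index), so the
    same plate seed reproduces bit-identical channels.
    """
    if fields_per_well < 0:
        raise ValueError("fields_per_well must be >= 0")
    wells = list(plate_spec.keys())
    if len(set(wells)) != len(wells):
        raise ValueError("duplicate well keys")
    for w in wells:
        if w not in well_labels_96:
            raise ValueError(f"invalid 96-well label {w!r}")
    from dataclasses import replace

    out: dict[tuple[str, int], SyntheticField] = {}
    for well, spec in plate_spec.items():
        for f in range(fields_per_well):
            fspec = replace(spec, seed=_field_seed(plate_seed, well, f))
            out[(well, f)] = generate_field(fspec)
    return out


def generate_trace(
    params: OscillatorParams,
    onset_min: float,
    noise_sd: float,
    t_end_min: float,
    dt_min: float,
    seed: int = 0,
    stimulus_kind: str = "sustained",
) -> Trace:
    """Noisy single-cell nuclear-GFP trace with a delayed activation onset.

    The underlying signal is the oscillator solution time-shifted by
    ``onset_min`` (values before onset sit at the pre-stimulus baseline);
    zero-mean Gaussian noise of sd ``noise_sd`` is added to ``n_p65``.
    """
    if t_end_min <= onset_min:
        raise ValueError("t_end_min must exceed onset_min")
    stim = StimulusProfile(kind=stimulus_kind, onset_min=onset_min)
    tr = simulate_cell(params, stim, t_end_min, dt_min)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = tr.n_p65 + rng.normal(0.0, noise_sd, len(tr.n_p65))
        tr = Trace(t_min=tr.t_min, x_ikba=tr.x_ikba, n_p65=np.clip(noisy, 0.0, 1.0))
    return tr


def write_field_tiffs(fld: SyntheticField, out_dir: Path, well: str, field_index: int) -> list[Path]:
    """Write stain/GFP channels as 16-bit TIFFs named <well>_f<i>_<channel>.tif.

    Float intensities are scaled by a fixed factor chosen per plate writer so
    images stay within uint16; here intensities are clipped into range.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in (("stain", fld.stain_channel), ("gfp", fld.gfp_channel)):
        p = out_dir / f"{well}_f{field_index}_{name}.tif"
        tifffile.imwrite(p, np.clip(arr, 0, 65535).astype(np.uint16))
        paths.append(p)
    return paths


def write_truth_csv(
    fields: Mapping[tuple[str, int], SyntheticField], path: Path
) -> Path:
    """Dump ground-truth cell records of a plate as CSV."""
    import pandas as pd

    rows = []
    for (well, fidx), fld in fields.items():
        for c in fld.truth:
            rows.append(
                {
                    "well": well,
                    "field": fidx,
                    "cell_id": c.cell_id,
                    "x": c.x,
                    "y": c.y,
                    "radius_px": c.radius_px,
                    "state": c.state,
                }
            )
    df = pd.DataFrame(rows, columns=["well", "field", "cell_id", "x", "y", "radius_px", "state"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
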