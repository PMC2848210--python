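import math

import numpy as np
import pytest

from transloc.synthetic import FieldSpec, IntensityParams, generate_field


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free 50-cell field with a 4:1 / 1:2 GFP split."""
    spec = FieldSpec(
        width_px=512,
        height_px=512,
        n_cells=50,
        fraction_nuclear=0.5,
        noise_sd=0.0,
        seed=11,
    )
    return spec, generate_field(spec)


@pytest.fixture(scope="session")
def noisy_field():
    spec = FieldSpec(
        width_px=512,
        height_px=512,
        n_cells=50,
        fraction_nuclear=0.5,
        noise_sd=30.0,
        seed=12,
    )
    return spec, generate_field(spec)


def brute_force_compartments(labels: np.ndarray, erosion: float, dist: float, width: float):
    """Exhaustive per-pixel Euclidean distance oracle for compartments.

    Independent of the package implementation: O(pixels^2) scans, intended
    for grids around 32x32 only.  Returns (eroded_sets, ring_sets) keyed by
    label, as sets of (row, col) tuples.  Contested ring pixels go to the
    nearer nucleus, ties to the lower label.
    """
    h, w = labels.shape
    nuclei = {}
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        nuclei[int(lab)] = [
            (y, x) for y in range(h) for x in range(w) if labels[y, x] == lab
        ]
    eroded = {}
    for lab, pix in nuclei.items():
        bg = [(y, x) for y in range(h) for x in range(w) if labels[y, x] != lab]
        keep = set()
        for y, x in pix:
            d = min(math.hypot(y - by, x - bx) for by, bx in bg)
            if d > erosion:
                keep.add((y, x))
        eroded[lab] = keep
    claims: dict[tuple[int, int], list[tuple[float, int]]] = {}
    for lab, pix in nuclei.items():
        for y in range(h):
            for x in range(w):
                if labels[y, x] != 0:
                    continue
                d = min(math.hypot(y - py, x - px) for py, px in pix)
                if dist < d <= dist + width:
                    claims.setdefault((y, x), []).append((d, lab))
    rings = {lab: set() for lab in nuclei}
    for pxl, cl in claims.items():
        _, lab = min(cl)
        rings[lab].add(pxl)
    return eroded, rings


def pixel_set(mask: tuple[np.ndarray, np.ndarray]) -> set[tuple[int, int]]:
    return set(zip(mask[0].tolist(), mask[1].tolist()))
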