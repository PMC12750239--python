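"""Periodic-boundary geometry primitives for orthorhombic boxes.

All distance-based observables (intra/intermolecular distances, RDFs,
order-parameter vectors) route through :func:`min_image_displacement`, so
the minimum-image convention is implemented exactly once.
"""

from __future__ import annotations

import numpy as np

from .model import Box


def min_image_displacement(a: np.ndarray, b: np.ndarray, box_lengths) -> np.ndarray:
    """Displacement b - a mapped to the nearest periodic image.

    ``a`` and ``b`` broadcast; ``box_lengths`` is (lx, ly, lz) or any
    broadcastable (..., 3) array.  Components are reduced into
    [-L/2, L/2) per axis.
    """
    L = np.asarray(box_lengths, dtype=float)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - L * np.round(d / L)


def min_image_distance(a, b, box: Box) -> float | np.ndarray:
    """Euclidean distance under the minimum-image convention (nm)."""
    d = min_image_displacement(a, b, box.lengths)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap(coords: np.ndarray, box_lengths) -> np.ndarray:
    """Wrap coordinates into the primary box [0, L) per axis."""
    L = np.asarray(box_lengths, dtype=float)
    return np.mod(coords, L)


def pairwise_min_image_distances(
    pos_a: np.ndarray, pos_b: np.ndarray, box_lengths
) -> np.ndarray:
    """All-pairs minimum-image distance matrix, shape (len(a), len(b))."""
    d = min_image_displacement(pos_a[:, None, :], pos_b[None, :, :], box_lengths)
    return np.sqrt(np.sum(d * d, axis=-1))
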