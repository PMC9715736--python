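"""Deterministic 2-D sensor layout and canonical microstate templates.

The synthetic generator and the canonical A-D template maps both need
electrode positions, but nothing downstream depends on real head geometry:
only the left-right (x) and anterior-posterior (y) axes matter.  We place
``n`` sensors on the unit disk with a sunflower (golden-angle) arrangement,
which is deterministic, roughly uniform for any channel count, and
left-right balanced enough for the template gradients.

The four canonical resting-state classes follow the standard convention:

* **A** - diagonal gradient, left-posterior vs right-anterior
* **B** - diagonal gradient, right-posterior vs left-anterior
* **C** - anterior-posterior gradient
* **D** - frontocentral maximum (radial bump shifted forward)

Polarity is irrelevant everywhere (maps are matched by absolute spatial
correlation), so only the orientation of each gradient is meaningful.
"""

from __future__ import annotations

import numpy as np

from .containers import PrototypeSet, normalize_rows

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

CANONICAL_LABELS = ["A", "B", "C", "D"]


def sensor_layout(n_channels: int) -> np.ndarray:
    """Return ``n_channels x 2`` sensor coordinates (x right, y anterior)."""
    if n_channels < 1:
        raise ValueError("need at least one channel")
    i = np.arange(n_channels)
    r = np.sqrt((i + 0.5) / n_channels)
    theta = i * GOLDEN_ANGLE
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def smooth_basis(positions: np.ndarray, degree: int = 3) -> np.ndarray:
    """Polynomial spatial basis (without the constant term) at ``positions``.

    Columns are the monomials x, y, x^2, xy, y^2, ... up to ``degree``;
    random combinations of these give smooth, spatially-structured maps.
    """
    x, y = positions[:, 0], positions[:, 1]
    cols = []
    for d in range(1, degree + 1):
        for j in range(d + 1):
            cols.append(x ** (d - j) * y ** j)
    return np.column_stack(cols)


def canonical_templates(n_channels: int, positions: np.ndarray | None = None) -> PrototypeSet:
    """Idealized A-D template maps used for automatic prototype labeling."""
    if positions is None:
        positions = sensor_layout(n_channels)
    x, y = positions[:, 0], positions[:, 1]
    a = x + y
    b = -x + y
    c = y
    d = np.exp(-((x - 0.0) ** 2 + (y - 0.3) ** 2) / (2 * 0.35**2))
    maps = normalize_rows(np.vstack([a, b, c, d]))
    return PrototypeSet(maps=maps, labels=list(CANONICAL_LABELS))
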