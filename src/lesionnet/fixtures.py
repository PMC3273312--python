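"""Small deterministic graphs with hand-placed coordinates.

Used by the test suite for hand-traceable examples and handy for quick
experiments.  Each fixture returns ``(SpatialGraph, DynamicsParams)``; the
coordinates and the resulting edge sets are documented below and stable
across releases.

* ``chain3`` — a(0.4, 0.5), b(0.5, 0.5), c(0.6, 0.5), r = 0.15:
  edges {a,b} and {b,c} only (a-c distance 0.2 > r).
* ``star5`` — hub (0.5, 0.5) plus four satellites 0.14 away along the
  axes, r = 0.15: satellites connect only to the hub (pairwise distance
  0.14 * sqrt(2) ~ 0.198 > r); degree vector (4, 1, 1, 1, 1).
* ``handplaced5`` — two clusters: (0.1, 0.1), (0.2, 0.1), (0.15, 0.2) form
  a triangle, (0.8, 0.8) and (0.9, 0.85) a single edge; r = 0.15.
* ``dense20`` — a 4 x 5 grid with spacing 0.2, r = 0.21: rook adjacency,
  31 edges, lesion centred on the grid.
"""

from __future__ import annotations

import numpy as np

from .dynamics import DynamicsParams
from .graph import SpatialGraph, build_graph

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("chain3", "star5", "handplaced5", "dense20")


def make_fixture(name: str) -> tuple[SpatialGraph, DynamicsParams]:
    if name == "chain3":
        coords = [(0.4, 0.5), (0.5, 0.5), (0.6, 0.5)]
        g = build_graph(np.array(coords), r=0.15)
        params = DynamicsParams(roi0=0.05, lesion_center=(0.5, 0.5))
    elif name == "star5":
        coords = [(0.5, 0.5), (0.64, 0.5), (0.36, 0.5), (0.5, 0.64), (0.5, 0.36)]
        g = build_graph(np.array(coords), r=0.15)
        params = DynamicsParams(roi0=0.05, lesion_center=(0.5, 0.5))
    elif name == "handplaced5":
        coords = [(0.1, 0.1), (0.2, 0.1), (0.15, 0.2), (0.8, 0.8), (0.9, 0.85)]
        g = build_graph(np.array(coords), r=0.15)
        params = DynamicsParams(roi0=0.12, lesion_center=(0.15, 0.13))
    elif name == "dense20":
        xs = 0.15 + 0.2 * np.arange(4)
        ys = 0.1 + 0.2 * np.arange(5)
        coords = np.array([(x, y) for y in ys for x in xs])
        g = build_graph(coords, r=0.21)
        params = DynamicsParams(roi0=0.11, lesion_center=(0.45, 0.5))
    else:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return g, params
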