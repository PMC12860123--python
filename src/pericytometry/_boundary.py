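"""Outer-boundary tracing and chain-length perimeter estimators.

Moore-neighbour tracing of the outer boundary of a filled region yields a
closed 8-connected chain of boundary pixels; the perimeter is estimated
from the chain's step codes.  Three estimators are provided:

``corner_corrected``
    Vossepoel-Smeulders weights: 0.980 per axis step, 1.406 per diagonal
    step, -0.091 per direction change.  Accurate to well under 1% on
    digitized circles, with error shrinking as resolution grows.
``chain``
    Plain Freeman chain length: 1 per axis step, sqrt(2) per diagonal.
``pixel_count``
    Number of boundary pixels (overestimates circular perimeters).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

# clockwise Moore neighbourhood starting West
_NBRS = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]

_VS_EVEN = 0.980
_VS_ODD = 1.406
_VS_CORNER = -0.091


def fill_and_select(mask: np.ndarray) -> np.ndarray:
    """Fill holes and keep the largest 8-connected component."""
    mask = ndi.binary_fill_holes(mask)
    lbl, n = ndi.label(mask, structure=np.ones((3, 3), bool))
    if n <= 1:
        return mask
    sizes = ndi.sum_labels(mask, lbl, index=np.arange(1, n + 1))
    return lbl == (1 + int(np.argmax(sizes)))


def trace_outer_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-trace the outer boundary; returns the chain of step vectors.

    ``mask`` must be a single filled component.  An isolated pixel yields
    an empty chain.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    r0 = rows.min()
    c0 = cols[rows == r0].min()
    start = (int(r0), int(c0))

    h, w = mask.shape

    def inside(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    chain: list[tuple[int, int]] = []
    cur = start
    prev = (start[0] - 1, start[1])  # North of the topmost pixel is outside
    first_step = None
    max_steps = 8 * int(mask.sum()) + 8
    while True:
        d = (prev[0] - cur[0], prev[1] - cur[1])
        i = _NBRS.index(d)
        nxt = None
        for k in range(1, 9):
            cand_dir = _NBRS[(i + k) % 8]
            cand = (cur[0] + cand_dir[0], cur[1] + cand_dir[1])
            if inside(cand):
                nxt = cand
                prev = (
                    cur[0] + _NBRS[(i + k - 1) % 8][0],
                    cur[1] + _NBRS[(i + k - 1) % 8][1],
                )
                break
        if nxt is None:
            return []  # isolated pixel
        step = (nxt[0] - cur[0], nxt[1] - cur[1])
        if cur == start and first_step is not None and step == first_step:
            break  # back at start, repeating the first move: loop closed
        if first_step is None:
            first_step = step
        chain.append(step)
        cur = nxt
        if len(chain) > max_steps:  # pragma: no cover - safety net
            raise RuntimeError("boundary tracing failed to terminate")
    return chain


def chain_length(chain: list[tuple[int, int]], metric: str) -> float:
    """Length in pixel units of a closed chain under the given metric."""
    if not chain:
        return 0.0
    if metric == "pixel_count":
        return float(len(chain))
    diag = sum(1 for d in chain if d[0] != 0 and d[1] != 0)
    axis = len(chain) - diag
    if metric == "chain":
        return axis + diag * np.sqrt(2.0)
    if metric == "corner_corrected":
        corners = sum(
            1 for a, b in zip(chain, chain[1:] + chain[:1]) if a != b
        )
        return _VS_EVEN * axis + _VS_ODD * diag + _VS_CORNER * corners
    raise ValueError(f"unknown perimeter metric {metric!r}")


def region_perimeter_px(mask: np.ndarray, metric: str = "corner_corrected") -> float:
    """Perimeter of the filled largest component of ``mask``, in pixels.

    Degenerate regions whose traced chain has fewer than 3 steps fall back
    to the unit-square exposed-edge count (a lone pixel has perimeter 4).
    """
    region = fill_and_select(mask)
    chain = trace_outer_boundary(region)
    if len(chain) < 3:
        # count exposed unit-square edges
        padded = np.pad(region, 1)
        edges = 0
        for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            edges += int((padded & ~np.roll(padded, shift, axis=ax)).sum())
        return float(edges)
    return chain_length(chain, metric)
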