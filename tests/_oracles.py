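"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: component
labelling is a hand-rolled flood fill, centroids are plain coordinate
means, and selection applies the two detection constraints by exhaustive
filtering.
"""

from __future__ import annotations

import numpy as np


def flood_fill_regions(pmap: np.ndarray, support: float, connectivity: int) -> list[dict]:
    """All connected components of {pmap >= support} by BFS flood fill."""
    h, w = pmap.shape
    mask = pmap >= support
    seen = np.zeros((h, w), dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    regions = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            coords = []
            while stack:
                r, c = stack.pop()
                coords.append((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            coords = sorted(coords)
            vals = [pmap[r, c] for r, c in coords]
            rows = [r for r, _ in coords]
            cols = [c for _, c in coords]
            regions.append(
                {
                    "coords": coords,
                    "area": len(coords),
                    "max": max(vals),
                    "centroid": (sum(rows) / len(rows), sum(cols) / len(cols)),
                }
            )
    return regions


def brute_force_detect(
    pmap: np.ndarray,
    prob_threshold: float = 0.5,
    support_threshold: float = 0.1,
    min_area: int = 50,
    connectivity: int = 8,
) -> dict | None:
    """Exhaustive reference for region selection: threshold, flood fill,
    filter by max value and area, pick max probability with larger-area and
    topmost-leftmost-centroid tie-breaks."""
    regions = flood_fill_regions(np.asarray(pmap, dtype=float), support_threshold, connectivity)
    survivors = [r for r in regions if r["max"] >= prob_threshold and r["area"] >= min_area]
    if not survivors:
        return None
    return min(survivors, key=lambda r: (-r["max"], -r["area"], r["centroid"]))
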