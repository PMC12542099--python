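"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — BFS flood fill, exhaustive
enumeration, permutation resampling — and shares no code path with the
implementation under test.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy.stats import rankdata
from shapely.geometry import MultiPoint, Point


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    components = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    cr, cc = queue.popleft()
                    comp.add((cr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = cr + dr, cc + dc
                            if (
                                0 <= nr < mask.shape[0]
                                and 0 <= nc < mask.shape[1]
                                and mask[nr, nc]
                                and not seen[nr, nc]
                            ):
                                seen[nr, nc] = True
                                queue.append((nr, nc))
                components.append(comp)
    components.sort(key=lambda comp: min(comp))
    return components


def _hole_mask(cells: set[tuple[int, int]], diagonal: bool) -> np.ndarray:
    """Background pockets of a component not reachable from outside.

    ``diagonal`` selects whether the background flood may pass through
    diagonal gaps (8-connectivity) or not (4-connectivity).
    """
    rows = [r for r, _ in cells]
    cols = [c for _, c in cells]
    r0, r1 = min(rows) - 1, max(rows) + 1
    c0, c1 = min(cols) - 1, max(cols) + 1
    outside = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    comp = np.zeros_like(outside)
    for r, c in cells:
        comp[r - r0, c - c0] = True
    steps = (
        [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
         if (dr, dc) != (0, 0)]
        if diagonal
        else [(1, 0), (-1, 0), (0, 1), (0, -1)]
    )
    queue = deque([(0, 0)])
    outside[0, 0] = True
    while queue:
        cr, cc = queue.popleft()
        for dr, dc in steps:
            nr, nc = cr + dr, cc + dc
            if (
                0 <= nr < outside.shape[0]
                and 0 <= nc < outside.shape[1]
                and not comp[nr, nc]
                and not outside[nr, nc]
            ):
                outside[nr, nc] = True
                queue.append((nr, nc))
    return ~comp & ~outside


def flood_fill_components_4(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """4-connected components by BFS (for hole counting)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    components = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    cr, cc = queue.popleft()
                    comp.add((cr, cc))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        nr, nc = cr + dr, cc + dc
                        if (
                            0 <= nr < mask.shape[0]
                            and 0 <= nc < mask.shape[1]
                            and mask[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                components.append(comp)
    return components


def convex_area(cells: set[tuple[int, int]]) -> int:
    """Convex-hull area in cells.

    Each cell contributes a diamond of edge midpoints (r±1/2, c) and
    (r, c±1/2); a cell counts when its center lies inside the hull of
    those points, boundary included.
    """
    corners = []
    for r, c in cells:
        corners += [(r - 0.5, c), (r + 0.5, c), (r, c - 0.5), (r, c + 0.5)]
    hull = MultiPoint(corners).convex_hull.buffer(1e-9)
    rows = [r for r, _ in cells]
    cols = [c for _, c in cells]
    count = 0
    for r in range(min(rows), max(rows) + 1):
        for c in range(min(cols), max(cols) + 1):
            if hull.contains(Point(r, c)):
                count += 1
    return count


def component_summary(cells: set[tuple[int, int]]) -> dict[str, float]:
    """area / filled_area / convex_area / euler_number, brute force.

    For an 8-connected component the Euler number pairs with
    4-connected holes (a diagonal foreground chain encloses), while
    hole *filling* treats the background as 8-connected (a diagonal
    background gap leaks) — the standard complementary-connectivity
    pairing for each operation.
    """
    holes_4 = _hole_mask(cells, diagonal=False)
    holes_8 = _hole_mask(cells, diagonal=True)
    n_holes = len(flood_fill_components_4(holes_4))
    return {
        "area": float(len(cells)),
        "filled_area": float(len(cells) + int(holes_8.sum())),
        "convex_area": float(convex_area(cells)),
        "euler_number": float(1 - n_holes),
    }


def pair_enumeration_auc(y_true, scores) -> float:
    """AUC by exhaustive positive/negative pair comparison."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = concordant = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                concordant += 1
            elif p == q:
                concordant += 0.5
    return concordant / total


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x: int) -> float:
        y = col1 - x
        if y < 0 or y > row2 or x > row1:
            return 0.0
        return (
            math.comb(row1, x) * math.comb(row2, y) / math.comb(n, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def permutation_spearman_p(x, y, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for Spearman's rho (midranks)."""
    rng = np.random.default_rng(seed)
    rx = rankdata(x)
    ry = rankdata(y)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    observed = abs(rho(rx, ry))
    hits = 0
    for _ in range(n_perm):
        hits += abs(rho(rx, rng.permutation(ry))) >= observed - 1e-12
    return (hits + 1) / (n_perm + 1)
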