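"""Independent reference implementations used only to check the package.

These are deliberately written without reusing any code path from
``calpain_ppi``: the SASA oracle uses seeded random sphere points and an
O(n^2) all-pairs occlusion test instead of a Fibonacci lattice with a
KD-tree; the consensus oracle ranks by explicit sorting with manual tie
averaging instead of ``scipy.stats.rankdata``.
"""

from __future__ import annotations

import numpy as np


def brute_force_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 16384,
    seed: int = 20240917,
) -> np.ndarray:
    """Per-atom SASA by Monte-Carlo quadrature with all-pairs occlusion."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    n = len(coords)
    out = np.empty(n)
    for i in range(n):
        r = radii[i] + probe
        surface = coords[i] + r * pts
        free = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            rj = radii[j] + probe
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            free &= d2 > rj * rj
        out[i] = 4.0 * np.pi * r * r * free.mean()
    return out


def brute_force_consensus(table: dict[str, dict[str, float]]) -> list[str]:
    """Consensus order of mutation labels from {predictor: {label: ddG}}.

    Per predictor: sort the scored labels by descending ddG and assign each
    the average of the 1-based positions of its value group (fractional
    ranks for ties).  Order labels by mean rank over the predictors that
    scored them; ties by larger mean ddG_binding, then label.
    """
    labels = sorted({m for scores in table.values() for m in scores})
    ranks: dict[str, list[float]] = {m: [] for m in labels}
    for scores in table.values():
        present = sorted(scores, key=lambda m: (-scores[m], m))
        pos = 0
        while pos < len(present):
            same = [m for m in present if scores[m] == scores[present[pos]]]
            first = present.index(same[0]) + 1
            avg = (first + first + len(same) - 1) / 2.0
            for m in same:
                ranks[m].append(avg)
            pos += len(same)
    def avg_binding(m: str) -> float:
        vals = [s[m] for s in table.values() if m in s]
        return sum(vals) / len(vals)

    def subunit_position(m: str) -> tuple[str, int]:
        sub, rest = m.split(":")
        return sub, int(rest)

    return sorted(
        labels,
        key=lambda m: (
            sum(ranks[m]) / len(ranks[m]),
            -avg_binding(m),
            subunit_position(m),
        ),
    )
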