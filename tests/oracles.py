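"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by the most direct means available —
linear-programming feasibility, exhaustive pixel loops, pairwise counting —
deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def hull_vertex_set(points: np.ndarray) -> set[tuple[float, float]]:
    """Convex-hull vertices by LP: a point is a vertex iff it is NOT a convex
    combination of the other points."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    vertices = set()
    for i, p in enumerate(pts):
        others = np.delete(pts, i, axis=0)
        if len(others) == 0:
            vertices.add(tuple(p))
            continue
        # find lambda >= 0 with sum(lambda) = 1 and others^T lambda = p
        a_eq = np.vstack([others.T, np.ones(len(others))])
        b_eq = np.append(p, 1.0)
        res = linprog(
            c=np.zeros(len(others)), A_eq=a_eq, b_eq=b_eq,
            bounds=[(0, None)] * len(others), method="highs",
        )
        if not res.success:
            vertices.add(tuple(p))
    return vertices


def pair_features_pixel_loop(
    temps_a: np.ndarray, temps_b: np.ndarray, delta_t: float
) -> tuple[float, float, int, float]:
    """The four per-view asymmetry statistics by explicit python loops."""
    def mean(xs):
        return sum(xs) / len(xs)

    def mad(xs):
        m = mean(xs)
        return sum(abs(x - m) for x in xs) / len(xs)

    a = [float(x) for x in temps_a]
    b = [float(x) for x in temps_b]
    d_mean = abs(mean(a) - mean(b))
    d_max = abs(max(a) - max(b))
    warm, cool = (a, b) if mean(a) >= mean(b) else (b, a)
    cut = max(cool) + delta_t
    n = sum(1 for x in warm if x > cut)
    d_dev = abs(mad(a) - mad(b))
    return d_mean, d_max, n, d_dev


def nearest_neighbor_label(x: np.ndarray, train: np.ndarray, labels: np.ndarray) -> int:
    """1-NN label by exhaustive distance sort; ties to the lowest row index."""
    dists = [(float(np.sqrt(((row - x) ** 2).sum())), i) for i, row in enumerate(train)]
    dists.sort()  # distance first, then index: lowest index wins ties
    return int(labels[dists[0][1]])


def auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the fraction of concordant (T, NT) score pairs, ties counting 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def ellipse_boundary_points(
    center_rc: tuple[float, float], a: float, b: float, angle_from_col_deg: float,
    n: int = 4000,
) -> np.ndarray:
    """Dense sampling of an ellipse boundary, (row, col)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    th = np.radians(angle_from_col_deg)
    major = np.array([np.sin(th), np.cos(th)])   # (row, col)
    minor = np.array([np.cos(th), -np.sin(th)])
    return (
        np.asarray(center_rc)
        + np.outer(a * np.cos(t), major)
        + np.outer(b * np.sin(t), minor)
    )


def welch_t(sample_x: np.ndarray, sample_y: np.ndarray) -> tuple[float, float]:
    """Welch's t statistic and degrees of freedom from the textbook formulas."""
    x = np.asarray(sample_x, float)
    y = np.asarray(sample_y, float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) / nx
    vy = y.var(ddof=1) / ny
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    return float(t), float(df)
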