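"""Independent oracles used by the test suite.

These are deliberately written in plain Python / brute force, sharing no
code path with the package implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def tn93_tally(a: str, b: str):
    """Per-site tally of a sequence pair: (n, P1, P2, Q, (gA,gC,gG,gT))."""
    n = ts_ag = ts_ct = tv = 0
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for x, y in zip(a.upper(), b.upper()):
        if x in counts and y in counts:
            n += 1
            counts[x] += 1
            counts[y] += 1
            if x != y:
                if {x, y} == {"A", "G"}:
                    ts_ag += 1
                elif {x, y} == {"C", "T"}:
                    ts_ct += 1
                else:
                    tv += 1
    if n == 0:
        return None
    freqs = tuple(counts[c] / (2 * n) for c in "ACGT")
    return n, ts_ag / n, ts_ct / n, tv / n, freqs


def tn93_oracle(a: str, b: str) -> float:
    """Direct evaluation of the TN93 closed form from a plain-python tally."""
    tally = tn93_tally(a, b)
    assert tally is not None, "no comparable sites"
    _, p1, p2, q, (ga, gc, gg, gt) = tally
    gr, gy = ga + gg, gc + gt
    assert ga * gg > 0 and gc * gt > 0, "degenerate base frequencies"
    d = (
        -(2 * ga * gg / gr) * math.log(1 - gr * p1 / (2 * ga * gg) - q / (2 * gr))
        - (2 * gt * gc / gy) * math.log(1 - gy * p2 / (2 * gt * gc) - q / (2 * gy))
        - 2
        * (gr * gy - ga * gg * gy / gr - gt * gc * gr / gy)
        * math.log(1 - q / (2 * gr * gy))
    )
    return d


def kimura2p(p: float, q: float) -> float:
    """Kimura two-parameter distance from transition/transversion proportions."""
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def random_pair(rng: np.random.Generator, length: int = 200,
                sub_prob: float = 0.12) -> tuple[str, str]:
    """A random sequence and a noisy copy (iid substitutions)."""
    bases = "ACGT"
    a = rng.integers(0, 4, size=length)
    b = a.copy()
    hit = rng.random(length) < sub_prob
    b[hit] = (b[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    to_str = lambda arr: "".join(bases[i] for i in arr)
    return to_str(a), to_str(b)


def procrustes_m2_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Brute-force minimum residual sum of squares over planar rotation,
    optional reflection, and non-negative scale (2-column inputs only)."""
    assert x.shape[1] == 2 and y.shape[1] == 2
    trace_x = float((x * x).sum())
    trace_y = float((y * y).sum())

    def m2_at(theta: float, reflect: bool) -> float:
        c, s = math.cos(theta), math.sin(theta)
        r = np.array([[c, -s], [s, c]])
        if reflect:
            r = r @ np.diag([1.0, -1.0])
        num = float((x * (y @ r)).sum())  # trace(X' Y R)
        num = max(num, 0.0)
        return trace_x - num**2 / trace_y

    best = math.inf
    thetas = np.linspace(0.0, 2 * math.pi, 2001)
    for reflect in (False, True):
        values = [m2_at(t, reflect) for t in thetas]
        i = int(np.argmin(values))
        lo = thetas[max(i - 1, 0)]
        hi = thetas[min(i + 1, len(thetas) - 1)]
        res = minimize_scalar(
            lambda t: m2_at(t, reflect), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        best = min(best, float(res.fun))
    return best


def random_centered(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    m = rng.normal(size=(rows, cols))
    return m - m.mean(axis=0, keepdims=True)
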