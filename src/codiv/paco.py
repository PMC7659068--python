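"""Procrustean co-phylogeny test (PACo) on genetic distance matrices.

The method asks whether parasite genetic divergence tracks host divergence
across the observed host-parasite association links:

1. Both distance matrices are embedded by principal coordinates analysis.
2. Host and parasite coordinates are expanded to one row per association
   link (a host infected by several parasites contributes one row per
   link), the narrower configuration zero-padded to common width, and both
   column-centered.
3. The parasite configuration is superimposed on the host configuration by
   least-squares Procrustes (rotation + scaling); the residual sum of
   squares m2_XY is the global goodness-of-fit statistic — small m2 means
   congruent divergence.
4. Significance comes from a permutation null that randomly reassigns
   hosts to parasites across the links; the contribution of each link is
   estimated by a leave-one-link-out jackknife on its squared residual,
   with a one-sided upper 95% confidence bound.

Ambiguous haplogroup assignments expand into alternative link sets;
``conservative_paco`` evaluates all of them and reports the least
significant (maximum P) one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io import DistanceMatrix, InfectionTable

__all__ = [
    "PcoaResult",
    "AssociationData",
    "LinkResidual",
    "PacoResult",
    "pcoa",
    "link_expand",
    "procrustes_m2",
    "paco_test",
    "jackknife_links",
    "conservative_paco",
    "association_from_infections",
]

Link = tuple[str, str]


@dataclass(frozen=True)
class PcoaResult:
    """Principal coordinates: labels, coordinates (rows = labels, columns =
    retained axes, scaled by sqrt(eigenvalue)), and the retained eigenvalues
    in descending order."""

    labels: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    def row(self, label: str) -> np.ndarray:
        try:
            return self.coordinates[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no coordinates for label '{label}'") from None


@dataclass(frozen=True)
class AssociationData:
    """Bipartite host-parasite links plus the alternative link sets that
    ambiguous observations expand into.

    ``links`` is the first (canonical) alternative; ``alternatives``
    contains every hypothesis, including the canonical one.
    """

    hosts: tuple[str, ...]
    parasites: tuple[str, ...]
    links: tuple[Link, ...]
    alternatives: tuple[tuple[Link, ...], ...] = ()

    def __post_init__(self) -> None:
        alts = self.alternatives or (self.links,)
        object.__setattr__(self, "alternatives", tuple(tuple(a) for a in alts))
        for alt in self.alternatives:
            if len(set(alt)) != len(alt):
                raise ValueError("duplicate links in an alternative")
            if len(alt) < 3:
                raise ValueError("each alternative needs at least 3 links")
        covered_h = {h for alt in self.alternatives for h, _ in alt}
        covered_p = {p for alt in self.alternatives for _, p in alt}
        if not set(self.hosts) <= covered_h:
            raise ValueError("some hosts appear in no alternative's links")
        if not set(self.parasites) <= covered_p:
            raise ValueError("some parasites appear in no alternative's links")

    @property
    def n_links(self) -> int:
        return len(self.links)


@dataclass(frozen=True)
class LinkResidual:
    host: str
    parasite: str
    observed: float
    jackknife_estimate: float
    upper_ci: float


@dataclass(frozen=True)
class PacoResult:
    m2_global: float
    p_value: float
    n_permutations: int
    seed: int
    link_residuals: tuple[LinkResidual, ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("permutation p-value must be in (0, 1]")
        total = sum(lr.observed for lr in self.link_residuals)
        if not math.isclose(total, self.m2_global, rel_tol=0, abs_tol=1e-9):
            raise ValueError("per-link residuals do not sum to m2_global")


# ---------------------------------------------------------------------------
# Principal coordinates


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making a distance matrix Euclidean."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    f1 = -0.5 * j @ (d * d) @ j
    f2 = -0.5 * j @ d @ j
    upper = np.block([[np.zeros((n, n)), 2.0 * f1], [-np.eye(n), -4.0 * f2]])
    eig = np.linalg.eigvals(upper)
    return float(max(np.real(eig).max(), 0.0))


def pcoa(
    dm: DistanceMatrix, tolerance: float = 1e-8, correction: str | None = None
) -> PcoaResult:
    """Principal coordinates analysis of a complete distance matrix.

    Gower-centers -0.5 * d^2, eigendecomposes, and retains the axes whose
    eigenvalue exceeds ``tolerance`` times the largest. Negative eigenvalues
    (non-Euclidean input) are dropped; ``correction='cailliez'`` instead
    adds the smallest constant to the off-diagonal distances that makes
    them Euclidean before embedding.
    """
    if not dm.is_complete:
        missing = np.argwhere(~np.isfinite(dm.values))
        i, j = missing[0]
        raise ValueError(
            "distance matrix has missing entries (first at "
            f"{dm.labels[i]}, {dm.labels[j]}); PACo needs a complete matrix"
        )
    d = dm.values.astype(float)
    if correction == "cailliez":
        c = _cailliez_constant(d)
        if c > 0:
            d = d + c
            np.fill_diagonal(d, 0.0)
    elif correction is not None:
        raise ValueError(f"unknown correction '{correction}'")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    if eigval[0] <= tolerance:
        raise ValueError("degenerate distance matrix: no positive eigenvalue")
    keep = eigval > tolerance * eigval[0]
    eigval = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(eigval)
    return PcoaResult(dm.labels, coords, eigval)


# ---------------------------------------------------------------------------
# Link expansion and Procrustes superimposition


def _expand_rows(
    x: PcoaResult, y: PcoaResult, links: Sequence[Link]
) -> tuple[np.ndarray, np.ndarray]:
    """Uncentered link-expanded configurations, zero-padded to common width."""
    hx = {l: i for i, l in enumerate(x.labels)}
    py = {l: i for i, l in enumerate(y.labels)}
    for h, p in links:
        if h not in hx:
            raise KeyError(f"host '{h}' not in host coordinate labels")
        if p not in py:
            raise KeyError(f"parasite '{p}' not in parasite coordinate labels")
    xrows = x.coordinates[[hx[h] for h, _ in links]]
    yrows = y.coordinates[[py[p] for _, p in links]]
    k = max(xrows.shape[1], yrows.shape[1])
    if xrows.shape[1] < k:
        xrows = np.pad(xrows, ((0, 0), (0, k - xrows.shape[1])))
    if yrows.shape[1] < k:
        yrows = np.pad(yrows, ((0, 0), (0, k - yrows.shape[1])))
    return xrows, yrows


def _center(m: np.ndarray) -> np.ndarray:
    return m - m.mean(axis=0, keepdims=True)


def link_expand(
    x: PcoaResult, y: PcoaResult, links: Sequence[Link]
) -> tuple[np.ndarray, np.ndarray]:
    """One coordinate row per association link, column-centered.

    Row l of the first matrix is the host coordinates of link l, of the
    second the parasite coordinates; a taxon in several links contributes
    one row per link. The narrower configuration is zero-padded to the
    common axis count before centering.
    """
    xrows, yrows = _expand_rows(x, y, links)
    return _center(xrows), _center(yrows)


def procrustes_m2(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Least-squares Procrustes fit of y onto x with rotation and scaling.

    Returns the residual sum of squares m2 and the per-row squared
    residuals. Both inputs must be column-centered and of equal shape.
    The closed form m2 = tr(X'X) - (sum sigma)^2 / tr(Y'Y) is checked
    against the explicit residual sum; they must agree to 1e-9.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("configurations must have equal shapes")
    if np.max(np.abs(x.mean(axis=0)), initial=0) > 1e-9 or np.max(
        np.abs(y.mean(axis=0)), initial=0
    ) > 1e-9:
        raise ValueError("configurations must be column-centered")
    trace_y = float((y * y).sum())
    if trace_y == 0.0:
        raise ValueError("parasite configuration is all zeros: scale undefined")
    m = y.T @ x
    u, sigma, vt = np.linalg.svd(m)
    scale = sigma.sum() / trace_y
    fitted = scale * y @ (u @ vt)
    residuals = ((x - fitted) ** 2).sum(axis=1)
    m2 = float(residuals.sum())
    trace_x = float((x * x).sum())
    m2_closed = trace_x - sigma.sum() ** 2 / trace_y
    if not math.isclose(m2, m2_closed, rel_tol=0, abs_tol=max(1e-9, 1e-12 * trace_x)):
        raise AssertionError(
            f"Procrustes residual sum {m2} disagrees with closed form {m2_closed}"
        )
    return m2, residuals


def _m2_closed(xc: np.ndarray, yc: np.ndarray) -> float:
    sigma = np.linalg.svd(yc.T @ xc, compute_uv=False)
    return float((xc * xc).sum() - sigma.sum() ** 2 / (yc * yc).sum())


# ---------------------------------------------------------------------------
# Permutation test and jackknife


def _permutation_m2(
    xc: np.ndarray, yc: np.ndarray, n_perm: int, rng: np.random.Generator,
    chunk: int = 4096,
) -> np.ndarray:
    """Null m2 values: hosts randomly reassigned to parasites across links.

    Permuting the host components of the link list permutes the rows of the
    centered host configuration (the row multiset, hence the centering and
    tr(X'X), are unchanged), so only the pairing term needs recomputing.
    """
    ell = xc.shape[0]
    trace_x = float((xc * xc).sum())
    trace_y = float((yc * yc).sum())
    out = np.empty(n_perm, dtype=float)
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((size, ell)), axis=1)
        xp = xc[perms]  # (size, L, k)
        m = np.einsum("lj,plk->pjk", yc, xp)
        sigma = np.linalg.svd(m, compute_uv=False)
        out[done : done + size] = trace_x - sigma.sum(axis=1) ** 2 / trace_y
        done += size
    return out


def _jackknife(xc: np.ndarray, yc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ell = xc.shape[0]
    if ell < 4:
        raise ValueError("jackknife needs at least 4 links")
    _, r2_full = procrustes_m2(xc, yc)
    pseudo = np.full((ell, ell), np.nan)  # pseudo[i, j] for deletion j
    keep_all = np.arange(ell)
    for j in range(ell):
        keep = keep_all[keep_all != j]
        xj = _center(xc[keep])
        yj = _center(yc[keep])
        _, r2_del = procrustes_m2(xj, yj)
        pseudo[keep, j] = ell * r2_full[keep] - (ell - 1) * r2_del
    tcrit = float(sps.t.ppf(0.95, ell - 2))
    estimates = np.empty(ell)
    upper = np.empty(ell)
    for i in range(ell):
        vals = pseudo[i, np.isfinite(pseudo[i])]
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        estimates[i] = max(mean, 0.0)
        upper[i] = estimates[i] + tcrit * se
    return estimates, upper


def jackknife_links(
    dh: DistanceMatrix,
    dp: DistanceMatrix,
    links: Sequence[Link],
    tolerance: float = 1e-8,
    correction: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-link-out jackknife of per-link squared residuals.

    The coordinates come from one PCoA per matrix (never recomputed per
    deletion); for each deleted link j the remaining link rows are
    re-centered and refit, giving residuals r2_i(-j). Pseudovalues
    nu_ij = L*r2_i(full) - (L-1)*r2_i(-j) are averaged over j != i,
    truncated below at zero, and given a one-sided upper 95% confidence
    bound using Student's t with L-2 degrees of freedom.

    Returns (estimates, upper bounds), one entry per link, in link order.
    Requires L >= 4 links. Small estimates mark links that support the
    co-phylogeny signal; large ones mark candidate host shifts.
    """
    links = tuple(links)
    if len(links) < 4:
        raise ValueError("jackknife needs at least 4 links")
    host_labels = tuple(dict.fromkeys(h for h, _ in links))
    para_labels = tuple(dict.fromkeys(p for _, p in links))
    px = pcoa(dh.submatrix(host_labels), tolerance=tolerance, correction=correction)
    py = pcoa(dp.submatrix(para_labels), tolerance=tolerance, correction=correction)
    xc, yc = link_expand(px, py, links)
    return _jackknife(xc, yc)


def paco_test(
    dh: DistanceMatrix,
    dp: DistanceMatrix,
    links: Sequence[Link],
    n_perm: int = 999,
    seed: int = 0,
    force: bool = False,
    with_jackknife: bool = True,
    tolerance: float = 1e-8,
    correction: str | None = None,
) -> PacoResult:
    """Global PACo test of host-parasite co-divergence.

    ``links`` are (host label, parasite label) pairs resolving into ``dh``
    and ``dp``. The permutation null reassigns hosts to parasites uniformly
    at random across the links; the p-value uses the add-one convention
    p = (1 + #{m2_perm <= m2_obs}) / (n_perm + 1), ties counting as at
    least as extreme. Fewer than 99 permutations are refused unless
    ``force=True``.
    """
    links = tuple(links)
    if len(links) < 3:
        raise ValueError("need at least 3 association links")
    if n_perm < 99 and not force:
        raise ValueError(
            "n_perm < 99 gives too coarse a p-value; pass force=True to override"
        )
    host_labels = tuple(dict.fromkeys(h for h, _ in links))
    para_labels = tuple(dict.fromkeys(p for _, p in links))
    px = pcoa(dh.submatrix(host_labels), tolerance=tolerance, correction=correction)
    py = pcoa(dp.submatrix(para_labels), tolerance=tolerance, correction=correction)
    xc, yc = link_expand(px, py, links)
    m2_obs, r2 = procrustes_m2(xc, yc)
    m2_obs_closed = _m2_closed(xc, yc)

    rng = np.random.default_rng(seed)
    null = _permutation_m2(xc, yc, n_perm, rng)
    p = (1 + int(np.count_nonzero(null <= m2_obs_closed + 1e-12))) / (n_perm + 1)

    if with_jackknife and len(links) >= 4:
        estimates, upper = _jackknife(xc, yc)
    else:
        estimates = np.full(len(links), np.nan)
        upper = np.full(len(links), np.nan)
    link_res = tuple(
        LinkResidual(h, par, float(r2[i]), float(estimates[i]), float(upper[i]))
        for i, (h, par) in enumerate(links)
    )
    return PacoResult(
        m2_global=m2_obs,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        link_residuals=link_res,
    )


def _alternative_seed(seed: int, index: int) -> int:
    """Deterministic per-alternative sub-seed derived from the user seed."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def conservative_paco(
    dh: DistanceMatrix,
    dp: DistanceMatrix,
    assoc: AssociationData,
    n_perm: int = 999,
    seed: int = 0,
    max_alternatives: int = 64,
    **kwargs,
) -> tuple[PacoResult, tuple[PacoResult, ...]]:
    """Run PACo for every ambiguity alternative; report the max-P one.

    Every alternative link set gets its own deterministic sub-seed derived
    from ``seed``. The selected result is the least significant (highest
    p-value, first such index on ties) — the conservative choice when
    ambiguous observations admit several association hypotheses.
    """
    if len(assoc.alternatives) == 0:
        raise ValueError("association data has no alternatives")
    if len(assoc.alternatives) > max_alternatives:
        raise ValueError(
            f"{len(assoc.alternatives)} alternatives exceed the cap of "
            f"{max_alternatives}; reduce the ambiguous observations manually"
        )
    results = tuple(
        paco_test(dh, dp, alt, n_perm=n_perm, seed=_alternative_seed(seed, i), **kwargs)
        for i, alt in enumerate(assoc.alternatives)
    )
    selected = max(results, key=lambda r: r.p_value)
    return selected, results


def association_from_infections(table: InfectionTable) -> AssociationData:
    """Expand an infection table into association data with alternatives.

    Each observation contributes a (host, candidate) link; ambiguous
    observations multiply into one alternative link set per combination of
    their candidates (Cartesian product, ambiguous rows in input order).
    Within each alternative, duplicate links collapse.
    """
    hosts = tuple(dict.fromkeys(r.host for r in table.rows))
    parasites = tuple(
        dict.fromkeys(c for r in table.rows for c in r.candidates)
    )
    ambiguous = [r for r in table.rows if r.ambiguous]
    choices = list(itertools.product(*(r.candidates for r in ambiguous)))
    alternatives = []
    for combo in choices or [()]:
        pick = dict(zip((r.observation for r in ambiguous), combo))
        links = tuple(
            dict.fromkeys(
                (r.host, pick.get(r.observation, r.candidates[0]))
                for r in table.rows
            )
        )
        alternatives.append(links)
    return AssociationData(
        hosts=hosts,
        parasites=parasites,
        links=alternatives[0],
        alternatives=tuple(alternatives),
    )
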