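"""Pairwise Tamura-Nei (1993) genetic distances on partial alignments.

TN93 distinguishes the two transition types (A<->G within purines, C<->T
within pyrimidines) from transversions and allows unequal base frequencies.
Sites are compared under *pairwise deletion*: for each pair of sequences,
only columns inside both coverage intervals where both characters are one
of A, C, G, T count. Gaps, N and padding are excluded per pair, never
globally, so short fragments contribute whatever overlap they have.

Base frequencies are pooled per pair over the comparable sites of both
sequences (not taken from the whole alignment); this makes the estimate
robust when fragments cover different regions, at the price of small
numeric differences from tools that use alignment-wide frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import DistanceMatrix, PartialAlignment

__all__ = [
    "OverlapError",
    "SaturationError",
    "SaturationWarning",
    "Tn93PairStats",
    "pair_stats",
    "tn93_distance",
    "distance_matrix",
]

# Nucleotide codes: A,C,G,T -> 0..3; everything else (gap, N, padding) -> 4.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


class OverlapError(ValueError):
    """Two sequences share no comparable site."""


class SaturationError(ValueError):
    """The TN93 distance is undefined (a logarithm argument is <= 0)."""


class SaturationWarning(UserWarning):
    """A pair was too divergent for TN93; its distance is reported missing."""


def encode(aln: PartialAlignment) -> np.ndarray:
    """Integer-encode an alignment: (n_sequences, columns) uint8 array."""
    flat = np.frombuffer(
        "".join(aln.residues).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), aln.columns)
    return _CODE[flat]


@dataclass(frozen=True)
class Tn93PairStats:
    """Sufficient statistics of one sequence pair for the TN93 distance.

    ``n`` comparable sites; ``p1``/``p2`` are the proportions of A<->G and
    C<->T differences, ``q`` the proportion of transversion differences;
    ``freqs`` = (gA, gC, gG, gT) pooled over both sequences' comparable sites.
    """

    n: int
    p1: float
    p2: float
    q: float
    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("site count cannot be negative")
        if min(self.p1, self.p2, self.q) < 0 or self.p1 + self.p2 + self.q > 1 + 1e-12:
            raise ValueError("difference proportions must be in [0,1] and sum <= 1")
        if self.n > 0 and abs(sum(self.freqs) - 1.0) > 1e-12:
            raise ValueError("pooled base frequencies must sum to 1")


def _pair_stats_codes(a: np.ndarray, b: np.ndarray) -> Tn93PairStats:
    mask = (a < 4) & (b < 4)
    n = int(mask.sum())
    if n == 0:
        raise OverlapError("sequences share no comparable site")
    am = a[mask]
    bm = b[mask]
    diff = am != bm
    # A=0, C=1, G=2, T=3: a transition changes A<->G (0,2) or C<->T (1,3).
    ts1 = int(np.count_nonzero(diff & (am + bm == 2) & (am % 2 == 0)))
    ts2 = int(np.count_nonzero(diff & (am + bm == 4) & (am % 2 == 1)))
    nd = int(np.count_nonzero(diff))
    counts = np.bincount(am, minlength=4) + np.bincount(bm, minlength=4)
    freqs = counts / (2 * n)
    return Tn93PairStats(
        n=n,
        p1=ts1 / n,
        p2=ts2 / n,
        q=(nd - ts1 - ts2) / n,
        freqs=(float(freqs[0]), float(freqs[1]), float(freqs[2]), float(freqs[3])),
    )


def pair_stats(a: str, b: str) -> Tn93PairStats:
    """Tally comparable sites of two aligned, equal-length sequences.

    Raises
    ------
    OverlapError
        If no column has both characters in {A, C, G, T}.
    """
    if len(a) != len(b):
        raise ValueError("sequences must come from the same alignment (equal length)")
    ca = _CODE[np.frombuffer(a.encode("ascii"), dtype=np.uint8)]
    cb = _CODE[np.frombuffer(b.encode("ascii"), dtype=np.uint8)]
    return _pair_stats_codes(ca, cb)


def tn93_distance(stats: Tn93PairStats, on_saturation: str = "missing") -> float:
    """TN93 distance (substitutions/site) from pair statistics.

    With gR = gA+gG, gY = gC+gT the distance is

        d = -k1 ln(1 - P1/k1 - Q/(2 gR)) - k2 ln(1 - P2/k2 - Q/(2 gY))
            - k3 ln(1 - Q/(2 gR gY)),

        k1 = 2 gA gG / gR,  k2 = 2 gT gC / gY,
        k3 = 2 (gR gY - gA gG gY/gR - gT gC gR/gY).

    A term with zero coefficient and zero observed differences of its type
    contributes 0. If any required logarithm argument is <= 0 (saturation)
    or a needed frequency product vanishes while differences of that type
    were observed, the distance is undefined: returned as NaN with a
    ``SaturationWarning`` by default, or raised as ``SaturationError`` when
    ``on_saturation='error'``.
    """
    if on_saturation not in ("missing", "error"):
        raise ValueError("on_saturation must be 'missing' or 'error'")
    if stats.n <= 0:
        raise ValueError("no comparable sites")
    ga, gc, gg, gt = stats.freqs
    gr = ga + gg
    gy = gc + gt
    p1, p2, q = stats.p1, stats.p2, stats.q

    def _fail(reason: str) -> float:
        if on_saturation == "error":
            raise SaturationError(reason)
        warnings.warn(reason, SaturationWarning, stacklevel=3)
        return float("nan")

    d = 0.0
    k1 = 2.0 * ga * gg / gr if gr > 0 else 0.0
    k2 = 2.0 * gt * gc / gy if gy > 0 else 0.0
    if k1 > 0:
        arg = 1.0 - p1 / k1 - q / (2.0 * gr)
        if arg <= 0:
            return _fail("purine-transition term saturated (log argument <= 0)")
        d -= k1 * np.log(arg)
    elif p1 > 0:
        return _fail("A<->G differences observed but gA*gG = 0")
    if k2 > 0:
        arg = 1.0 - p2 / k2 - q / (2.0 * gy)
        if arg <= 0:
            return _fail("pyrimidine-transition term saturated (log argument <= 0)")
        d -= k2 * np.log(arg)
    elif p2 > 0:
        return _fail("C<->T differences observed but gC*gT = 0")
    if gr > 0 and gy > 0:
        k3 = 2.0 * (gr * gy - ga * gg * gy / gr - gt * gc * gr / gy)
        arg = 1.0 - q / (2.0 * gr * gy)
        if arg <= 0:
            return _fail("transversion term saturated (log argument <= 0)")
        d -= k3 * np.log(arg)
    elif q > 0:
        return _fail("transversions observed but one base class is absent")
    # Guard against -0.0 / tiny negative round-off for identical pairs.
    return max(float(d), 0.0)


def distance_matrix(aln: PartialAlignment, strict: bool = False) -> DistanceMatrix:
    """All-pairs TN93 distance matrix under pairwise deletion.

    In strict mode, any saturated or non-overlapping pair is an error;
    otherwise such entries are NaN (missing) with a warning, and downstream
    steps requiring a complete matrix will refuse them.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    codes = encode(aln)
    values = np.zeros((n, n), dtype=float)
    mode = "error" if strict else "missing"
    for i in range(n):
        for j in range(i + 1, n):
            try:
                stats = _pair_stats_codes(codes[i], codes[j])
            except OverlapError:
                if strict:
                    raise OverlapError(
                        f"no comparable sites between '{aln.labels[i]}' "
                        f"and '{aln.labels[j]}'"
                    ) from None
                warnings.warn(
                    f"pair ({aln.labels[i]}, {aln.labels[j]}) has no comparable "
                    "sites; distance set to missing",
                    SaturationWarning,
                    stacklevel=2,
                )
                values[i, j] = values[j, i] = float("nan")
                continue
            d = tn93_distance(stats, on_saturation=mode)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(aln.labels, values)
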