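"""Haplogroup clustering of variable-length sequences by diagnostic sites.

A haplogroup is a cluster of sequences separated from every other cluster
by at least one variable ("diagnostic") site within shared coverage. With
nested 5'-anchored fragments of different lengths, a short sequence may be
identical — over the region it covers — to the representatives of several
haplogroups whose diagnostic sites all lie beyond its end. Such sequences
are assigned *ambiguously* to every matching haplogroup: they carry a
candidate set rather than a membership, mirroring the downstream treatment
of ambiguity as alternative association hypotheses.

Clustering is greedy and deterministic: sequences are processed longest
coverage first (ties broken lexicographically by label), so every
representative is a maximal-information sequence and re-runs are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .distances import encode, pair_stats, tn93_distance
from .io import PartialAlignment

__all__ = [
    "UnassignableSequenceError",
    "Haplogroup",
    "HaplogroupPartition",
    "build_haplogroups",
    "assign_species",
]


class UnassignableSequenceError(ValueError):
    """A sequence shares no comparable site with any haplogroup representative."""


@dataclass(frozen=True)
class Haplogroup:
    """One haplogroup: members, its longest member as representative, and
    the alignment columns at which the representative differs from every
    other comparable representative."""

    id: str
    members: tuple[str, ...]
    representative: str
    diagnostic_sites: frozenset[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"haplogroup {self.id} has no members")
        if self.representative not in self.members:
            raise ValueError(f"representative of {self.id} is not a member")


@dataclass(frozen=True)
class HaplogroupPartition:
    """All haplogroups plus the (possibly ambiguous) per-sequence assignment.

    ``assignments`` maps every input label to a non-empty set of haplogroup
    ids; singletons are unambiguous members, larger sets are candidate-only
    sequences compatible with several groups.
    """

    haplogroups: tuple[Haplogroup, ...]
    assignments: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        ids = {h.id for h in self.haplogroups}
        for label, cands in self.assignments.items():
            if not cands:
                raise ValueError(f"sequence '{label}' has no assignment")
            if not cands <= ids:
                raise ValueError(f"sequence '{label}' assigned to unknown haplogroup")

    def __len__(self) -> int:
        return len(self.haplogroups)

    @property
    def ambiguous_labels(self) -> tuple[str, ...]:
        return tuple(
            sorted(l for l, c in self.assignments.items() if len(c) > 1)
        )

    def group(self, hg_id: str) -> Haplogroup:
        for h in self.haplogroups:
            if h.id == hg_id:
                return h
        raise KeyError(f"no haplogroup '{hg_id}'")


def _mismatches(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """(comparable sites, mismatches) for two integer-coded rows."""
    mask = (a < 4) & (b < 4)
    n = int(mask.sum())
    mm = int(np.count_nonzero(a[mask] != b[mask]))
    return n, mm


def build_haplogroups(aln: PartialAlignment) -> HaplogroupPartition:
    """Greedy longest-first haplogroup clustering.

    Each sequence is compared to every existing representative over the
    comparable sites they share. At least one mismatch against all
    representatives (with positive overlap) founds a new haplogroup; a
    perfect match with exactly one joins it; perfect matches with several
    yield an ambiguous candidate-only assignment that neither founds a
    group nor alters any representative. Diagnostic sites are recomputed
    from the final representatives.
    """
    if len(aln) == 0:
        raise ValueError("empty alignment")
    codes = encode(aln)
    order = sorted(
        range(len(aln)),
        key=lambda i: (-(aln.coverage[i][1] - aln.coverage[i][0]), aln.labels[i]),
    )
    rep_rows: list[int] = []            # seed row index per haplogroup
    members: list[list[int]] = []
    assignments: dict[str, frozenset[str]] = {}
    group_of_row: dict[int, int] = {}

    for i in order:
        label = aln.labels[i]
        compatible: list[int] = []
        any_overlap = False
        for g, rep in enumerate(rep_rows):
            n, mm = _mismatches(codes[i], codes[rep])
            if n > 0:
                any_overlap = True
                if mm == 0:
                    compatible.append(g)
        if rep_rows and not any_overlap:
            raise UnassignableSequenceError(
                f"sequence '{label}' shares no comparable site with any "
                "haplogroup representative"
            )
        if len(compatible) == 0:
            g = len(rep_rows)
            rep_rows.append(i)
            members.append([i])
            group_of_row[i] = g
        elif len(compatible) == 1:
            g = compatible[0]
            members[g].append(i)
            group_of_row[i] = g
        else:
            assignments[label] = frozenset(f"hg{g + 1:02d}" for g in compatible)

    for g, rows in enumerate(members):
        hg_id = f"hg{g + 1:02d}"
        for r in rows:
            assignments[aln.labels[r]] = frozenset({hg_id})

    diagnostic = _diagnostic_sites(codes, rep_rows)
    haplogroups = tuple(
        Haplogroup(
            id=f"hg{g + 1:02d}",
            members=tuple(aln.labels[r] for r in rows),
            representative=aln.labels[rep_rows[g]],
            diagnostic_sites=diagnostic[g],
        )
        for g, rows in enumerate(members)
    )
    return HaplogroupPartition(haplogroups, assignments)


def _diagnostic_sites(codes: np.ndarray, rep_rows: list[int]) -> list[frozenset[int]]:
    """Columns at which each representative differs from every other
    representative comparable at that column (and at least one is)."""
    k = len(rep_rows)
    out: list[frozenset[int]] = []
    reps = codes[rep_rows] if k else codes[:0]
    for g in range(k):
        mine = reps[g]
        valid = mine < 4
        differs_all = valid.copy()
        any_other = np.zeros_like(valid)
        for h in range(k):
            if h == g:
                continue
            both = valid & (reps[h] < 4)
            any_other |= both
            differs_all &= ~both | (mine != reps[h])
        out.append(frozenset(np.flatnonzero(differs_all & any_other).tolist()))
    return out


def assign_species(
    aln: PartialAlignment,
    partition: HaplogroupPartition,
    refs: PartialAlignment,
    ref_species: Mapping[str, str],
    threshold: float = 0.10,
) -> dict[str, tuple[str, float]]:
    """Label each haplogroup with the species of its nearest reference.

    The representative of each haplogroup is compared (TN93, pairwise
    deletion) to every reference sequence; the species of the minimum-
    distance reference is assigned. Ties between species are broken by the
    smaller mean distance to all references of each tied species. A minimum
    distance above ``threshold`` (default 0.10 substitutions/site), or no
    comparable overlap with any reference, yields ``"unassigned"``.

    References must share the alignment coordinate system (same column
    count) and each must appear in ``ref_species``.
    """
    if refs.columns != aln.columns:
        raise ValueError(
            "reference alignment does not share the query coordinate system"
        )
    missing = [l for l in refs.labels if l not in ref_species]
    if missing:
        raise ValueError(f"references without species labels: {missing}")

    result: dict[str, tuple[str, float]] = {}
    for hg in partition.haplogroups:
        rep_seq = aln.sequence(hg.representative)
        dists: dict[str, float] = {}
        for ref_label in refs.labels:
            try:
                stats = pair_stats(rep_seq, refs.sequence(ref_label))
            except Exception:
                continue
            d = tn93_distance(stats, on_saturation="missing")
            if np.isfinite(d):
                dists[ref_label] = d
        if not dists:
            result[hg.id] = ("unassigned", float("nan"))
            continue
        dmin = min(dists.values())
        if dmin > threshold:
            result[hg.id] = ("unassigned", dmin)
            continue
        nearest_species = sorted(
            {ref_species[l] for l, d in dists.items() if d == dmin}
        )
        if len(nearest_species) > 1:
            means = {
                s: float(
                    np.mean([d for l, d in dists.items() if ref_species[l] == s])
                )
                for s in nearest_species
            }
            nearest_species = sorted(means, key=lambda s: (means[s], s))
        result[hg.id] = (nearest_species[0], dmin)
    return result
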