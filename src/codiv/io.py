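"""File formats and core data containers.

The pipeline works on three kinds of input: aligned nucleotide sequences of
heterogeneous length sharing one coordinate system (``PartialAlignment``),
labeled symmetric distance matrices (``DistanceMatrix``), and infection
tables linking observed parasites to host taxa, possibly ambiguously
(``InfectionTable``).

Conventions, stated once here and used everywhere:

* Alignment columns are 0-based, half-open intervals ``[start, end)``.
* ``?`` is the padding character ("not sequenced"); ``-`` is an alignment
  gap ("indel") and is only meaningful *inside* a sequence's coverage.
  Leading/trailing gaps in input files are normalized to padding.
* Distance matrices are CSV with labels in the first row and first column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PAD = "?"
GAP = "-"
#: Characters allowed inside a coverage interval.
ALPHABET = frozenset("ACGTN-?")

__all__ = [
    "PAD",
    "GAP",
    "FormatError",
    "PartialAlignment",
    "DistanceMatrix",
    "Observation",
    "InfectionTable",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_distance_csv",
    "write_distance_csv",
    "read_infection_table",
    "write_infection_table",
    "read_links",
    "write_links",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _coverage_of(residues: str) -> tuple[int, int]:
    """Half-open column interval outside which characters are padding.

    Leading/trailing ``?`` and ``-`` are both treated as "not sequenced";
    only the inner span counts as covered.
    """
    inner = {"?", "-"}
    start = 0
    end = len(residues)
    while start < end and residues[start] in inner:
        start += 1
    while end > start and residues[end - 1] in inner:
        end -= 1
    return start, end


@dataclass(frozen=True)
class PartialAlignment:
    """Aligned sequences, each covering a contiguous column interval.

    Parameters
    ----------
    labels : unique sequence identifiers, in file order.
    columns : total alignment length.
    residues : per-sequence strings over ``ACGTN-?``, each of length
        ``columns``; characters outside the coverage interval are ``?``.
    coverage : per-sequence half-open ``[start, end)`` intervals.
    """

    labels: tuple[str, ...]
    columns: int
    residues: tuple[str, ...]
    coverage: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.columns <= 0:
            raise FormatError("alignment must have at least one column")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise FormatError(f"duplicate sequence labels: {', '.join(dupes)}")
        if not (len(self.labels) == len(self.residues) == len(self.coverage)):
            raise FormatError("labels, residues and coverage must align")
        for label, seq, (start, end) in zip(self.labels, self.residues, self.coverage):
            if len(seq) != self.columns:
                raise FormatError(
                    f"record '{label}' has length {len(seq)}, expected {self.columns}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise FormatError(
                    f"record '{label}' contains invalid characters: {sorted(bad)}"
                )
            if not (0 <= start < end <= self.columns):
                raise FormatError(f"record '{label}' has empty or invalid coverage")
            if any(c != PAD for c in seq[:start]) or any(c != PAD for c in seq[end:]):
                raise FormatError(
                    f"record '{label}' has non-padding characters outside coverage"
                )

    @classmethod
    def from_sequences(cls, pairs: Iterable[tuple[str, str]]) -> "PartialAlignment":
        """Build from (label, residues) pairs, normalizing outer gaps to padding."""
        labels: list[str] = []
        residues: list[str] = []
        coverage: list[tuple[int, int]] = []
        columns = None
        for label, seq in pairs:
            seq = seq.upper()
            if columns is None:
                columns = len(seq)
            elif len(seq) != columns:
                raise FormatError(
                    f"record '{label}' has length {len(seq)}, expected {columns}"
                )
            start, end = _coverage_of(seq)
            if start >= end:
                raise FormatError(f"record '{label}' has empty coverage")
            seq = PAD * start + seq[start:end] + PAD * (len(seq) - end)
            labels.append(label)
            residues.append(seq)
            coverage.append((start, end))
        if columns is None:
            raise FormatError("no sequence records found")
        return cls(tuple(labels), columns, tuple(residues), tuple(coverage))

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no sequence labeled '{label}'") from None

    def sequence(self, label: str) -> str:
        return self.residues[self.index(label)]

    def coverage_length(self, label: str) -> int:
        start, end = self.coverage[self.index(label)]
        return end - start


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric matrix of genetic distances (substitutions/site).

    Missing (e.g. saturated) entries are NaN; the diagonal is exactly zero.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise FormatError("duplicate labels in distance matrix")
        if values.shape != (n, n):
            raise FormatError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if np.any(np.diagonal(values) != 0.0):
            raise FormatError("distance matrix diagonal must be exactly zero")
        finite = np.isfinite(values)
        if np.any(values[finite] < 0):
            raise FormatError("distance matrix has negative entries")
        asym = np.abs(values - values.T)
        if np.nanmax(np.where(finite & finite.T, asym, 0.0), initial=0.0) > 1e-12:
            raise FormatError("distance matrix is not symmetric")
        if np.any(finite != finite.T):
            raise FormatError("missing entries are not symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no taxon labeled '{label}'") from None

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class Observation:
    """One parasite observation: host taxon plus candidate haplogroups.

    More than one candidate marks the observation as ambiguous (a short
    fragment missing its group's diagnostic sites).
    """

    observation: str
    host: str
    candidates: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise FormatError(
                f"observation '{self.observation}' has no candidate haplogroup"
            )
        if len(set(self.candidates)) != len(self.candidates):
            raise FormatError(
                f"observation '{self.observation}' lists a candidate twice"
            )

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1


@dataclass(frozen=True)
class InfectionTable:
    rows: tuple[Observation, ...]

    def __post_init__(self) -> None:
        ids = [r.observation for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate observation ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_ambiguous(self) -> int:
        return sum(r.ambiguous for r in self.rows)


# ---------------------------------------------------------------------------
# Readers / writers


def read_fasta_alignment(path: str | Path) -> PartialAlignment:
    """Read an aligned FASTA file, '?'-padding allowed, into a PartialAlignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return PartialAlignment.from_sequences((r.id, str(r.seq)) for r in records)


def write_fasta_alignment(aln: PartialAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=label, description="")
        for label, seq in zip(aln.labels, aln.residues)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    """Read a labeled square CSV distance matrix.

    Row and column labels must match (same order). Asymmetries below 1e-9
    (rounding in exported spreadsheets) are averaged away; anything larger
    is an error.
    """
    frame = pd.read_csv(path, index_col=0)
    rows = [str(l) for l in frame.index]
    cols = [str(l) for l in frame.columns]
    if len(rows) != len(cols):
        raise FormatError(f"{path}: matrix is not square ({len(rows)}x{len(cols)})")
    if rows != cols:
        raise FormatError(f"{path}: row labels do not match column labels")
    values = frame.to_numpy(dtype=float)
    if np.any(values[np.isfinite(values)] < 0):
        raise FormatError(f"{path}: negative distance entries")
    asym = np.abs(values - values.T)
    max_asym = np.nanmax(asym, initial=0.0)
    if max_asym >= 1e-9:
        i, j = np.unravel_index(np.nanargmax(asym), asym.shape)
        raise FormatError(
            f"{path}: asymmetric at ({rows[i]}, {rows[j]}): "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(tuple(rows), values)


def write_distance_csv(dm: DistanceMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels)
    frame.to_csv(path, float_format="%.12g")


def read_infection_table(path: str | Path) -> InfectionTable:
    """Read a TSV with columns ``observation``, ``host``, ``candidates``.

    Candidates are pipe-separated haplogroup ids; more than one means the
    observation could not be attributed to a single haplogroup.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"observation", "host", "candidates"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for _, rec in frame.iterrows():
        cand_field = rec["candidates"]
        if pd.isna(cand_field) or not str(cand_field).strip():
            raise FormatError(
                f"{path}: observation '{rec['observation']}' has empty candidates"
            )
        candidates = tuple(c.strip() for c in str(cand_field).split("|") if c.strip())
        rows.append(Observation(str(rec["observation"]), str(rec["host"]), candidates))
    return InfectionTable(tuple(rows))


def write_infection_table(table: InfectionTable, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "observation": [r.observation for r in table.rows],
            "host": [r.host for r in table.rows],
            "candidates": ["|".join(r.candidates) for r in table.rows],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_links(path: str | Path) -> tuple[tuple[str, str], ...]:
    """Read a two-column TSV of (host, parasite) association links."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["host", "parasite"]:
        raise FormatError(f"{path}: expected columns 'host' and 'parasite'")
    return tuple((str(h), str(p)) for h, p in zip(frame["host"], frame["parasite"]))


def write_links(links: Iterable[tuple[str, str]], path: str | Path) -> None:
    frame = pd.DataFrame(list(links), columns=["host", "parasite"])
    frame.to_csv(path, sep="\t", index=False)


def read_association_matrix(
    path: str | Path, hosts_as_rows: bool = True
) -> tuple[tuple[str, str], ...]:
    """Read a binary host-parasite association CSV into a link list.

    ``hosts_as_rows=False`` accepts the transposed orientation (parasites
    as rows), since supplementary matrices come in both layouts.
    """
    frame = pd.read_csv(path, index_col=0)
    if not hosts_as_rows:
        frame = frame.T
    links = []
    for host in frame.index:
        for parasite in frame.columns:
            value = frame.loc[host, parasite]
            if value not in (0, 1):
                raise FormatError(
                    f"{path}: non-binary entry {value!r} at ({host}, {parasite})"
                )
            if value == 1:
                links.append((str(host), str(parasite)))
    if not links:
        raise FormatError(f"{path}: association matrix has no links")
    return tuple(links)
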