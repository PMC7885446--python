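"""Alignment input/output and haplotype collapsing.

Sequences are aligned mtDNA fragments (here typically the 1140-bp
cytochrome b gene) over the alphabet ``{A, C, G, T, N, -}``.  ``N`` and
``-`` are treated as ambiguous/missing: pairwise comparisons exclude any
site that is ambiguous in either sequence ("pairwise deletion"), and two
sequences belong to the same haplotype when they agree at every site at
which both are unambiguous.

Because the identity-up-to-ambiguity relation is not transitive (an ``N``
matches both an ``A`` and a ``C``), collapsing assigns each sequence, in
input order, to the first haplotype class whose *representative* it
matches; otherwise it founds a new class.  This makes the collapse
deterministic and order-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALLOWED = set("ACGTN-")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}


class AlignmentError(ValueError):
    """Raised when input sequences do not form a valid alignment."""


class InputError(ValueError):
    """Raised for malformed input files (duplicate ids, bad residues...)."""


@dataclass
class Alignment:
    """An aligned set of sequences with optional group labels.

    Attributes
    ----------
    records:
        Ordered ``(sample_id, sequence)`` pairs.
    group_of:
        Optional mapping ``sample_id -> group label``.
    """

    records: list[tuple[str, str]]
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment contains no sequences")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sample ids: {dupes}")
        k = len(self.records[0][1])
        for sid, seq in self.records:
            if len(seq) != k:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {k}"
                )
            bad = set(seq) - ALLOWED
            if bad:
                raise InputError(
                    f"sequence {sid!r} contains unknown residue(s) "
                    f"{sorted(bad)}; allowed: A, C, G, T, N, -"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def k(self) -> int:
        """Alignment length in base pairs."""
        return len(self.records[0][1])

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def encoded(self) -> np.ndarray:
        """Integer matrix (n, k): A,C,G,T -> 0..3; N and '-' -> -1."""
        out = np.empty((self.n, self.k), dtype=np.int8)
        for i, (_, seq) in enumerate(self.records):
            out[i] = [_BASE_CODE[c] for c in seq]
        return out

    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for sid, _ in self.records:
            g = self.group_of.get(sid)
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with their frequencies and members.

    ``haplotypes`` is an ordered list of ``(sequence, frequency, member
    sample ids)``; frequencies sum to the sample size ``n``.
    """

    haplotypes: list[tuple[str, int, list[str]]]
    n: int

    @property
    def k_obs(self) -> int:
        """Number of distinct haplotypes (alleles)."""
        return len(self.haplotypes)

    @property
    def sequences(self) -> list[str]:
        return [h for h, _, _ in self.haplotypes]

    @property
    def frequencies(self) -> list[int]:
        return [f for _, f, _ in self.haplotypes]


def _matches(a: str, b: str) -> bool:
    """True if a and b agree wherever both are unambiguous."""
    return all(
        x == y or x in "N-" or y in "N-" for x, y in zip(a, b)
    )


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV; header row optional.

    A header is detected when the first line's first field is literally
    ``sample_id`` or ``sample`` (case-insensitive).
    """
    mapping: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise InputError(
                f"{path}: line {lineno + 1} has fewer than 2 tab-separated "
                "columns"
            )
        sid, grp = parts[0].strip(), parts[1].strip()
        if lineno == 0 and sid.lower() in {"sample_id", "sample", "id"}:
            continue
        mapping[sid] = grp
    return mapping


def read_alignment(
    path: str | Path, group_table: str | Path | None = None
) -> Alignment:
    """Read an aligned FASTA (optionally attaching group labels).

    The sample id is the description line up to the first whitespace.
    Sequences are upper-cased; wrapped and single-line FASTA both work.
    Samples present in the group table but absent from the FASTA are
    warned about and ignored.
    """
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    group_of: dict[str, str] = {}
    if group_table is not None:
        table = read_group_table(group_table)
        known = {sid for sid, _ in records}
        unknown = sorted(set(table) - known)
        if unknown:
            warnings.warn(
                f"group table lists {len(unknown)} sample(s) absent from the "
                f"alignment (ignored): {unknown[:5]}...",
                stacklevel=2,
            )
        group_of = {sid: g for sid, g in table.items() if sid in known}
    return Alignment(records=records, group_of=group_of)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an Alignment to FASTA (one line per sequence)."""
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(recs)


def write_group_table(group_of: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in group_of.items():
            fh.write(f"{sid}\t{grp}\n")


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group identical sequences into haplotypes.

    Identity is up to ambiguity: two sequences are the same haplotype when
    they agree at every site where both are unambiguous.  Assignment is
    greedy in input order against each class representative (see module
    docstring); class order is first occurrence.
    """
    classes: list[tuple[str, list[str]]] = []  # (representative, members)
    for sid, seq in aln.records:
        for idx, (rep, members) in enumerate(classes):
            if _matches(seq, rep):
                members.append(sid)
                break
        else:
            classes.append((seq, [sid]))
    haplotypes = [(rep, len(members), members) for rep, members in classes]
    return HaplotypeTable(haplotypes=haplotypes, n=aln.n)


def subset_by_group(aln: Alignment, group: str) -> Alignment:
    """Restrict an Alignment to the members of one group."""
    if group not in set(aln.group_of.values()):
        raise KeyError(f"unknown group label: {group!r}")
    records = [
        (sid, seq) for sid, seq in aln.records if aln.group_of.get(sid) == group
    ]
    return Alignment(
        records=records,
        group_of={sid: group for sid, _ in records},
    )


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    """Write a haplotype table as TSV (haplotype id, frequency, members, seq)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("haplotype\tfrequency\tmembers\tsequence\n")
        for i, (seq, freq, members) in enumerate(table.haplotypes, start=1):
            fh.write(f"H{i}\t{freq}\t{','.join(members)}\t{seq}\n")
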