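"""Gapped protein alignments and FASTA I/O.

Alignment columns are 1-based everywhere in this package, matching the
way sites are reported ("site 3" means the third alignment column).
"""

from __future__ import annotations

import io
from typing import Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical amino-acid order used throughout the package (alphabetical
#: one-letter codes). All probability vectors index into this string.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"
AMBIGUOUS = "X"  # fully ambiguous residue; treated as missing data
VALID_CHARS = frozenset(AMINO_ACIDS) | {GAP, AMBIGUOUS}


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


class Alignment:
    """A named multiple sequence alignment of protein sequences.

    Parameters
    ----------
    taxa : sequence of str
        Taxon names, unique and nonempty, in input order.
    rows : sequence of str
        Gapped sequences over the 20 amino acids, ``-`` and ``X``; one
        per taxon, all the same length.
    name : str
        Label for the alignment, typically the alignment method that
        produced it (e.g. ``"muscle"``).
    """

    def __init__(self, taxa: Sequence[str], rows: Sequence[str], name: str = "alignment"):
        taxa = list(taxa)
        rows = [r.upper() for r in rows]
        if len(taxa) != len(rows):
            raise AlignmentError("taxa and rows differ in length")
        if not taxa:
            raise AlignmentError("alignment must contain at least one sequence")
        if any(not t for t in taxa):
            raise AlignmentError("taxon names must be nonempty")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon names: {', '.join(dupes)}")
        ncols = len(rows[0])
        if ncols < 1:
            raise AlignmentError("alignment must have at least one column")
        for t, r in zip(taxa, rows):
            if len(r) != ncols:
                raise AlignmentError(
                    f"ragged alignment: {t!r} has length {len(r)}, expected {ncols}"
                )
            bad = sorted(set(r) - VALID_CHARS)
            if bad:
                raise AlignmentError(
                    f"invalid characters in sequence for {t!r}: {', '.join(bad)}"
                )
        self.name = name
        self.taxa = taxa
        self.rows = rows
        self.ncols = ncols
        self._index = {t: i for i, t in enumerate(taxa)}

    def __len__(self) -> int:
        return len(self.taxa)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.taxa == other.taxa and self.rows == other.rows

    def __repr__(self) -> str:
        return f"Alignment({self.name!r}, ntaxa={len(self.taxa)}, ncols={self.ncols})"

    def row(self, taxon: str) -> str:
        """Gapped sequence for one taxon."""
        try:
            return self.rows[self._index[taxon]]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in alignment {self.name!r}") from None

    def degapped(self, taxon: str) -> str:
        """Unaligned (gap-free) sequence for one taxon."""
        return self.row(taxon).replace(GAP, "")

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col``, in taxon order."""
        if not 1 <= col <= self.ncols:
            raise IndexError(f"column {col} out of range 1..{self.ncols}")
        return "".join(r[col - 1] for r in self.rows)

    def columns(self) -> Iterator[str]:
        for c in range(1, self.ncols + 1):
            yield self.column(c)

    def subset_columns(self, kept: Sequence[int]) -> "Alignment":
        """New alignment containing only the 1-based columns in ``kept``."""
        if not kept:
            raise AlignmentError("cannot build an alignment with zero columns")
        rows = ["".join(r[c - 1] for c in kept) for r in self.rows]
        return Alignment(self.taxa, rows, name=self.name)


def read_fasta(path_or_handle, aligned: bool = True, name: str | None = None):
    """Read a FASTA file.

    With ``aligned=True`` returns an :class:`Alignment` (sequences must be
    equal length). With ``aligned=False`` returns a ``dict`` of taxon name
    to gap-stripped sequence. Headers are truncated at the first
    whitespace; sequences are uppercased.
    """
    if isinstance(path_or_handle, str) and (
            path_or_handle == "" or path_or_handle.lstrip().startswith(">")):
        handle = io.StringIO(path_or_handle)
    else:
        handle = path_or_handle
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise AlignmentError("no FASTA records found")
    taxa = [rec.id for rec in records]
    rows = [str(rec.seq).upper() for rec in records]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise AlignmentError(f"duplicate taxon names: {', '.join(dupes)}")
    if not aligned:
        out = {}
        for t, r in zip(taxa, rows):
            bad = sorted(set(r) - VALID_CHARS)
            if bad:
                raise AlignmentError(
                    f"invalid characters in sequence for {t!r}: {', '.join(bad)}"
                )
            out[t] = r.replace(GAP, "")
        return out
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentError(
            f"aligned input has unequal sequence lengths: {sorted(lengths)}"
        )
    if name is None:
        name = getattr(path_or_handle, "name", None) or "alignment"
    return Alignment(taxa, rows, name=str(name))


def write_fasta(aln: Alignment, path_or_handle) -> None:
    """Write an alignment as FASTA, 60 characters per line, in row order."""
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    SeqIO.write(records, path_or_handle, "fasta")


def empirical_frequencies(aln: Alignment, pseudocount: float = 0.25):
    """Amino-acid frequencies observed in an alignment.

    A pseudocount (default 0.25 per amino acid) keeps every frequency
    strictly positive, which the substitution-model math requires.
    """
    import numpy as np

    counts = np.full(20, float(pseudocount))
    for row in aln.rows:
        for ch in row:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1.0
    return counts / counts.sum()
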