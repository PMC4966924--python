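"""Cross-alignment residue maps, site identity and column masking.

Different alignment programs place the same residues in different
columns; because reconstructed ancestors inherit the column coordinate
system of their alignment, such disagreements propagate into ancestral
sequences. The residue map tracks, for every residue of every taxon,
which column it occupies in each alignment, which yields per-column
"site identity" distributions (where do the residues of a reference
column land elsewhere?) and a scalar consistency score.

The consistency score — the mean over other alignments of the largest
single-column fraction — is a summary invented here for ranking
columns; it is labeled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import GAP, Alignment, AlignmentError


@dataclass
class SiteIdentity:
    """Where the residues of one reference column land in other alignments."""

    reference: str
    column: int
    # other alignment name -> {column -> fraction of reference residues}
    distributions: dict[str, dict[int, float]]


@dataclass
class ColumnScores:
    """Per-column quality scores (e.g. from a probabilistic masker)."""

    name: str
    scores: np.ndarray
    provenance: str  # "external file" or "uniform default"


class ResidueMap:
    """Residue-level correspondence among alignments of the same sequences.

    For each alignment and taxon, ``positions[name][taxon][k]`` is the
    1-based column holding that taxon's (k+1)-th residue. All
    alignments must degap to identical sequences per taxon.
    """

    def __init__(self, alignments: list[Alignment]):
        if len(alignments) < 2:
            raise AlignmentError("need at least 2 alignments to compare")
        names = [a.name for a in alignments]
        if len(set(names)) != len(names):
            raise AlignmentError("alignment names must be unique")
        ref = alignments[0]
        taxa = list(ref.taxa)
        for aln in alignments[1:]:
            if set(aln.taxa) != set(taxa):
                raise AlignmentError(
                    f"alignments {ref.name!r} and {aln.name!r} "
                    "contain different taxa")
            for t in taxa:
                a, b = ref.degapped(t), aln.degapped(t)
                if a != b:
                    k = next(i for i, (x, y) in
                             enumerate(zip(a + "\0", b + "\0")) if x != y)
                    raise AlignmentError(
                        f"degapped sequences differ for taxon {t!r} "
                        f"between {ref.name!r} and {aln.name!r} at "
                        f"residue {k + 1}")
        self.alignments = {a.name: a for a in alignments}
        self.taxa = taxa
        self.positions: dict[str, dict[str, np.ndarray]] = {}
        for aln in alignments:
            per_taxon = {}
            for t in taxa:
                row = aln.row(t)
                per_taxon[t] = np.array(
                    [c + 1 for c, ch in enumerate(row) if ch != GAP],
                    dtype=int)
            self.positions[aln.name] = per_taxon

    @property
    def names(self) -> list[str]:
        return list(self.alignments)

    def column_of(self, name: str, taxon: str, residue_index: int) -> int:
        """1-based column of a taxon's 1-based unaligned residue index."""
        return int(self.positions[name][taxon][residue_index - 1])

    def residue_at(self, name: str, taxon: str, column: int) -> int | None:
        """1-based residue index at a column, or None if gapped there."""
        pos = self.positions[name][taxon]
        k = np.searchsorted(pos, column)
        if k < len(pos) and pos[k] == column:
            return int(k + 1)
        return None


def build_residue_map(alignments: list[Alignment]) -> ResidueMap:
    """Map every residue of every taxon across all alignments."""
    return ResidueMap(alignments)


def site_identity(rmap: ResidueMap, reference: str,
                  column: int) -> SiteIdentity:
    """Distribution of one reference column's residues over the columns
    of each other alignment.

    Rows gapped at the reference column are excluded from the
    denominator; an all-gap reference column is an error.
    """
    ref_aln = rmap.alignments[reference]
    if not 1 <= column <= ref_aln.ncols:
        raise AlignmentError(
            f"column {column} out of range 1..{ref_aln.ncols}")
    carriers = []  # (taxon, residue index) pairs present at the column
    for t in rmap.taxa:
        r = rmap.residue_at(reference, t, column)
        if r is not None:
            carriers.append((t, r))
    if not carriers:
        raise AlignmentError(
            f"column {column} of {reference!r} contains only gaps; "
            "site identity is undefined")
    dists = {}
    for other in rmap.names:
        if other == reference:
            continue
        counts: dict[int, int] = {}
        for t, r in carriers:
            c = rmap.column_of(other, t, r)
            counts[c] = counts.get(c, 0) + 1
        total = len(carriers)
        dists[other] = {c: n / total for c, n in sorted(counts.items())}
    return SiteIdentity(reference=reference, column=column,
                        distributions=dists)


def consistency_score(rmap: ResidueMap, reference: str) -> np.ndarray:
    """Per-column agreement score in [0, 1] for a reference alignment.

    For each reference column, the mean over the other alignments of
    the largest single-column fraction of its site-identity
    distribution; 1.0 iff every method keeps that column's residues
    together. All-gap columns score NaN.
    """
    ref_aln = rmap.alignments[reference]
    out = np.full(ref_aln.ncols, np.nan)
    for col in range(1, ref_aln.ncols + 1):
        try:
            si = site_identity(rmap, reference, col)
        except AlignmentError:
            continue
        maxima = [max(d.values()) for d in si.distributions.values()]
        out[col - 1] = float(np.mean(maxima))
    return out


def read_column_scores(path: str, name: str = "scores") -> ColumnScores:
    """Read a per-column score file: one float per line."""
    with open(path) as fh:
        vals = [float(line.strip()) for line in fh if line.strip()]
    return ColumnScores(name=name, scores=np.asarray(vals),
                        provenance="external file")


def uniform_scores(aln: Alignment, value: float = 1.0) -> ColumnScores:
    return ColumnScores(name=aln.name,
                        scores=np.full(aln.ncols, float(value)),
                        provenance="uniform default")


def apply_column_mask(aln: Alignment, scores: ColumnScores,
                      threshold: float):
    """Drop columns scoring below ``threshold``.

    Returns the masked alignment and the kept 1-based column indices
    (the old->new mapping: new column j is old column kept[j-1]).
    A threshold outside the score range triggers a warning, not an
    error; keeping zero columns is an error.
    """
    import warnings

    if len(scores.scores) != aln.ncols:
        raise AlignmentError(
            f"scores cover {len(scores.scores)} columns, "
            f"alignment has {aln.ncols}")
    lo, hi = float(np.min(scores.scores)), float(np.max(scores.scores))
    if not lo <= threshold <= hi:
        warnings.warn(
            f"mask threshold {threshold} outside score range "
            f"[{lo}, {hi}]", stacklevel=2)
    kept = [c for c in range(1, aln.ncols + 1)
            if scores.scores[c - 1] >= threshold]
    if not kept:
        raise AlignmentError(
            "mask threshold removes every column of the alignment")
    return aln.subset_columns(kept), kept
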