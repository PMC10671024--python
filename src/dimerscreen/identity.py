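"""Pairwise sequence identity between receptor sequences.

Identity is computed from a single optimal global alignment (Needleman-
Wunsch with a substitution matrix and affine gap penalties, via
Biopython's :class:`PairwiseAligner`) as::

    100 * identical_columns / alignment_length

where the alignment length counts gap columns.  The published values this
mirrors were produced by the UniProt "align" tool whose exact parameters
are unstated, so the matrix and gap penalties are exposed rather than
baked in; small (about one percentage point) variation between parameter
sets is expected.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["pairwise_identity", "VALID_AA"]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _make_aligner(matrix: str, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
) -> float:
    """Percent identity (0-100) of two amino-acid sequences, case-insensitive.

    Raises ValueError on empty input or non-amino-acid characters.
    """
    a = seq_a.strip().upper()
    b = seq_b.strip().upper()
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    for label, s in (("first", a), ("second", b)):
        bad = set(s) - VALID_AA
        if bad:
            raise ValueError(
                f"{label} sequence contains non-amino-acid characters: {sorted(bad)}"
            )
    aligner = _make_aligner(matrix, open_gap, extend_gap)
    # co-optimal alignments can differ in identity; canonicalise the input
    # order so the result is symmetric in its arguments
    if b < a:
        a, b = b, a
    aln = aligner.align(a, b)[0]
    top, bottom = str(aln[0]), str(aln[1])
    assert len(top) == len(bottom)
    identical = sum(1 for x, y in zip(top, bottom) if x == y and x != "-")
    return round(100.0 * identical / len(top))
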