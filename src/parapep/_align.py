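"""Pinned pairwise global aligners.

The pipeline needs two ordinary global alignments: paralogue protein onto an
orthologue-alignment reference row, and transcript CDS onto a parent CDS.
Parameters are fixed here so results are reproducible; they are conventional
choices, not tuned.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

#: Protein global alignment: BLOSUM62 with affine gaps (open -11, extend -1).
PROTEIN_OPEN_GAP = -11.0
PROTEIN_EXTEND_GAP = -1.0

#: Nucleotide glocal alignment: match +2, mismatch -3, open -7, extend -2,
#: free end gaps (a 5'-truncated transcript should not be punished for the
#: parent overhang).
NT_MATCH = 2.0
NT_MISMATCH = -3.0
NT_OPEN_GAP = -7.0
NT_EXTEND_GAP = -2.0


def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = PROTEIN_OPEN_GAP
    aligner.extend_gap_score = PROTEIN_EXTEND_GAP
    return aligner


def nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = NT_MATCH
    aligner.mismatch_score = NT_MISMATCH
    aligner.open_gap_score = NT_OPEN_GAP
    aligner.extend_gap_score = NT_EXTEND_GAP
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def aligned_pairs(alignment) -> list[tuple[int | None, int | None]]:
    """Column-wise (target_index, query_index) pairs, None marking a gap."""
    pairs: list[tuple[int | None, int | None]] = []
    coords = alignment.coordinates
    for k in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        if t1 - t0 == q1 - q0:
            for off in range(t1 - t0):
                pairs.append((t0 + off, q0 + off))
        elif q1 == q0:
            for t in range(t0, t1):
                pairs.append((t, None))
        else:
            for q in range(q0, q1):
                pairs.append((None, q))
    return pairs
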