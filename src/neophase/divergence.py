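"""Three-way alignment, conserved-block filtering and uncorrected
divergence.

The two in-group haplotypes and the outgroup are aligned by a center-star
projection around the neoX sequence (pairwise affine alignments projected
onto common columns). Poorly aligned segments are removed with two
parameters: minimum block length 100 columns and at most four consecutive
non-conserved positions, a column being non-conserved when any of the
three sequences gaps or mismatches. Divergence is the uncorrected
p-distance over masked-in, gap-free columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align


@dataclass(frozen=True)
class BlockFilterParams:
    min_block_length: int = 100
    max_nonconserved_run: int = 4

    def __post_init__(self) -> None:
        if self.min_block_length <= 0 or self.max_nonconserved_run <= 0:
            raise ValueError("block filter parameters must be positive")


@dataclass(frozen=True)
class AlignmentTriple:
    neoX: str
    neoY: str
    outgroup: str
    kept_columns: np.ndarray  # bool mask, len == aligned length

    def __post_init__(self) -> None:
        n = len(self.neoX)
        if len(self.neoY) != n or len(self.outgroup) != n:
            raise ValueError("aligned sequences must have equal lengths")
        if len(self.kept_columns) != n:
            raise ValueError("mask length must equal aligned length")


def _pair_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 10.0
    aligner.mismatch_score = -5.0
    aligner.open_gap_score = -16.6
    aligner.extend_gap_score = -6.6
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


def _pairwise(center: str, other: str) -> tuple[str, str, float]:
    """Global alignment (free end gaps) of other against center; returns
    gapped strings (center_row, other_row) and the fraction identity over
    gap-free columns."""
    aligner = _pair_aligner()
    aln = aligner.align(center, other)[0]
    row_c, row_o = str(aln[0]), str(aln[1])
    comparable = matches = 0
    for a, b in zip(row_c, row_o):
        if a != "-" and b != "-":
            comparable += 1
            if a == b:
                matches += 1
    ident = matches / comparable if comparable else 0.0
    return row_c, row_o, ident


def _split_by_center(row_c: str, row_o: str) -> tuple[list[str], list[str]]:
    """Per center-base decomposition: ins[k] = other-row chars inserted
    before center base k; aligned[k] = other-row char at center base k."""
    n = sum(1 for c in row_c if c != "-")
    ins = [""] * (n + 1)
    aligned = [""] * n
    k = 0
    for c, o in zip(row_c, row_o):
        if c == "-":
            ins[k] += o
        else:
            aligned[k] = o
            k += 1
    return ins, aligned


def align_three_way(
    neoX: str, neoY: str, outgroup: str, min_identity: float = 0.6
) -> AlignmentTriple | None:
    """Center-star alignment of the triple anchored on neoX.

    Both partners are aligned pairwise to neoX and projected onto common
    columns; insertions relative to neoX are padded against each other.
    Returns None when either pairwise identity falls below `min_identity`
    (the triple is rejected, mirroring the all-three-sequences rule)."""
    if not (neoX and neoY and outgroup):
        raise ValueError("all three sequences must be non-empty")
    cy, ry, ident_y = _pairwise(neoX, neoY)
    co, ro, ident_o = _pairwise(neoX, outgroup)
    if ident_y < min_identity or ident_o < min_identity:
        return None
    ins_y, al_y = _split_by_center(cy, ry)
    ins_o, al_o = _split_by_center(co, ro)
    n = len(neoX)
    out_x: list[str] = []
    out_y: list[str] = []
    out_o: list[str] = []
    for k in range(n + 1):
        a, b = ins_y[k], ins_o[k]
        width = max(len(a), len(b))
        if width:
            out_x.append("-" * width)
            out_y.append(a.ljust(width, "-"))
            out_o.append(b.ljust(width, "-"))
        if k < n:
            out_x.append(neoX[k])
            out_y.append(al_y[k])
            out_o.append(al_o[k])
    x, y, o = "".join(out_x), "".join(out_y), "".join(out_o)
    return AlignmentTriple(
        neoX=x, neoY=y, outgroup=o, kept_columns=np.ones(len(x), dtype=bool)
    )


def filter_blocks(
    triple: AlignmentTriple, params: BlockFilterParams | None = None
) -> AlignmentTriple:
    """Mask poorly aligned segments.

    A column is non-conserved when any sequence has a gap or the three
    bases disagree. Runs of more than `max_nonconserved_run` non-conserved
    columns break the alignment into blocks; those runs are excluded and
    only blocks of at least `min_block_length` columns are kept."""
    params = params or BlockFilterParams()
    n = len(triple.neoX)
    nonconserved = np.zeros(n, dtype=bool)
    for i, (a, b, c) in enumerate(zip(triple.neoX, triple.neoY, triple.outgroup)):
        if "-" in (a, b, c) or not (a == b == c):
            nonconserved[i] = True
    mask = np.zeros(n, dtype=bool)
    # break columns: non-conserved runs longer than the allowed maximum
    breaking = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if nonconserved[i]:
            j = i
            while j < n and nonconserved[j]:
                j += 1
            if j - i > params.max_nonconserved_run:
                breaking[i:j] = True
            i = j
        else:
            i += 1
    i = 0
    while i < n:
        if breaking[i]:
            i += 1
            continue
        j = i
        while j < n and not breaking[j]:
            j += 1
        if j - i >= params.min_block_length:
            mask[i:j] = True
        i = j
    return AlignmentTriple(
        neoX=triple.neoX,
        neoY=triple.neoY,
        outgroup=triple.outgroup,
        kept_columns=mask,
    )


def p_distance(
    seqA_aligned: str, seqB_aligned: str, mask: Sequence[bool] | np.ndarray
) -> float | None:
    """Uncorrected divergence: mismatches / comparable columns, comparable
    being masked-in columns with no gap in either sequence. None when no
    column is comparable."""
    if len(seqA_aligned) != len(seqB_aligned) or len(mask) != len(seqA_aligned):
        raise ValueError("aligned sequences and mask must have equal lengths")
    comparable = mismatches = 0
    for a, b, keep in zip(seqA_aligned, seqB_aligned, mask):
        if not keep or a == "-" or b == "-":
            continue
        comparable += 1
        if a != b:
            mismatches += 1
    if comparable == 0:
        return None
    return mismatches / comparable
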