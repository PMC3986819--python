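"""Reference ID assignment, fragment merging/scaffolding and ORF integrity.

IDs are assigned by reciprocal best hit against a reference transcript
set. Fragments are merged on near-identical suffix/prefix overlaps and
scaffolded against a reference protein, gaps filled with N runs sized by
the unaligned protein span. ORF status is classified by aligning each
transcript to its homologous reference CDS and walking the transcript in
codons from the aligned start: indels of length not divisible by three are
frameshifts (the reading frame follows the transcript's shifted phase
afterwards), and any stop codon strictly before the ancestral stop is a
premature termination codon (PTC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .mapper import revcomp
from .seqio import Transcript

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

STATUS_INTACT = "intact"
STATUS_FRAMESHIFT = "frameshift_only"
STATUS_PTC = "ptc"
STATUS_BOTH = "frameshift_and_ptc"
STATUS_UNALIGNABLE = "unalignable"


@dataclass(frozen=True)
class RbhAssignment:
    transcript_id: str
    reference_id: str
    forward_score: float
    reverse_score: float
    tie_broken: bool = False


@dataclass(frozen=True)
class CdsAlignment:
    """Local affine alignment of a transcript against a reference CDS."""

    transcript_id: str
    ref_id: str
    tx_seq: str
    ref_seq: str
    t_start: int
    t_end: int
    r_start: int
    r_end: int
    aligned_tx: str
    aligned_ref: str
    identity: float
    score: float
    unalignable: bool


@dataclass(frozen=True)
class OrfAnnotation:
    transcript_id: str
    status: str
    frameshift_positions: tuple[int, ...] = ()  # transcript coordinates
    frameshift_ref_codon_indices: tuple[int, ...] = ()
    first_ptc_codon_index: int | None = None
    first_ptc_relative: float | None = None
    first_stop_end_tpos: int | None = None
    ancestral_stop_end_tpos: int | None = None
    utr3_from_first_stop_bp: int | None = None
    utr3_from_ancestral_stop_bp: int | None = None


def _nucleotide_matrix() -> "Align.substitution_matrices.Array":
    """Match/mismatch matrix over ACGTN with N neutral (score 0), so
    scaffold N runs stay aligned instead of being gamed into gaps."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            m[a, b] = 0.0 if "N" in (a, b) else (10.0 if a == b else -5.0)
    return m


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _nucleotide_matrix()
    aligner.open_gap_score = -16.6
    aligner.extend_gap_score = -6.6
    return aligner


def alignment_scorer(a: str, b: str) -> float:
    """Local affine alignment score used as the default RBH similarity."""
    return float(_default_aligner().score(a, b))


def _kmer_set(seq: str, k: int = 15, step: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(0, max(1, len(seq) - k + 1), step)}


def assign_ids_rbh(
    queries: Sequence[Transcript],
    references: Sequence[Transcript],
    scorer: Callable[[str, str], float] | None = None,
) -> list[RbhAssignment]:
    """Reciprocal-best-hit assignment of queries to references.

    q is assigned r iff r is q's best hit and q is r's best hit. Equal-score
    ties are broken by lexicographically smaller id and the assignment is
    flagged. With the default scorer a shared-k-mer prefilter limits the
    alignments actually computed; pairs sharing no k-mer score -inf."""
    use_prefilter = scorer is None
    scorer = scorer or alignment_scorer
    scores: dict[tuple[str, str], float] = {}
    if use_prefilter:
        ref_kmers = {r.id: _kmer_set(r.bases, step=1) for r in references}
        for q in queries:
            qk = _kmer_set(q.bases)
            for r in references:
                if qk & ref_kmers[r.id]:
                    scores[(q.id, r.id)] = scorer(q.bases, r.bases)
    else:
        for q in queries:
            for r in references:
                scores[(q.id, r.id)] = scorer(q.bases, r.bases)

    def best(
        ids: Iterable[str], partner_ids: Iterable[str], by_query: bool
    ) -> dict[str, tuple[str, bool]]:
        out: dict[str, tuple[str, bool]] = {}
        for i in ids:
            cand = []
            for j in partner_ids:
                key = (i, j) if by_query else (j, i)
                if key in scores:
                    cand.append((scores[key], j))
            if not cand:
                continue
            top = max(s for s, _ in cand)
            tied = sorted(j for s, j in cand if s == top)
            out[i] = (tied[0], len(tied) > 1)
        return out

    qids = [q.id for q in queries]
    rids = [r.id for r in references]
    q_best = best(qids, rids, by_query=True)
    r_best = best(rids, qids, by_query=False)
    assignments = []
    for q, (r, q_tie) in q_best.items():
        if r in r_best and r_best[r][0] == q:
            r_tie = r_best[r][1]
            assignments.append(
                RbhAssignment(
                    transcript_id=q,
                    reference_id=r,
                    forward_score=scores[(q, r)],
                    reverse_score=scores[(q, r)],
                    tie_broken=q_tie or r_tie,
                )
            )
    return sorted(assignments, key=lambda a: a.transcript_id)


def _overlap_length(a: str, b: str, min_overlap: int, min_identity: float) -> int:
    """Longest suffix-of-a / prefix-of-b overlap meeting the thresholds."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        sa, sb = a[-k:], b[:k]
        matches = sum(x == y for x, y in zip(sa, sb))
        if matches / k >= min_identity:
            return k
    return 0


def merge_fragments(
    fragments: Sequence[Transcript],
    min_overlap_bp: int = 40,
    min_identity: float = 0.99,
) -> list[Transcript]:
    """Greedily merge fragments on their longest qualifying suffix/prefix
    overlap; disagreeing (sub-threshold) overlaps are left unmerged."""
    frags = {t.id: t.bases for t in fragments}
    meta = {t.id: t for t in fragments}
    merged_ids: dict[str, list[str]] = {t.id: [t.id] for t in fragments}
    while len(frags) > 1:
        best_pair: tuple[str, str] | None = None
        best_k = 0
        for a in frags:
            for b in frags:
                if a == b:
                    continue
                k = _overlap_length(
                    frags[a], frags[b], min_overlap_bp, min_identity
                )
                if k > best_k:
                    best_k, best_pair = k, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        joined = frags[a] + frags[b][best_k:]
        new_id = f"{a}+{b}"
        merged_ids[new_id] = merged_ids.pop(a) + merged_ids.pop(b)
        first = meta[a]
        del frags[a], frags[b], meta[a], meta[b]
        frags[new_id] = joined
        meta[new_id] = Transcript(
            id=new_id, bases=joined, chrom_class=first.chrom_class
        )
    return sorted(meta.values(), key=lambda t: t.id)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -2.0
    return aligner


def translate(seq: str) -> str:
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def _best_protein_placement(
    fragment: str, protein: str
) -> tuple[float, int, int, str, int]:
    """(score, protein_start, protein_end, oriented_fragment, frame) of the
    best translated local alignment over six frames; `frame` is the
    nucleotide offset of the codon lattice within the oriented fragment."""
    aligner = _protein_aligner()
    best = (-np.inf, 0, 0, fragment, 0)
    for oriented in (fragment, revcomp(fragment)):
        for frame in range(3):
            pep = translate(oriented[frame:]).replace("*", "X")
            if not pep:
                continue
            alns = aligner.align(protein, pep)
            try:
                aln = alns[0]
            except IndexError:
                continue
            if aln.score > best[0]:
                p_start = int(aln.aligned[0][0][0])
                p_end = int(aln.aligned[0][-1][1])
                best = (float(aln.score), p_start, p_end, oriented, frame)
    return best


def scaffold_by_protein(
    fragments: Sequence[Transcript],
    reference_protein_id: str,
    reference_protein: str,
    scaffold_id: str | None = None,
) -> list[Transcript]:
    """Order fragments along a reference protein and join with N runs.

    Fragments are oriented by their best translated alignment, overlapping
    ones merged first, then joined in protein order with 3x(unaligned
    intervening residues) Ns. Conflicting (interleaved) placements are
    returned unscaffolded with a warning. Returns a single-element list on
    success, the input fragments otherwise."""
    if len(fragments) == 1:
        return [fragments[0]]
    merged = merge_fragments(fragments)
    if len(merged) == 1:
        return merged
    placed = []
    for frag in merged:
        score, p_start, p_end, oriented, frame = _best_protein_placement(
            frag.bases, reference_protein
        )
        if not np.isfinite(score):
            logger.warning(
                "fragment %s does not align to %s; left unscaffolded",
                frag.id,
                reference_protein_id,
            )
            return list(merged)
        placed.append((p_start, p_end, oriented, frag.id, frame))
    placed.sort()
    for (s1, e1, _, id1, _), (s2, e2, _, id2, _) in zip(placed, placed[1:]):
        if s2 < e1:  # interleaved/overlapping despite failed merge
            logger.warning(
                "conflicting protein placements for %s and %s; unscaffolded",
                id1,
                id2,
            )
            return list(merged)
    parts = [placed[0][2]]
    scaffold_len = len(placed[0][2])
    frame_anchor = placed[0][4]
    for (s1, e1, prev_frag, _, f1), (s2, e2, frag, _, f2) in zip(placed, placed[1:]):
        gap_res = s2 - e1
        # pad with ~3x(gap residues) Ns, phase-adjusted so the next
        # fragment's codon lattice stays in frame with the first fragment's
        pad = 3 * gap_res + ((frame_anchor - f2 - scaffold_len) % 3)
        parts.append("N" * pad)
        parts.append(frag)
        scaffold_len += pad + len(frag)
    sid = scaffold_id or "+".join(p[3] for p in placed)
    return [Transcript(id=sid, bases="".join(parts))]


def align_to_reference_cds(
    transcript: Transcript,
    reference_cds: Transcript,
    min_identity: float = 0.6,
) -> CdsAlignment:
    """Affine local alignment of a transcript against its homologous CDS,
    with per-column correspondence so codon phase can be tracked."""
    aligner = _default_aligner()
    try:
        aln = aligner.align(transcript.bases, reference_cds.bases)[0]
    except IndexError:
        return CdsAlignment(
            transcript_id=transcript.id,
            ref_id=reference_cds.id,
            tx_seq=transcript.bases,
            ref_seq=reference_cds.bases,
            t_start=0,
            t_end=0,
            r_start=0,
            r_end=0,
            aligned_tx="",
            aligned_ref="",
            identity=0.0,
            score=-np.inf,
            unalignable=True,
        )
    tblocks, qblocks = aln.aligned
    a_tx: list[str] = []
    a_ref: list[str] = []
    matches = 0
    cols = 0
    for i, ((ts, te), (qs, qe)) in enumerate(zip(tblocks, qblocks)):
        if i > 0:
            pt, pq = tblocks[i - 1][1], qblocks[i - 1][1]
            if ts > pt:  # transcript bases with no ref partner
                a_tx.append(transcript.bases[pt:ts])
                a_ref.append("-" * (ts - pt))
                cols += ts - pt
            if qs > pq:  # ref bases missing from transcript
                a_tx.append("-" * (qs - pq))
                a_ref.append(reference_cds.bases[pq:qs])
                cols += qs - pq
        tseg = transcript.bases[ts:te]
        qseg = reference_cds.bases[qs:qe]
        a_tx.append(tseg)
        a_ref.append(qseg)
        matches += sum(x == y for x, y in zip(tseg, qseg))
        cols += te - ts
    identity = matches / cols if cols else 0.0
    return CdsAlignment(
        transcript_id=transcript.id,
        ref_id=reference_cds.id,
        tx_seq=transcript.bases,
        ref_seq=reference_cds.bases,
        t_start=int(tblocks[0][0]),
        t_end=int(tblocks[-1][1]),
        r_start=int(qblocks[0][0]),
        r_end=int(qblocks[-1][1]),
        aligned_tx="".join(a_tx),
        aligned_ref="".join(a_ref),
        identity=identity,
        score=float(aln.score),
        unalignable=identity < min_identity,
    )


def classify_orf(alignment: CdsAlignment, reference_cds: Transcript) -> OrfAnnotation:
    """Classify ORF integrity from a transcript-vs-CDS alignment.

    Indels with length % 3 != 0 are frameshifts. The transcript is then
    read codon by codon from the position aligned to the first complete
    reference codon; the reading frame follows the transcript's own phase,
    so it shifts after each frameshift. Any stop codon strictly before the
    ancestral stop is a PTC; its codon index is normalized by the
    reference codon count."""
    if alignment.unalignable:
        return OrfAnnotation(
            transcript_id=alignment.transcript_id, status=STATUS_UNALIGNABLE
        )
    ref = reference_cds.bases
    if len(ref) % 3 != 0 or ref[-3:] not in STOP_CODONS:
        raise ValueError(
            f"reference CDS {reference_cds.id} must be a multiple of 3 "
            "ending in a stop codon"
        )
    n_ref_codons = len(ref) // 3
    tx = alignment.tx_seq

    # frameshifts: gap runs in the aligned region with length % 3 != 0
    frameshifts: list[int] = []
    frameshift_ref_codons: list[int] = []
    t_pos = alignment.t_start
    r_pos = alignment.r_start
    i = 0
    a_tx, a_ref = alignment.aligned_tx, alignment.aligned_ref
    n_cols = len(a_tx)
    while i < n_cols:
        if a_tx[i] == "-":  # deletion from the transcript
            j = i
            while j < n_cols and a_tx[j] == "-":
                j += 1
            if (j - i) % 3 != 0:
                frameshifts.append(t_pos)
                frameshift_ref_codons.append(r_pos // 3)
            r_pos += j - i
            i = j
        elif a_ref[i] == "-":  # insertion into the transcript
            j = i
            while j < n_cols and a_ref[j] == "-":
                j += 1
            if (j - i) % 3 != 0:
                frameshifts.append(t_pos)
                frameshift_ref_codons.append(r_pos // 3)
            t_pos += j - i
            i = j
        else:
            t_pos += 1
            r_pos += 1
            i += 1

    # map reference positions to transcript positions (first column at or
    # after each ref position)
    t_at_ref: dict[int, int] = {}
    t_pos = alignment.t_start
    r_pos = alignment.r_start
    for col in range(n_cols):
        if a_ref[col] != "-":
            t_at_ref.setdefault(r_pos, t_pos)
            r_pos += 1
        if a_tx[col] != "-":
            t_pos += 1
    t_at_ref.setdefault(r_pos, t_pos)  # one past the last aligned ref base

    # start the codon walk at the first complete reference codon
    first_full_codon = (alignment.r_start + 2) // 3
    walk_ref_start = first_full_codon * 3
    if walk_ref_start not in t_at_ref:
        return OrfAnnotation(
            transcript_id=alignment.transcript_id, status=STATUS_UNALIGNABLE
        )
    walk_start = t_at_ref[walk_ref_start]
    anc_stop_start_ref = len(ref) - 3
    t_anc_stop_start = t_at_ref.get(anc_stop_start_ref)
    t_anc_stop_end = t_at_ref.get(len(ref))
    walk_end = (
        t_anc_stop_end if t_anc_stop_end is not None else alignment.t_end
    )

    first_ptc_codon = None
    first_stop_end = None
    ancestral_stop_end = None
    pos = walk_start
    codon_index = first_full_codon
    while pos + 3 <= len(tx) and pos < walk_end:
        codon = tx[pos : pos + 3]
        if codon in STOP_CODONS:
            at_ancestral = (
                t_anc_stop_start is not None and pos >= t_anc_stop_start
            )
            if at_ancestral:
                ancestral_stop_end = pos + 3
                if first_stop_end is None:
                    first_stop_end = pos + 3
                break
            if first_ptc_codon is None:
                first_ptc_codon = codon_index
                first_stop_end = pos + 3
                break
        pos += 3
        codon_index += 1
    if first_ptc_codon is not None and t_anc_stop_start is not None:
        # locate the ancestral stop independently of the PTC walk
        if tx[t_anc_stop_start : t_anc_stop_start + 3] in STOP_CODONS:
            ancestral_stop_end = t_anc_stop_start + 3

    has_fs = bool(frameshifts)
    has_ptc = first_ptc_codon is not None
    if has_fs and has_ptc:
        status = STATUS_BOTH
    elif has_fs:
        status = STATUS_FRAMESHIFT
    elif has_ptc:
        status = STATUS_PTC
    else:
        status = STATUS_INTACT
    ann = OrfAnnotation(
        transcript_id=alignment.transcript_id,
        status=status,
        frameshift_positions=tuple(frameshifts),
        frameshift_ref_codon_indices=tuple(frameshift_ref_codons),
        first_ptc_codon_index=first_ptc_codon,
        first_ptc_relative=(
            first_ptc_codon / n_ref_codons if first_ptc_codon is not None else None
        ),
        first_stop_end_tpos=first_stop_end,
        ancestral_stop_end_tpos=ancestral_stop_end,
    )
    utr_first, utr_anc = utr3_lengths(
        Transcript(id=alignment.transcript_id, bases=tx), ann
    )
    return replace(
        ann,
        utr3_from_first_stop_bp=utr_first,
        utr3_from_ancestral_stop_bp=utr_anc,
    )


def utr3_lengths(
    transcript: Transcript, orf: OrfAnnotation
) -> tuple[int | None, int | None]:
    """3'UTR lengths: distance from the end of the first stop codon (PTC if
    present, else ancestral) to the transcript end; when a PTC exists the
    ancestral-stop measure is reported as well. (None, None) when no stop
    codon was found."""
    L = len(transcript.bases)
    if orf.first_stop_end_tpos is None:
        return None, None
    utr_first = L - orf.first_stop_end_tpos
    utr_anc = None
    if orf.first_ptc_codon_index is not None and orf.ancestral_stop_end_tpos is not None:
        utr_anc = L - orf.ancestral_stop_end_tpos
    return utr_first, utr_anc
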