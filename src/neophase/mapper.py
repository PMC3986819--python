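"""Lightweight read-to-transcript alignment and pileup construction.

Two mapping modes: `map_exact` reports every zero-mismatch placement of a
read on either strand; `map_scored` seeds with exact k-mers and extends,
scoring with affine gap penalties (gap open 10, gap extension 6.6,
mismatch -5 by default; scores are real-valued because the extension
penalty is fractional). Pileups tally per-position allele counts split by
read sex, with a separate tally restricted to bases above a quality
threshold. Indels are left-aligned against the target before being keyed
into the pileup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .seqio import ReadRecord, Sex, Transcript

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
BASES = "ACGTN"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode bases as uint8 codes: A=0 C=1 G=2 T=3, anything else 4."""
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MapperParams:
    gap_open_penalty: float = 10.0
    gap_extend_penalty: float = 6.6
    mismatch_score: float = -5.0
    match_score: float = 10.0
    seed_length: int = 20
    max_hits_reported: int | None = None
    min_score_frac: float = 0.4
    clip_ends: bool = True  # free soft-clipping of read ends in scored mode

    def __post_init__(self) -> None:
        if self.gap_open_penalty < 0 or self.gap_extend_penalty < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")
        if self.match_score <= 0:
            raise ValueError("match score must be positive")
        if self.seed_length < 1:
            raise ValueError("seed length must be >= 1")


@dataclass(frozen=True)
class Indel:
    """An indel on the target: 'del' removes target bases starting at
    target_pos; 'ins' inserts `bases` before target_pos."""

    target_pos: int
    kind: str  # 'ins' | 'del'
    length: int
    bases: str | None = None


@dataclass(frozen=True)
class Alignment:
    read_id: str
    target_id: str
    target_start: int
    target_end: int
    strand: str
    n_mismatches: int
    indels: tuple[Indel, ...]
    score: float
    is_multi: bool = False
    # aligned span on the oriented read (soft-clipped ends excluded);
    # read_end None means the read is aligned to its full length
    read_start: int = 0
    read_end: int | None = None


def left_align_deletion(target: str, pos: int, length: int) -> int:
    """Shift a deletion of `length` bases at `pos` as far left as sequence
    identity allows; returns the new anchor position."""
    while pos > 0 and target[pos - 1] == target[pos + length - 1]:
        pos -= 1
    return pos


def left_align_insertion(target: str, pos: int, bases: str) -> tuple[int, str]:
    """Shift an insertion (before `pos`) left; returns (pos, rotated bases)."""
    while pos > 0 and bases[-1] == target[pos - 1]:
        bases = target[pos - 1] + bases[:-1]
        pos -= 1
    return pos, bases


class TargetIndex:
    """Exact k-mer index over a set of target sequences."""

    def __init__(self, targets: Sequence[Transcript], k: int):
        self.k = k
        self.targets = {t.id: t for t in targets}
        self.ids = [t.id for t in targets]
        self.seqs = {t.id: t.bases for t in targets}
        self.codes = {t.id: encode(t.bases) for t in targets}
        index: dict[str, list[tuple[str, int]]] = {}
        for t in targets:
            s = t.bases
            for p in range(len(s) - k + 1):
                index.setdefault(s[p : p + k], []).append((t.id, p))
        self._index = index

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _mark_multi(alns: list[Alignment]) -> list[Alignment]:
    targets = {a.target_id for a in alns}
    if len(targets) > 1:
        return [
            Alignment(**{**a.__dict__, "is_multi": True}) for a in alns
        ]
    return alns


def map_exact(
    reads: Iterable[ReadRecord],
    targets: Sequence[Transcript] | TargetIndex,
    seed_length: int = 20,
) -> list[Alignment]:
    """Report every exact (zero-mismatch) placement of each read on either
    strand of the targets. Reads shorter than the seed length are rejected
    with a warning; reads with no exact placement are simply unreported."""
    index = (
        targets
        if isinstance(targets, TargetIndex)
        else TargetIndex(targets, seed_length)
    )
    k = index.k
    out: list[Alignment] = []
    n_short = 0
    for read in reads:
        L = len(read.bases)
        if L < k:
            n_short += 1
            continue
        placements: list[tuple[str, int, str]] = []
        for strand, seq in (("+", read.bases), ("-", revcomp(read.bases))):
            for tid, p in index.seed_hits(seq[:k]):
                if index.seqs[tid][p : p + L] == seq:
                    placements.append((tid, p, strand))
        if not placements:
            continue
        score = L * 10.0
        alns = [
            Alignment(
                read_id=read.id,
                target_id=tid,
                target_start=p,
                target_end=p + L,
                strand=strand,
                n_mismatches=0,
                indels=(),
                score=score,
            )
            for tid, p, strand in placements
        ]
        out.extend(_mark_multi(alns))
    if n_short:
        logger.warning("map_exact: %d reads shorter than seed length skipped", n_short)
    return out


def _make_glocal_aligner(params: MapperParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = -(params.gap_open_penalty + params.gap_extend_penalty)
    aligner.extend_gap_score = -params.gap_extend_penalty
    # target overhangs are free; read ends may be soft-clipped at no cost so
    # junction-spanning reads do not smear foreign sequence onto exon edges
    aligner.end_deletion_score = 0.0
    if params.clip_ends:
        aligner.end_insertion_score = 0.0
    return aligner


def _parse_biopython_alignment(
    aln: Align.Alignment, target: str, read_seq: str, window_offset: int
) -> tuple[int, int, int, tuple[Indel, ...], int, int]:
    """Extract coordinates, mismatch count, left-aligned indels and the
    aligned read span from a Biopython pairwise alignment of (window, read)."""
    tblocks, qblocks = aln.aligned
    n_mm = 0
    indels: list[Indel] = []
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        wseg = aln.target[ts:te]
        rseg = read_seq[qs:qe]
        n_mm += sum(a != b for a, b in zip(wseg, rseg))
    for i in range(1, len(tblocks)):
        t_gap = tblocks[i][0] - tblocks[i - 1][1]
        q_gap = qblocks[i][0] - qblocks[i - 1][1]
        tpos = tblocks[i - 1][1] + window_offset
        if t_gap > 0:  # target advances without read: deletion from read
            pos = left_align_deletion(target, tpos, t_gap)
            indels.append(Indel(target_pos=pos, kind="del", length=t_gap))
        if q_gap > 0:  # read bases not in target: insertion
            ibases = read_seq[qblocks[i - 1][1] : qblocks[i][0]]
            pos, ibases = left_align_insertion(target, tpos, ibases)
            indels.append(
                Indel(target_pos=pos, kind="ins", length=q_gap, bases=ibases)
            )
    t_start = int(tblocks[0][0]) + window_offset
    t_end = int(tblocks[-1][1]) + window_offset
    return (
        t_start,
        t_end,
        n_mm,
        tuple(sorted(indels, key=lambda d: d.target_pos)),
        int(qblocks[0][0]),
        int(qblocks[-1][1]),
    )


def map_scored(
    reads: Iterable[ReadRecord],
    targets: Sequence[Transcript] | TargetIndex,
    params: MapperParams | None = None,
) -> list[Alignment]:
    """Best-placement mapping allowing mismatches and affine gaps.

    Seeds with exact k-mers at several offsets along the read (both
    strands), scores candidate diagonals gaplessly, and falls back to
    affine-gap dynamic programming only when the gapless score suggests an
    indel. All top-scoring placements are reported and flagged is_multi
    when they span more than one target; placements scoring below
    min_score_frac of the perfect score are dropped."""
    params = params or MapperParams()
    index = (
        targets
        if isinstance(targets, TargetIndex)
        else TargetIndex(targets, params.seed_length)
    )
    k = index.k
    aligner = _make_glocal_aligner(params)
    match, mismatch = params.match_score, params.mismatch_score
    out: list[Alignment] = []
    n_short = 0
    for read in reads:
        L = len(read.bases)
        if L < k:
            n_short += 1
            continue
        min_score = params.min_score_frac * L * match
        # trigger DP when gapless leaves more than 4 mismatches
        gapless_ok = L * match - 4 * (match - mismatch)
        candidates: dict[tuple[str, int, str], None] = {}
        for strand, seq in (("+", read.bases), ("-", revcomp(read.bases))):
            for off in range(0, L - k + 1, k):
                for tid, p in index.seed_hits(seq[off : off + k]):
                    start = p - off
                    candidates[(tid, start, strand)] = None
        if not candidates:
            continue
        scored: list[tuple[float, Alignment]] = []
        need_dp: list[tuple[str, int, str]] = []
        best_gapless = -np.inf
        rc = revcomp(read.bases)
        codes = {"+": encode(read.bases), "-": encode(rc)}
        for tid, start, strand in candidates:
            tcodes = index.codes[tid]
            if start < 0 or start + L > len(tcodes):
                need_dp.append((tid, start, strand))
                continue
            n_mm = int(np.count_nonzero(tcodes[start : start + L] != codes[strand]))
            score = (L - n_mm) * match + n_mm * mismatch
            best_gapless = max(best_gapless, score)
            if score >= min_score:
                scored.append(
                    (
                        score,
                        Alignment(
                            read_id=read.id,
                            target_id=tid,
                            target_start=start,
                            target_end=start + L,
                            strand=strand,
                            n_mismatches=n_mm,
                            indels=(),
                            score=float(score),
                        ),
                    )
                )
        if best_gapless < gapless_ok:
            # no clean gapless placement: an indel may be hiding on any diagonal
            need_dp.extend(candidates)
        for tid, start, strand in dict.fromkeys(need_dp):
            target = index.seqs[tid]
            margin = 25
            w0 = max(0, start - margin)
            w1 = min(len(target), start + L + margin)
            if w1 - w0 < k:
                continue
            window = target[w0:w1]
            seq = read.bases if strand == "+" else rc
            try:
                best = aligner.align(window, seq)[0]
            except (IndexError, OverflowError):
                continue
            if best.score < min_score:
                continue
            t_start, t_end, n_mm, indels, r_start, r_end = (
                _parse_biopython_alignment(best, target, seq, w0)
            )
            scored.append(
                (
                    float(best.score),
                    Alignment(
                        read_id=read.id,
                        target_id=tid,
                        target_start=t_start,
                        target_end=t_end,
                        strand=strand,
                        n_mismatches=n_mm,
                        indels=indels,
                        score=float(best.score),
                        read_start=r_start,
                        read_end=r_end,
                    ),
                )
            )
        if not scored:
            continue
        top = max(s for s, _ in scored)
        best_alns: dict[tuple[str, int, str], Alignment] = {}
        for s, a in scored:
            if s > top - 1e-9:
                key = (a.target_id, a.target_start, a.strand)
                best_alns.setdefault(key, a)
        alns = list(best_alns.values())
        if params.max_hits_reported is not None:
            alns = alns[: params.max_hits_reported]
        out.extend(_mark_multi(alns))
    if n_short:
        logger.warning("map_scored: %d reads shorter than seed length skipped", n_short)
    return out


@dataclass(frozen=True)
class PileupSite:
    """Per-position allele tallies at one target position, split by sex.

    counts maps sex -> {allele: (raw_count, quality_passing_count)}.
    Alleles are single bases, '-N' for an N-bp deletion anchored here, or
    '+SEQ' for an insertion of SEQ before this position.
    """

    target_id: str
    pos: int
    ref_allele: str
    depth: dict[Sex, int]
    counts: dict[Sex, dict[str, tuple[int, int]]]


class Pileup:
    """Numpy-backed pileup over one target; indexable into PileupSites."""

    def __init__(self, target: Transcript):
        self.target_id = target.id
        self.ref = target.bases
        L = len(target.bases)
        self.length = L
        self.depth = {s: np.zeros(L, dtype=np.int32) for s in Sex}
        self.base_raw = {s: np.zeros((L, 5), dtype=np.int32) for s in Sex}
        self.base_qual = {s: np.zeros((L, 5), dtype=np.int32) for s in Sex}
        self.indels: dict[tuple[int, str], dict[Sex, list[int]]] = {}

    def __len__(self) -> int:
        return self.length

    def add_indel(self, pos: int, allele: str, sex: Sex, qual_pass: bool) -> None:
        rec = self.indels.setdefault((pos, allele), {s: [0, 0] for s in Sex})
        rec[sex][0] += 1
        if qual_pass:
            rec[sex][1] += 1

    def site(self, pos: int) -> PileupSite:
        if not (0 <= pos < self.length):
            raise IndexError(pos)
        counts: dict[Sex, dict[str, tuple[int, int]]] = {s: {} for s in Sex}
        for s in Sex:
            for b in range(4):
                raw = int(self.base_raw[s][pos, b])
                if raw:
                    counts[s][BASES[b]] = (raw, int(self.base_qual[s][pos, b]))
        for (p, allele), rec in self.indels.items():
            if p == pos:
                for s in Sex:
                    if rec[s][0]:
                        counts[s][allele] = (rec[s][0], rec[s][1])
        return PileupSite(
            target_id=self.target_id,
            pos=pos,
            ref_allele=self.ref[pos],
            depth={s: int(self.depth[s][pos]) for s in Sex},
            counts=counts,
        )

    def __getitem__(self, pos: int) -> PileupSite:
        return self.site(pos)


def build_pileup(
    alignments: Iterable[Alignment],
    reads: Mapping[str, ReadRecord] | Iterable[ReadRecord],
    target: Transcript,
    min_bq: int = 13,
) -> Pileup:
    """Build a per-position pileup of the given alignments on `target`.

    Depth counts every covering read (including across deleted bases);
    quality-passing tallies require base quality strictly greater than
    min_bq. N read bases are tallied but never usable as alleles."""
    if not isinstance(reads, Mapping):
        reads = {r.id: r for r in reads}
    pile = Pileup(target)
    L = pile.length
    depth_diff = {s: np.zeros(L + 1, dtype=np.int32) for s in Sex}
    # batched gapless contributions: positions, base codes, qual flags
    batch: dict[Sex, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {
        s: [] for s in Sex
    }
    for aln in alignments:
        if aln.target_id != target.id:
            continue
        if aln.target_start < 0 or aln.target_end > L:
            raise ValueError(
                f"alignment of {aln.read_id} out of bounds on {target.id}"
            )
        read = reads[aln.read_id]
        sex = read.sex
        if aln.strand == "+":
            seq, quals = read.bases, read.quals
        else:
            seq, quals = revcomp(read.bases), read.quals[::-1]
        r0 = aln.read_start
        r1 = len(seq) if aln.read_end is None else aln.read_end
        seq, quals = seq[r0:r1], quals[r0:r1]
        depth_diff[sex][aln.target_start] += 1
        depth_diff[sex][aln.target_end] -= 1
        if not aln.indels:
            pos = np.arange(aln.target_start, aln.target_end)
            codes = encode(seq)
            qflags = np.asarray(quals, dtype=np.int32) > min_bq
            batch[sex].append((pos, codes, qflags))
            continue
        # segmented walk across indels
        t = aln.target_start
        r = 0
        events = sorted(aln.indels, key=lambda d: (d.target_pos, d.kind))
        for ev in events:
            # matched segment before the event (anchor may be left-shifted, so clamp)
            seg_end = max(ev.target_pos, t)
            n = seg_end - t
            if n > 0:
                pos = np.arange(t, seg_end)
                codes = encode(seq[r : r + n])
                qflags = np.asarray(quals[r : r + n], dtype=np.int32) > min_bq
                batch[sex].append((pos, codes, qflags))
                t += n
                r += n
            if ev.kind == "del":
                flank_q = [q for q in quals[max(0, r - 1) : r + 1]]
                qp = bool(flank_q) and min(flank_q) > min_bq
                pile.add_indel(ev.target_pos, f"-{ev.length}", sex, qp)
                t += ev.length
            else:
                ins_q = quals[r : r + ev.length]
                qp = bool(ins_q) and min(ins_q) > min_bq
                pile.add_indel(ev.target_pos, f"+{ev.bases}", sex, qp)
                r += ev.length
        n = aln.target_end - t
        if n > 0:
            pos = np.arange(t, aln.target_end)
            codes = encode(seq[r : r + n])
            qflags = np.asarray(quals[r : r + n], dtype=np.int32) > min_bq
            batch[sex].append((pos, codes, qflags))
    for s in Sex:
        pile.depth[s] = np.cumsum(depth_diff[s][:-1]).astype(np.int32)
        if batch[s]:
            pos = np.concatenate([b[0] for b in batch[s]])
            codes = np.concatenate([b[1] for b in batch[s]]).astype(np.intp)
            qflags = np.concatenate([b[2] for b in batch[s]])
            np.add.at(pile.base_raw[s], (pos, codes), 1)
            np.add.at(pile.base_qual[s], (pos[qflags], codes[qflags]), 1)
    return pile
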