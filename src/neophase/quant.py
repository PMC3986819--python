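"""Probabilistic read assignment between near-identical homologs (EM) and
FPKM computation.

Zero-mismatch multi-mapping reads are distributed over their candidate
transcripts by expectation-maximization: the E-step splits each read
proportional to (current abundance / transcript length), the M-step sums
the fractions. Initialization is uniform and the procedure is fully
deterministic. Effective length equals transcript length (no
fragment-length model) so small fixed points stay closed-form.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .mapper import Alignment
from .seqio import Transcript

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbundanceRecord:
    transcript_id: str
    assigned_fragments: float
    fpkm: float
    n_unique_reads: int
    n_ambiguous_reads_touching: int


@dataclass(frozen=True)
class QuantReport:
    records: list[AbundanceRecord]
    n_assigned_reads: int
    n_unmapped_reads: int
    n_repetitive_dropped: int
    log_likelihoods: list[float]
    fragment_totals: list[float]  # sum of assigned fragments per iteration


def em_quantify(
    exact_alignments: Sequence[Alignment],
    transcripts: Sequence[Transcript],
    max_iter: int = 1000,
    tol: float = 1e-8,
    max_candidates: int = 50,
    total_reads: int | None = None,
) -> QuantReport:
    """EM assignment of reads to transcripts from zero-mismatch alignments.

    Reads are collapsed into equivalence classes by candidate transcript
    set. Reads mapping to more than `max_candidates` transcripts are
    dropped as repetitive (counted in the report); `total_reads`, when
    given, is used to count reads with empty candidate sets."""
    tids = [t.id for t in transcripts]
    lengths = np.array([float(len(t.bases)) for t in transcripts])
    tidx = {tid: i for i, tid in enumerate(tids)}
    cand: dict[str, set[int]] = {}
    for a in exact_alignments:
        if a.target_id in tidx:
            cand.setdefault(a.read_id, set()).add(tidx[a.target_id])
    n_repetitive = 0
    classes: Counter[frozenset[int]] = Counter()
    for read_id, cset in cand.items():
        if len(cset) > max_candidates:
            n_repetitive += 1
            continue
        classes[frozenset(cset)] += 1
    n_assigned = sum(classes.values())
    n_unmapped = (
        max(0, total_reads - n_assigned - n_repetitive)
        if total_reads is not None
        else 0
    )

    n_t = len(tids)
    unique_counts = np.zeros(n_t)
    ambiguous_touch = np.zeros(n_t, dtype=int)
    class_members = []
    class_counts = []
    for cset, n in sorted(
        classes.items(), key=lambda kv: sorted(kv[0])
    ):  # deterministic order
        members = np.fromiter(sorted(cset), dtype=int)
        class_members.append(members)
        class_counts.append(n)
        if len(members) == 1:
            unique_counts[members[0]] += n
        else:
            ambiguous_touch[members] += n
    counts = np.array(class_counts, dtype=float)

    theta = np.full(n_t, 1.0 / n_t) if n_t else np.zeros(0)
    frags = np.zeros(n_t)
    logls: list[float] = []
    totals: list[float] = []
    for _ in range(max_iter):
        new_frags = np.zeros(n_t)
        logl = 0.0
        for members, n in zip(class_members, counts):
            w = theta[members] / lengths[members]
            tot = w.sum()
            if tot <= 0:
                w = 1.0 / lengths[members]
                tot = w.sum()
            new_frags[members] += n * w / tot
            logl += n * np.log(tot)
        logls.append(float(logl))
        total = new_frags.sum()
        totals.append(float(total))
        new_theta = new_frags / total if total > 0 else theta
        delta = float(np.max(np.abs(new_frags - frags))) if n_t else 0.0
        frags = new_frags
        theta = new_theta
        if delta < tol and len(logls) > 1:
            break
    if n_repetitive:
        logger.info("em_quantify: dropped %d repetitive reads", n_repetitive)

    total_mapped = frags.sum()
    records = [
        AbundanceRecord(
            transcript_id=tids[i],
            assigned_fragments=float(frags[i]),
            fpkm=compute_fpkm(float(frags[i]), int(lengths[i]), total_mapped)
            if total_mapped > 0
            else 0.0,
            n_unique_reads=int(unique_counts[i]),
            n_ambiguous_reads_touching=int(ambiguous_touch[i]),
        )
        for i in range(n_t)
    ]
    return QuantReport(
        records=records,
        n_assigned_reads=n_assigned,
        n_unmapped_reads=n_unmapped,
        n_repetitive_dropped=n_repetitive,
        log_likelihoods=logls,
        fragment_totals=totals,
    )


def compute_fpkm(
    assigned_fragments: float,
    transcript_length_bp: int,
    total_mapped_fragments: float,
) -> float:
    """fragments / ((length/1000) * (total/1e6))."""
    if transcript_length_bp <= 0:
        raise ValueError("transcript length must be positive")
    if total_mapped_fragments <= 0:
        raise ValueError("total mapped fragments must be positive")
    return assigned_fragments / (
        (transcript_length_bp / 1000.0) * (total_mapped_fragments / 1e6)
    )
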