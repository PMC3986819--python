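"""Exon splitting, diagnostic-site calling/categorization, transcript
rewriting and RNA-support filtering — the core of the pipeline.

Sites are called with a pure threshold rule: an allele is called when 3 or
more quality-passing reads support it, or 2 when total depth at the site is
9 or less; base quality must exceed 13 (strict). Called sites are sorted
into three categories:

  CAT1 — males polymorphic, all female reads carry a non-reference allele
         (the transcript already carries the Y-specific variant);
  CAT2 — both sexes show a non-reference allele (polymorphism, error or
         paralogous mapping) — left unchanged;
  CAT3 — males polymorphic, females show nothing but reference (the
         transcript carries the X variant; rewritten to the Y allele).

CAT1 and CAT3 sites are "diagnostic": they distinguish the two haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mapper import Alignment, Pileup, PileupSite, encode
from .seqio import Region, Sex, Transcript


@dataclass(frozen=True)
class CallerParams:
    min_alt_reads: int = 3
    min_alt_reads_lowcov: int = 2
    lowcov_threshold: int = 9
    min_bq: int = 13  # exclusive bound: quality must be > min_bq
    # CAT1 tolerance: quality-passing female reference reads allowed while
    # still counting "all female reads" as variant (0 = strict)
    cat1_ref_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.min_alt_reads_lowcov > self.min_alt_reads:
            raise ValueError("low-coverage support bound must not exceed the default")


@dataclass(frozen=True)
class SiteCall:
    target_id: str
    pos: int
    ref_allele: str
    called_alleles: dict[Sex, frozenset[str]]
    depth: dict[Sex, int]


CAT1 = "CAT1"
CAT2 = "CAT2"
CAT3 = "CAT3"
INVARIANT = "INVARIANT"


@dataclass(frozen=True)
class CategorizedSite:
    site: SiteCall
    category: str
    substitution_allele: str | None = None

    @property
    def is_diagnostic(self) -> bool:
        return self.category in (CAT1, CAT3)


@dataclass(frozen=True)
class KeptRegion:
    region: Region
    n_diagnostic_sites: int
    rna_min_coverage: int

    def __post_init__(self) -> None:
        if self.n_diagnostic_sites < 1:
            raise ValueError("kept regions must contain a diagnostic site")
        if self.rna_min_coverage < 1:
            raise ValueError("kept regions must be RNA-covered")


def split_into_exons(
    transcript: Transcript,
    genomic_exact_alignments: Sequence[Alignment],
    min_overlap: int = 6,
) -> list[tuple[Region, str]]:
    """Partition a transcript into putative exons from zero-mismatch
    genomic-read tiling.

    Wherever the maximum overlap between the reads tiling so far and the
    next read is below `min_overlap` (including plain coverage gaps) a
    junction is declared. The boundary sits at the end of the left piece;
    overlap bases stay with the left piece. Uncovered stretches are
    dropped. Returns (region-on-parent, subsequence) pairs."""
    ivals = sorted(
        (a.target_start, a.target_end)
        for a in genomic_exact_alignments
        if a.target_id == transcript.id
    )
    if not ivals:
        return []
    pieces: list[tuple[int, int]] = []
    cur_start, cur_end = ivals[0]
    for start, end in ivals[1:]:
        if start >= cur_end:  # coverage gap: junction, drop the gap
            pieces.append((cur_start, cur_end))
            cur_start, cur_end = start, end
        elif cur_end - start < min_overlap:  # low overlap: junction at cur_end
            pieces.append((cur_start, cur_end))
            cur_start = cur_end
            cur_end = max(cur_end, end)
        else:
            cur_end = max(cur_end, end)
    pieces.append((cur_start, cur_end))
    return [
        (Region(transcript.id, s, e), transcript.bases[s:e]) for s, e in pieces
    ]


def call_site(
    pileup_site: PileupSite, params: CallerParams, sex: Sex
) -> frozenset[str]:
    """Alleles at one site passing the support rule for the given sex.

    An allele (reference included) is called when its quality-passing
    support is >= min_alt_reads, or >= min_alt_reads_lowcov when the raw
    depth is <= lowcov_threshold. N is never called."""
    sex = Sex(sex)
    depth = pileup_site.depth[sex]
    need = (
        params.min_alt_reads_lowcov
        if depth <= params.lowcov_threshold
        else params.min_alt_reads
    )
    called = {
        allele
        for allele, (_, qual) in pileup_site.counts[sex].items()
        if allele != "N" and qual >= need
    }
    return frozenset(called)


def make_site_call(
    pileup_site: PileupSite, params: CallerParams
) -> SiteCall:
    return SiteCall(
        target_id=pileup_site.target_id,
        pos=pileup_site.pos,
        ref_allele=pileup_site.ref_allele,
        called_alleles={s: call_site(pileup_site, params, s) for s in Sex},
        depth=dict(pileup_site.depth),
    )


def categorize_site(
    male_call: SiteCall,
    female_call: SiteCall,
    ref_allele: str,
    female_ref_qual_count: int = 0,
    params: CallerParams | None = None,
) -> CategorizedSite:
    """Assign exactly one category to a site from its per-sex calls.

    "Polymorphic" in males means the reference allele and exactly one
    non-reference allele both pass the support rule. Sites with two or more
    non-reference male alleles cannot name a unique Y-specific variant and
    fall into CAT2. `female_ref_qual_count` is the number of
    quality-passing female reads carrying the reference, used for the
    strict "all female reads showed a variant" clause of CAT1."""
    params = params or CallerParams()
    if male_call.ref_allele != female_call.ref_allele:
        raise ValueError(
            f"conflicting reference alleles at {male_call.target_id}:"
            f"{male_call.pos}: {male_call.ref_allele!r} vs {female_call.ref_allele!r}"
        )
    if ref_allele != male_call.ref_allele:
        raise ValueError(
            f"stale site list at {male_call.target_id}:{male_call.pos}: "
            f"expected ref {male_call.ref_allele!r}, got {ref_allele!r}"
        )
    male = male_call.called_alleles[Sex.male]
    female = female_call.called_alleles[Sex.female]
    male_nonref = male - {ref_allele}
    female_nonref = female - {ref_allele}
    male_polymorphic = ref_allele in male and len(male_nonref) == 1

    site = SiteCall(
        target_id=male_call.target_id,
        pos=male_call.pos,
        ref_allele=ref_allele,
        called_alleles={Sex.male: male, Sex.female: female},
        depth={
            Sex.male: male_call.depth[Sex.male],
            Sex.female: female_call.depth[Sex.female],
        },
    )
    if len(male_nonref) >= 2:
        # multi-allelic in males: no unique Y allele, leave unchanged
        return CategorizedSite(site=site, category=CAT2)
    if (
        male_polymorphic
        and female_nonref
        and ref_allele not in female
        and female_ref_qual_count <= params.cat1_ref_tolerance
    ):
        # the female (X) allele: prefer the one males are polymorphic for
        shared = male_nonref & female_nonref
        sub = (
            next(iter(female_nonref))
            if len(female_nonref) == 1
            else next(iter(shared))
            if shared
            else sorted(female_nonref)[0]
        )
        return CategorizedSite(site=site, category=CAT1, substitution_allele=sub)
    if male_nonref and female_nonref:
        return CategorizedSite(site=site, category=CAT2)
    if male_polymorphic and not female_nonref:
        return CategorizedSite(
            site=site, category=CAT3, substitution_allele=next(iter(male_nonref))
        )
    return CategorizedSite(site=site, category=INVARIANT)


def categorize_pileups(
    male_pileup: Pileup,
    female_pileup: Pileup,
    params: CallerParams | None = None,
) -> tuple[list[CategorizedSite], int]:
    """Categorize every candidate site of a target from per-sex pileups.

    Returns (non-INVARIANT categorized sites, site universe size), the
    universe being positions covered in both sexes. Positions are
    prefiltered with a vectorized support check so only plausible variant
    sites go through the scalar rule; the remainder are INVARIANT by
    construction (no allele but reference can reach the support bound)."""
    params = params or CallerParams()
    if male_pileup.target_id != female_pileup.target_id:
        raise ValueError("pileups refer to different targets")
    L = male_pileup.length
    m_depth = male_pileup.depth[Sex.male]
    f_depth = female_pileup.depth[Sex.female]
    universe = (m_depth > 0) & (f_depth > 0)

    ref_idx = encode(male_pileup.ref).astype(np.intp)
    cols = np.arange(L)

    def nonref_support(pile: Pileup, sex: Sex, depth: np.ndarray) -> np.ndarray:
        qual = pile.base_qual[sex][:, :4].copy()
        valid = ref_idx < 4
        qual[cols[valid], ref_idx[valid]] = 0
        need = np.where(
            depth <= params.lowcov_threshold,
            params.min_alt_reads_lowcov,
            params.min_alt_reads,
        )
        return (qual.max(axis=1) >= need) & (depth > 0)

    candidate = nonref_support(male_pileup, Sex.male, m_depth) | nonref_support(
        female_pileup, Sex.female, f_depth
    )
    for (pos, _allele), rec in male_pileup.indels.items():
        if rec[Sex.male][1] >= params.min_alt_reads_lowcov:
            candidate[pos] = True
    for (pos, _allele), rec in female_pileup.indels.items():
        if rec[Sex.female][1] >= params.min_alt_reads_lowcov:
            candidate[pos] = True
    candidate &= universe

    sites: list[CategorizedSite] = []
    for pos in np.flatnonzero(candidate):
        pos = int(pos)
        m_site = male_pileup.site(pos)
        f_site = female_pileup.site(pos)
        ref = male_pileup.ref[pos]
        m_call = make_site_call(m_site, params)
        f_call = make_site_call(f_site, params)
        f_ref_qual = f_site.counts[Sex.female].get(ref, (0, 0))[1]
        cat = categorize_site(
            m_call, f_call, ref, female_ref_qual_count=f_ref_qual, params=params
        )
        if cat.category != INVARIANT:
            sites.append(cat)
    return sites, int(universe.sum())


def _parse_allele(allele: str) -> tuple[str, int, str]:
    """Return (kind, length, payload) for an allele string."""
    if allele.startswith("-"):
        return "del", int(allele[1:]), ""
    if allele.startswith("+"):
        return "ins", len(allele) - 1, allele[1:]
    return "snp", 1, allele


def select_rewrite_sites(
    categorized_sites: Sequence[CategorizedSite], direction: str = "toY"
) -> list[CategorizedSite]:
    """Drop substitutions whose edit intervals overlap an earlier one.

    SNP substitutions win over indel substitutions at the same position
    (systematic gap artifacts near junctions can collide with real SNPs);
    otherwise the leftmost edit is kept. The result satisfies the
    non-overlap precondition of rewrite_haplotype."""
    want_cat = CAT3 if direction == "toY" else CAT1
    prio = {"snp": 0, "ins": 1, "del": 2}

    def key(s: CategorizedSite) -> tuple[int, int]:
        kind, _, _ = _parse_allele(s.substitution_allele or "")
        return (s.site.pos, prio[kind])

    edits = sorted(
        (s for s in categorized_sites if s.category == want_cat and s.substitution_allele),
        key=key,
    )
    kept: list[CategorizedSite] = []
    others = [s for s in categorized_sites if s.category != want_cat]
    last_end = -1
    for s in edits:
        kind, length, _ = _parse_allele(s.substitution_allele or "")
        span = length if kind == "del" else 1
        if s.site.pos < last_end:
            continue
        kept.append(s)
        last_end = s.site.pos + span
    return sorted(kept + others, key=lambda s: s.site.pos)


def rewrite_haplotype(
    transcript: Transcript,
    categorized_sites: Sequence[CategorizedSite],
    direction: str = "toY",
) -> tuple[Transcript, np.ndarray]:
    """Rewrite a transcript into one haplotype by applying substitutions.

    direction "toY": every CAT3 site's reference allele is replaced by its
    substitution allele (SNP or indel); CAT1/CAT2 untouched. direction
    "toX": CAT1 sites are replaced by the female allele (CAT3 sites already
    carry the female-matching reference). Returns the rewritten transcript
    and an old->new coordinate map of length len+1. Rewriting is
    idempotent: a site already carrying its substitution allele is
    skipped; any other mismatch with the recorded reference is an error."""
    if direction not in ("toY", "toX"):
        raise ValueError(f"unknown direction {direction!r}")
    want_cat = CAT3 if direction == "toY" else CAT1
    edits = sorted(
        (s for s in categorized_sites if s.category == want_cat),
        key=lambda s: s.site.pos,
    )
    seq = transcript.bases
    L = len(seq)
    out: list[str] = []
    offset_map = np.empty(L + 1, dtype=np.int64)
    new_len = 0

    def emit(segment: str) -> None:
        nonlocal new_len
        out.append(segment)
        new_len += len(segment)

    last_end = 0
    for cs in edits:
        pos = cs.site.pos
        allele = cs.substitution_allele
        if allele is None:
            raise ValueError(f"{want_cat} site at {pos} lacks a substitution allele")
        if pos < last_end:
            raise ValueError(f"overlapping substitutions at {pos}")
        kind, length, payload = _parse_allele(allele)
        # copy untouched span
        offset_map[last_end : pos + 1] = np.arange(
            new_len, new_len + (pos - last_end) + 1
        )
        emit(seq[last_end:pos])
        if kind == "snp":
            if seq[pos] == allele:
                emit(allele)  # already rewritten: idempotent no-op
            elif seq[pos] == cs.site.ref_allele:
                emit(allele)
            else:
                raise ValueError(
                    f"stale site list: {transcript.id}:{pos} has "
                    f"{seq[pos]!r}, expected {cs.site.ref_allele!r}"
                )
            last_end = pos + 1
        elif kind == "del":
            if pos + length > L:
                raise ValueError(f"deletion at {pos} runs past transcript end")
            last_end = pos + length
            offset_map[pos + 1 : last_end + 1] = new_len
        else:  # ins (payload inserted before pos)
            emit(payload)
            last_end = pos
    offset_map[last_end : L + 1] = np.arange(
        new_len, new_len + (L - last_end) + 1
    )
    emit(seq[last_end:])
    new_bases = "".join(out)
    if not new_bases:
        raise ValueError(f"rewrite of {transcript.id} produced an empty sequence")
    return (
        Transcript(
            id=transcript.id,
            bases=new_bases,
            chrom_class=transcript.chrom_class,
            ref_protein_id=transcript.ref_protein_id,
        ),
        offset_map,
    )


def filter_supported_regions(
    rewritten_transcript: Transcript,
    rna_exact_alignments: Sequence[Alignment],
    categorized_sites: Sequence[CategorizedSite],
    diagnostic_positions: Sequence[int] | None = None,
) -> list[KeptRegion]:
    """Keep maximal RNA-covered runs that contain >= 1 diagnostic site.

    RNA alignments must be zero-mismatch placements on the REWRITTEN
    sequence. `diagnostic_positions` overrides the positions taken from
    CAT1/CAT3 sites (use it when site coordinates were shifted by indel
    rewriting). Runs without a diagnostic variant are dropped — this is
    what removes homomorphic and silenced-homolog transcripts."""
    L = len(rewritten_transcript.bases)
    cov = np.zeros(L + 1, dtype=np.int32)
    for a in rna_exact_alignments:
        if a.target_id != rewritten_transcript.id:
            continue
        cov[a.target_start] += 1
        cov[a.target_end] -= 1
    cov = np.cumsum(cov[:-1])
    if diagnostic_positions is None:
        diag = sorted(
            s.site.pos for s in categorized_sites if s.is_diagnostic
        )
    else:
        diag = sorted(diagnostic_positions)
    diag_arr = np.zeros(L, dtype=bool)
    for p in diag:
        if 0 <= p < L:
            diag_arr[p] = True
    covered = cov >= 1
    out: list[KeptRegion] = []
    pos = 0
    while pos < L:
        if not covered[pos]:
            pos += 1
            continue
        end = pos
        while end < L and covered[end]:
            end += 1
        n_diag = int(diag_arr[pos:end].sum())
        if n_diag >= 1:
            out.append(
                KeptRegion(
                    region=Region(rewritten_transcript.id, pos, end),
                    n_diagnostic_sites=n_diag,
                    rna_min_coverage=int(cov[pos:end].min()),
                )
            )
        pos = end
    return out
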