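"""Coverage-based gene-loss screens.

Two screens: (1) genes deleted from the X haplotype show zero female
genomic coverage of the male transcript and no polymorphism among male
genomic reads; (2) for genes with an expressed X copy but no recovered Y
transcript, the normalized male/female genomic coverage ratio on the X
transcript separates Y-deleted copies (males carry one mappable copy
against the females' two, ratio ~0.5) from present-but-silenced copies
(both male copies map, ratio ~1). The 0.7 / 0.85 verdict thresholds are
configurable; normalization uses a per-sex baseline such as the autosomal
(or cohort) median depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .haplotype import SiteCall
from .mapper import Alignment
from .seqio import Sex, Transcript

Y_DELETED = "Y_deleted"
Y_PRESENT_SILENCED = "Y_present_silenced"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CoverageProfile:
    transcript_id: str
    mean_depth: dict[Sex, float]
    fraction_covered: dict[Sex, float]
    n_polymorphic_sites_male: int = 0


@dataclass(frozen=True)
class DeletionCandidate:
    transcript_id: str
    female_fraction_covered: float
    n_polymorphic_sites_male: int
    zero_female_coverage: bool
    male_monomorphic: bool

    @property
    def is_candidate(self) -> bool:
        return self.zero_female_coverage and self.male_monomorphic


@dataclass(frozen=True)
class AbsenceVerdict:
    transcript_id: str
    male_mean_depth: float
    female_mean_depth: float
    normalized_ratio: float
    verdict: str


def coverage_profile(
    transcript: Transcript,
    alignments: Iterable[Alignment],
    read_sex: Mapping[str, Sex],
    n_polymorphic_sites_male: int = 0,
) -> CoverageProfile:
    """Mean depth and fraction of positions covered, per sex."""
    L = len(transcript.bases)
    diff = {s: np.zeros(L + 1, dtype=np.int64) for s in Sex}
    for a in alignments:
        if a.target_id != transcript.id:
            continue
        s = read_sex[a.read_id]
        diff[s][a.target_start] += 1
        diff[s][a.target_end] -= 1
    mean_depth = {}
    fraction = {}
    for s in Sex:
        depth = np.cumsum(diff[s][:-1])
        mean_depth[s] = float(depth.mean())
        fraction[s] = float((depth > 0).mean())
    return CoverageProfile(
        transcript_id=transcript.id,
        mean_depth=mean_depth,
        fraction_covered=fraction,
        n_polymorphic_sites_male=n_polymorphic_sites_male,
    )


def count_male_polymorphic_sites(site_calls: Iterable[SiteCall]) -> dict[str, int]:
    """Per-target count of sites where male reads show any non-reference
    called allele ('polymorphism among male genomic reads')."""
    out: dict[str, int] = {}
    for sc in site_calls:
        male = sc.called_alleles[Sex.male]
        if male - {sc.ref_allele}:
            out[sc.target_id] = out.get(sc.target_id, 0) + 1
    return out


def neoX_deletion_screen(
    male_transcripts: Sequence[Transcript],
    female_genomic_alignments: Sequence[Alignment],
    male_site_calls: Sequence[SiteCall],
    read_sex: Mapping[str, Sex] | None = None,
) -> list[DeletionCandidate]:
    """Flag male transcripts absent from the female genome.

    A transcript is a deletion candidate iff its female genomic coverage is
    exactly zero AND male genomic reads show no polymorphism (a polymorphic
    male pileup suggests collapsed paralogs instead). Both clauses are
    reported separately for every transcript."""
    cov_start: dict[str, int] = {}
    for a in female_genomic_alignments:
        cov_start[a.target_id] = cov_start.get(a.target_id, 0) + 1
    covered_frac: dict[str, float] = {}
    for t in male_transcripts:
        alns = [a for a in female_genomic_alignments if a.target_id == t.id]
        if not alns:
            covered_frac[t.id] = 0.0
            continue
        L = len(t.bases)
        diff = np.zeros(L + 1, dtype=np.int64)
        for a in alns:
            diff[a.target_start] += 1
            diff[a.target_end] -= 1
        covered_frac[t.id] = float((np.cumsum(diff[:-1]) > 0).mean())
    poly = count_male_polymorphic_sites(male_site_calls)
    out = []
    for t in male_transcripts:
        frac = covered_frac[t.id]
        n_poly = poly.get(t.id, 0)
        out.append(
            DeletionCandidate(
                transcript_id=t.id,
                female_fraction_covered=frac,
                n_polymorphic_sites_male=n_poly,
                zero_female_coverage=frac == 0.0,
                male_monomorphic=n_poly == 0,
            )
        )
    return out


def neoY_absence_screen(
    neoX_transcripts: Sequence[Transcript],
    male_coverage: Mapping[str, float],
    female_coverage: Mapping[str, float],
    depth_normalizers: tuple[float, float],
    deleted_below: float = 0.7,
    silenced_above: float = 0.85,
) -> list[AbsenceVerdict]:
    """Classify untranscribed Y copies as deleted vs. present-but-silenced.

    `male_coverage` / `female_coverage` give mean genomic depth of each X
    transcript per sex; `depth_normalizers` = (male, female) baseline
    depths (e.g. autosomal medians). The normalized male/female ratio is
    ~0.5 when the Y copy is deleted (one mappable male copy vs. the
    females' two) and ~1 when present."""
    male_norm, female_norm = depth_normalizers
    if male_norm <= 0 or female_norm <= 0:
        raise ValueError("depth normalizers must be positive")
    out = []
    for t in neoX_transcripts:
        m = float(male_coverage.get(t.id, 0.0))
        f = float(female_coverage.get(t.id, 0.0))
        if f <= 0:
            verdict = AMBIGUOUS
            ratio = float("nan")
        else:
            ratio = (m / male_norm) / (f / female_norm)
            if ratio < deleted_below:
                verdict = Y_DELETED
            elif ratio >= silenced_above:
                verdict = Y_PRESENT_SILENCED
            else:
                verdict = AMBIGUOUS
        out.append(
            AbsenceVerdict(
                transcript_id=t.id,
                male_mean_depth=m,
                female_mean_depth=f,
                normalized_ratio=ratio,
                verdict=verdict,
            )
        )
    return out
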