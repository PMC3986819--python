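"""Synthetic neo-sex-chromosome datasets with full ground truth.

Each simulated gene has an ancestral transcript (5'UTR + CDS + 3'UTR) with
introns in its genomic form. Two haplotypes (neoX, neoY) diverge from the
ancestor by independent per-site substitution; an outgroup sits further
away. Lesions (premature stops, frameshift indels), silencing and
deletions are injected into the neoY per configured fractions. Genomic
reads are drawn 50/50 from both haplotypes in males and from the neoX only
in females; RNA reads follow per-haplotype expression levels with
non-functional copies down-regulated. Everything is driven by one seeded
RNG, so a fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mapper import left_align_deletion, left_align_insertion, revcomp
from .seqio import (
    ChromClass,
    ReadRecord,
    ReadSource,
    Sex,
    Transcript,
    write_table,
)

STOPS = ("TAA", "TAG", "TGA")
_B = "ACGT"

# lesion / fate classes, mutually exclusive per gene
INTACT = "intact"
PTC = "ptc"
FRAMESHIFT = "frameshift"
Y_SILENCED = "y_silenced"
Y_DELETED = "y_deleted"
X_DELETED = "x_deleted"


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 200
    mean_cds_codons: int = 400
    neoXY_divergence: float = 0.015
    outgroup_divergence: float = 0.021
    indel_rate: float = 0.0002  # intron/UTR background indels only
    frac_ptc: float = 0.09
    frac_frameshift: float = 0.19
    frac_neoY_silenced: float = 0.05
    frac_neoY_deleted: float = 0.05
    frac_neoX_deleted: float = 0.02
    n_introns: int = 2
    read_length: int = 100
    male_genomic_depth: float = 45.0
    female_genomic_depth: float = 62.0
    rna_depth: float = 50.0
    nonfunctional_expression_factor: float = 0.5
    sequencing_error_rate: float = 0.0
    utr5_len: int = 60
    utr3_mean: int = 300
    chimera_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_ptc,
            self.frac_frameshift,
            self.frac_neoY_silenced,
            self.frac_neoY_deleted,
            self.frac_neoX_deleted,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1.0:
            raise ValueError(
                "gene fate classes are exclusive; fractions must sum to <= 1"
            )
        if min(self.male_genomic_depth, self.female_genomic_depth, self.rna_depth) <= 0:
            raise ValueError("depths must be positive")
        if not (0 <= self.neoXY_divergence < 1 and 0 <= self.outgroup_divergence < 1):
            raise ValueError("divergences must lie in [0, 1)")


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene.

    Transcript coordinates of diagnostic sites refer to the ancestral/neoX
    backbone, which is also the coordinate system of the male input
    transcript (the neoX carries no transcript indels)."""

    gene_id: str
    n_codons: int
    cds_start: int
    cds_end: int  # end of CDS incl. stop codon, backbone coords
    fate: str
    neoX_tx: str
    neoY_tx: str
    outgroup_tx: str
    male_tx: str
    neoX_genomic: str | None
    neoY_genomic: str | None
    diagnostic_sites: list[tuple[int, str, str]]  # (pos, X allele, Y allele)
    diagnostic_indel: tuple[int, str] | None  # (anchor pos, allele e.g. '-2')
    ptc_codon_index: int | None
    frameshift_tx_pos: int | None
    frameshift_codon_index: int | None
    x_level: float
    y_level: float

    @property
    def neoX_deleted(self) -> bool:
        return self.fate == X_DELETED

    @property
    def neoY_deleted(self) -> bool:
        return self.fate == Y_DELETED

    @property
    def neoY_silenced(self) -> bool:
        return self.fate == Y_SILENCED


@dataclass
class SimTruth:
    config: SimConfig
    genes: list[GeneTruth]

    def gene(self, gene_id: str) -> GeneTruth:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class SimBundle:
    """Pipeline inputs plus ground truth for one simulated dataset."""

    truth: SimTruth
    male_transcripts: list[Transcript]
    female_transcripts: list[Transcript]
    reference_cds: list[Transcript]  # outgroup CDS (incl. stop codon)
    reference_transcripts: list[Transcript]  # outgroup full transcripts


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_B[i] for i in rng.integers(0, 4, size=n))


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = _random_seq(rng, 3)
        if c not in STOPS:
            return c


def _safe_alt(
    rng: np.random.Generator, seq: str, pos: int, cds_start: int, cds_end: int
) -> str | None:
    """A random alternative base at pos that does not create a stop codon
    when pos lies in the CDS. Start and stop codons are never touched."""
    ref = seq[pos]
    if cds_start <= pos < cds_end:
        codon_idx = (pos - cds_start) // 3
        n_codons = (cds_end - cds_start) // 3
        if codon_idx == 0 or codon_idx == n_codons - 1:
            return None  # keep ATG and the ancestral stop intact
        c0 = cds_start + codon_idx * 3
        codon = seq[c0 : c0 + 3]
        off = pos - c0
        alts = [b for b in _B if b != ref]
        rng.shuffle(alts)
        for b in alts:
            if codon[:off] + b + codon[off + 1 :] not in STOPS:
                return b
        return None
    alts = [b for b in _B if b != ref]
    return alts[rng.integers(0, 3)]


def _scrub_stop_creating_subs(
    anc: str, subs: dict[int, str], cds_start: int, cds_end: int
) -> None:
    """Remove substitution combinations that jointly form a stop codon
    (individually stop-safe edits can still combine into one)."""
    seq = _apply_subs(anc, subs)
    n_codons = (cds_end - cds_start) // 3
    for ci in range(n_codons - 1):  # the final (real) stop stays
        c0 = cds_start + 3 * ci
        if seq[c0 : c0 + 3] in STOPS:
            for p in range(c0, c0 + 3):
                subs.pop(p, None)


def _apply_subs(seq: str, subs: dict[int, str]) -> str:
    if not subs:
        return seq
    chars = list(seq)
    for pos, base in subs.items():
        chars[pos] = base
    return "".join(chars)


def _choose_fate(rng: np.random.Generator, config: SimConfig) -> str:
    u = rng.random()
    edges = (
        (config.frac_ptc, PTC),
        (config.frac_frameshift, FRAMESHIFT),
        (config.frac_neoY_silenced, Y_SILENCED),
        (config.frac_neoY_deleted, Y_DELETED),
        (config.frac_neoX_deleted, X_DELETED),
    )
    acc = 0.0
    for frac, fate in edges:
        acc += frac
        if u < acc:
            return fate
    return INTACT


def _build_gene(
    rng: np.random.Generator, config: SimConfig, gene_id: str
) -> GeneTruth:
    n_codons = int(
        np.clip(
            round(rng.normal(config.mean_cds_codons, config.mean_cds_codons / 4)),
            60,
            2 * config.mean_cds_codons,
        )
    )
    cds = "ATG" + "".join(_random_codon(rng) for _ in range(n_codons - 2))
    cds += STOPS[rng.integers(0, 3)]
    utr5 = _random_seq(rng, config.utr5_len)
    utr3 = _random_seq(rng, int(rng.exponential(config.utr3_mean)) + 30)
    anc = utr5 + cds + utr3
    L = len(anc)
    cds_start = len(utr5)
    cds_end = cds_start + 3 * n_codons

    # intron insertion points (between transcript bases, inside the CDS)
    intron_points: list[int] = []
    if config.n_introns > 0 and cds_end - cds_start > 120:
        pts = rng.choice(
            np.arange(cds_start + 30, cds_end - 30),
            size=min(config.n_introns, 4),
            replace=False,
        )
        intron_points = sorted(int(p) for p in pts)
    intron_seqs = [
        _random_seq(rng, int(rng.integers(60, 300))) for _ in intron_points
    ]
    # intergenic flanks so genomic coverage is uniform across the transcript
    flank5 = _random_seq(rng, 150)
    flank3 = _random_seq(rng, 150)

    fate = _choose_fate(rng, config)

    # haplotype substitutions on the transcript
    x_subs: dict[int, str] = {}
    y_subs: dict[int, str] = {}
    site_mask = rng.random(L) < config.neoXY_divergence
    for pos in np.flatnonzero(site_mask):
        pos = int(pos)
        alt = _safe_alt(rng, anc, pos, cds_start, cds_end)
        if alt is None:
            continue
        if rng.random() < 0.5:
            x_subs[pos] = alt
        else:
            y_subs[pos] = alt

    _scrub_stop_creating_subs(anc, x_subs, cds_start, cds_end)
    _scrub_stop_creating_subs(anc, y_subs, cds_start, cds_end)

    # outgroup substitutions at the residual distance
    out_rate = max(0.0, config.outgroup_divergence - config.neoXY_divergence / 2)
    o_subs: dict[int, str] = {}
    for pos in np.flatnonzero(rng.random(L) < out_rate):
        pos = int(pos)
        alt = _safe_alt(rng, anc, pos, cds_start, cds_end)
        if alt is not None:
            o_subs[pos] = alt
    _scrub_stop_creating_subs(anc, o_subs, cds_start, cds_end)

    ptc_codon = None
    fs_pos = None
    fs_codon = None
    fs_allele: str | None = None
    if fate == PTC:
        ptc_codon = int(rng.integers(5, n_codons - 5))
        c0 = cds_start + ptc_codon * 3
        for off, b in enumerate("TAA"):
            y_subs[c0 + off] = b
    elif fate == FRAMESHIFT:
        length = int(rng.integers(1, 3))  # 1 or 2 bp
        kind = "del" if rng.random() < 0.5 else "ins"
        for _ in range(100):
            q = int(rng.integers(cds_start + 30, cds_end - 45))
            near = any(abs(q - p) < length + 6 for p in intron_points)
            if not near:
                break
        fs_pos = q
        fs_codon = (q - cds_start) // 3
        if kind == "ins":
            fs_allele = "+" + _random_seq(rng, length)
        else:
            fs_allele = f"-{length}"

    neoX_tx = _apply_subs(anc, x_subs)
    neoY_pre = _apply_subs(anc, y_subs)

    # diagnostic SNP sites: positions where the built haplotypes differ
    diag_sites = []
    for pos in sorted(set(x_subs) | set(y_subs)):
        xb, yb = neoX_tx[pos], neoY_pre[pos]
        if xb != yb:
            diag_sites.append((pos, xb, yb))

    diagnostic_indel = None
    if fs_pos is not None:
        assert fs_allele is not None
        if fs_allele.startswith("-"):
            length = int(fs_allele[1:])
            neoY_tx = neoY_pre[:fs_pos] + neoY_pre[fs_pos + length :]
            anchor = left_align_deletion(neoX_tx, fs_pos, length)
            diagnostic_indel = (anchor, fs_allele)
        else:
            ins = fs_allele[1:]
            neoY_tx = neoY_pre[:fs_pos] + ins + neoY_pre[fs_pos:]
            anchor, rot = left_align_insertion(neoX_tx, fs_pos, ins)
            diagnostic_indel = (anchor, "+" + rot)
    else:
        neoY_tx = neoY_pre

    outgroup_tx = _apply_subs(anc, o_subs)

    # genomic sequences: haplotype transcript with introns re-inserted
    def genomic(tx: str, hap: str) -> str:
        def hap_flank(seq: str) -> str:
            fmask = rng.random(len(seq)) < config.neoXY_divergence / 2
            return _apply_subs(
                seq, {int(j): _B[rng.integers(0, 4)] for j in np.flatnonzero(fmask)}
            )

        pieces: list[str] = [hap_flank(flank5)]
        prev = 0
        for idx, p in enumerate(intron_points):
            p_adj = p
            if hap == "Y" and fs_pos is not None and fs_pos < p:
                p_adj = p + (len(neoY_tx) - len(neoX_tx))
            pieces.append(tx[prev:p_adj])
            iseq = intron_seqs[idx]
            # haplotype-specific intron substitutions and background indels
            imask = rng.random(len(iseq)) < config.neoXY_divergence / 2
            isubs = {
                int(j): _B[rng.integers(0, 4)] for j in np.flatnonzero(imask)
            }
            iseq = _apply_subs(iseq, isubs)
            if config.indel_rate > 0:
                cuts = np.flatnonzero(rng.random(len(iseq)) < config.indel_rate)
                for j in sorted((int(c) for c in cuts), reverse=True):
                    if 0 < j < len(iseq) - 1:
                        iseq = iseq[:j] + iseq[j + 1 :]
            pieces.append(iseq)
            prev = p_adj
        pieces.append(tx[prev:])
        pieces.append(hap_flank(flank3))
        return "".join(pieces)

    neoX_genomic = None if fate == X_DELETED else genomic(neoX_tx, "X")
    neoY_genomic = None if fate == Y_DELETED else genomic(neoY_tx, "Y")

    # male input transcript: neoX backbone, possibly chimeric at SNP sites
    if fate == X_DELETED:
        male_tx = neoY_tx  # only the Y copy exists
    elif fate in (Y_DELETED, PTC, FRAMESHIFT):
        # the down-regulated (or absent) Y copy contributes few RNA reads,
        # so the assembled male transcript follows the X backbone
        male_tx = neoX_tx
    elif rng.random() < config.chimera_prob and diag_sites:
        # assembler chimeras switch haplotype inside locally undifferentiated
        # stretches, so breakpoints go mid-gap between diagnostic sites
        # separated by more than a read length (no read can straddle both)
        site_pos = [p for p, _x, _y in diag_sites]
        gaps = [
            (a + b) // 2
            for a, b in zip([0] + site_pos, site_pos + [L])
            if b - a > config.read_length + 10
        ]
        n_bp = min(int(rng.integers(1, 3)), len(gaps))
        bps = (
            sorted(int(g) for g in rng.choice(gaps, size=n_bp, replace=False))
            if n_bp
            else []
        )
        hap = "X" if rng.random() < 0.5 else "Y"
        prev = 0
        chars = list(neoX_tx)
        for b in bps + [L]:
            if hap == "Y":
                for pos, _xb, yb in diag_sites:
                    if prev <= pos < b:
                        chars[pos] = yb
            hap = "Y" if hap == "X" else "X"
            prev = b
        male_tx = "".join(chars)
    else:
        male_tx = neoX_tx if rng.random() < 0.5 else _apply_subs(
            neoX_tx, {pos: yb for pos, _xb, yb in diag_sites}
        )

    x_level = float(rng.lognormal(1.5, 1.0))
    if fate in (PTC, FRAMESHIFT):
        y_level = x_level * config.nonfunctional_expression_factor
    elif fate in (Y_SILENCED, Y_DELETED):
        y_level = 0.0
    else:
        y_level = x_level
    if fate == X_DELETED:
        x_level = 0.0

    return GeneTruth(
        gene_id=gene_id,
        n_codons=n_codons,
        cds_start=cds_start,
        cds_end=cds_end,
        fate=fate,
        neoX_tx=neoX_tx,
        neoY_tx=neoY_tx,
        outgroup_tx=outgroup_tx,
        male_tx=male_tx,
        neoX_genomic=neoX_genomic,
        neoY_genomic=neoY_genomic,
        diagnostic_sites=diag_sites,
        diagnostic_indel=diagnostic_indel,
        ptc_codon_index=ptc_codon,
        frameshift_tx_pos=fs_pos,
        frameshift_codon_index=fs_codon,
        x_level=x_level,
        y_level=y_level,
    )


def simulate_gene_set(config: SimConfig) -> SimBundle:
    """Simulate the full gene set and assemble pipeline input transcripts."""
    rng = _rng_for(config, 0)
    genes = [
        _build_gene(rng, config, f"g{i:04d}") for i in range(config.n_genes)
    ]
    truth = SimTruth(config=config, genes=genes)
    male_transcripts = [
        Transcript(id=g.gene_id, bases=g.male_tx, chrom_class=ChromClass.unknown)
        for g in genes
    ]
    female_transcripts = [
        Transcript(id=f"{g.gene_id}_X", bases=g.neoX_tx, chrom_class=ChromClass.neoX)
        for g in genes
        if not g.neoX_deleted
    ]
    reference_cds = [
        Transcript(
            id=f"ref_{g.gene_id}",
            bases=g.outgroup_tx[g.cds_start : g.cds_end],
        )
        for g in genes
    ]
    reference_transcripts = [
        Transcript(id=f"ref_{g.gene_id}", bases=g.outgroup_tx) for g in genes
    ]
    return SimBundle(
        truth=truth,
        male_transcripts=male_transcripts,
        female_transcripts=female_transcripts,
        reference_cds=reference_cds,
        reference_transcripts=reference_transcripts,
    )


def _draw_reads(
    rng: np.random.Generator,
    seq: str,
    n: int,
    read_len: int,
    prefix: str,
    sex: Sex,
    source: ReadSource,
    error_rate: float,
) -> list[ReadRecord]:
    L = len(seq)
    if L < read_len or n <= 0:
        return []
    starts = rng.integers(0, L - read_len + 1, size=n)
    flips = rng.random(n) < 0.5
    out = []
    for i, (s, flip) in enumerate(zip(starts, flips)):
        bases = seq[s : s + read_len]
        quals = [40] * read_len
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_len) < error_rate)
            if errs.size:
                chars = list(bases)
                for e in errs:
                    e = int(e)
                    chars[e] = _B[
                        (_B.index(chars[e]) + int(rng.integers(1, 4))) % 4
                    ] if chars[e] in _B else "N"
                    quals[e] = 11
                bases = "".join(chars)
        if flip:
            bases = revcomp(bases)
            quals = quals[::-1]
        out.append(
            ReadRecord(
                id=f"{prefix}:{i}",
                bases=bases,
                quals=tuple(quals),
                sex=sex,
                source=source,
            )
        )
    return out


def simulate_genomic_reads(
    truth: SimTruth, config: SimConfig | None = None
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Uniform-coverage genomic reads per sex.

    Males carry one neoX and one neoY copy, so each haplotype is sampled at
    half the male depth; females carry neoX only, at the full female
    depth. Deleted haplotypes yield no reads."""
    config = config or truth.config
    rng = _rng_for(config, 1)
    rl = config.read_length
    male: list[ReadRecord] = []
    female: list[ReadRecord] = []
    for g in truth.genes:
        for hap, seq, depth, sink, sex in (
            ("X", g.neoX_genomic, config.male_genomic_depth / 2, male, Sex.male),
            ("Y", g.neoY_genomic, config.male_genomic_depth / 2, male, Sex.male),
            ("X", g.neoX_genomic, config.female_genomic_depth, female, Sex.female),
        ):
            if seq is None:
                continue
            if sex == Sex.female and hap == "Y":
                continue
            n = round(depth * len(seq) / rl)
            sink.extend(
                _draw_reads(
                    rng,
                    seq,
                    n,
                    rl,
                    prefix=f"{sex.value[0]}g:{g.gene_id}:{hap}",
                    sex=sex,
                    source=ReadSource.genomic,
                    error_rate=config.sequencing_error_rate,
                )
            )
    return male, female


def simulate_rna_reads(
    truth: SimTruth,
    config: SimConfig | None = None,
    sample: str = "male",
) -> list[ReadRecord]:
    """RNA reads for one sample, multinomial over (gene, haplotype)
    proportional to expression level x transcript length.

    The male sample draws from both haplotypes' transcripts; the female
    sample from the neoX only. Silenced/deleted copies have level 0."""
    config = config or truth.config
    if sample not in ("male", "female"):
        raise ValueError("sample must be 'male' or 'female'")
    rng = _rng_for(config, 2 if sample == "male" else 3)
    rl = config.read_length
    sex = Sex.male if sample == "male" else Sex.female
    pool: list[tuple[str, str, str]] = []  # (gene, hap, seq)
    weights: list[float] = []
    for g in truth.genes:
        entries = [("X", g.neoX_tx, g.x_level)]
        if sample == "male":
            entries.append(("Y", g.neoY_tx, g.y_level))
        for hap, seq, level in entries:
            if hap == "X" and g.neoX_deleted:
                continue
            if level <= 0 or len(seq) < rl:
                continue
            pool.append((g.gene_id, hap, seq))
            weights.append(level * len(seq))
    if not pool:
        return []
    w = np.asarray(weights)
    expressed_len = sum(len(seq) for _, _, seq in pool)
    total = round(config.rna_depth * expressed_len / rl)
    counts = rng.multinomial(total, w / w.sum())
    out: list[ReadRecord] = []
    for (gene, hap, seq), n in zip(pool, counts):
        out.extend(
            _draw_reads(
                rng,
                seq,
                int(n),
                rl,
                prefix=f"{sample[0]}r:{gene}:{hap}",
                sex=sex,
                source=ReadSource.rna,
                error_rate=config.sequencing_error_rate,
            )
        )
    return out


def write_truth_tables(truth: SimTruth, outdir: str | Path) -> None:
    """Persist ground truth as TSVs (genes, diagnostic sites, lesions)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(
        [
            {
                "gene_id": g.gene_id,
                "fate": g.fate,
                "n_codons": g.n_codons,
                "cds_start": g.cds_start,
                "cds_end": g.cds_end,
                "x_level": g.x_level,
                "y_level": g.y_level,
                "n_diagnostic_sites": len(g.diagnostic_sites),
            }
            for g in truth.genes
        ],
        outdir / "truth_genes.tsv",
        schema=[
            "gene_id",
            "fate",
            "n_codons",
            "cds_start",
            "cds_end",
            "x_level",
            "y_level",
            "n_diagnostic_sites",
        ],
    )
    site_rows = []
    for g in truth.genes:
        for pos, xb, yb in g.diagnostic_sites:
            site_rows.append(
                {"gene_id": g.gene_id, "pos": pos, "x_allele": xb, "y_allele": yb}
            )
        if g.diagnostic_indel is not None:
            pos, allele = g.diagnostic_indel
            site_rows.append(
                {"gene_id": g.gene_id, "pos": pos, "x_allele": "-", "y_allele": allele}
            )
    write_table(
        site_rows,
        outdir / "truth_sites.tsv",
        schema=["gene_id", "pos", "x_allele", "y_allele"],
    )
    lesion_rows = [
        {
            "gene_id": g.gene_id,
            "type": g.fate,
            "ptc_codon_index": g.ptc_codon_index,
            "frameshift_tx_pos": g.frameshift_tx_pos,
        }
        for g in truth.genes
        if g.fate in (PTC, FRAMESHIFT)
    ]
    write_table(
        lesion_rows,
        outdir / "truth_lesions.tsv",
        schema=["gene_id", "type", "ptc_codon_index", "frameshift_tx_pos"],
    )
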