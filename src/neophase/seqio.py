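"""Shared sequence types and FASTA/FASTQ/TSV input-output.

Coordinates are 0-based, half-open everywhere. FASTQ qualities are Sanger
Phred+33. All tabular output is TSV with a header row, rows sorted by the
first schema column and floats printed with six decimals so files diff
reproducibly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when a sequence file violates its format contract."""


class ChromClass(str, enum.Enum):
    neoX = "neoX"
    neoY = "neoY"
    autosome = "autosome"
    unknown = "unknown"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class ReadSource(str, enum.Enum):
    genomic = "genomic"
    rna = "rna"


@dataclass(frozen=True)
class Transcript:
    """A named nucleotide sequence with an optional chromosome-class label."""

    id: str
    bases: str
    chrom_class: ChromClass = ChromClass.unknown
    ref_protein_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.bases:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read tagged with the sex and library type it came from."""

    id: str
    bases: str
    quals: tuple[int, ...]
    sex: Sex
    source: ReadSource

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, order=True)
class Region:
    """Half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.seq_id}:[{self.start},{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _normalize_bases(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(
    path: str | Path,
    chrom_class: ChromClass = ChromClass.unknown,
) -> list[Transcript]:
    """Read a FASTA file into Transcripts.

    Sequences are uppercased and U is normalized to T. Duplicate ids and
    empty sequences are errors; records are never silently dropped.
    """
    path = Path(path)
    out: list[Transcript] = []
    seen: set[str] = set()
    with path.open() as fh:
        for i, (header, seq) in enumerate(SimpleFastaParser(fh), start=1):
            rid = header.split()[0] if header.split() else ""
            if not rid:
                raise ParseError(f"{path}: record {i}: empty FASTA header")
            if rid in seen:
                raise ParseError(f"{path}: record {i}: duplicate id {rid!r}")
            seen.add(rid)
            if not seq:
                raise ParseError(f"{path}: record {i} ({rid}): empty sequence")
            bases = _normalize_bases(seq)
            bad = set(bases) - _VALID_BASES
            if bad:
                raise ParseError(
                    f"{path}: record {i} ({rid}): invalid characters "
                    f"{sorted(bad)!r}"
                )
            out.append(Transcript(id=rid, bases=bases, chrom_class=chrom_class))
    return out


def write_fasta(
    transcripts: Iterable[Transcript], path: str | Path, width: int = 70
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.bases), width):
                fh.write(t.bases[i : i + width] + "\n")


def read_fastq(path: str | Path, sex: Sex, source: ReadSource) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a Sanger Phred+33 FASTQ file."""
    path = Path(path)
    sex = Sex(sex)
    source = ReadSource(source)
    with path.open() as fh:
        try:
            for i, (header, seq, qual) in enumerate(
                FastqGeneralIterator(fh), start=1
            ):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {i}: sequence/quality length mismatch"
                    )
                rid = header.split()[0]
                quals = tuple(ord(c) - 33 for c in qual)
                if any(q < 0 for q in quals):
                    raise ParseError(
                        f"{path}: record {i}: quality character below '!'"
                    )
                yield ReadRecord(
                    id=rid,
                    bases=_normalize_bases(seq),
                    quals=quals,
                    sex=sex,
                    source=source,
                )
        except ValueError as exc:  # malformed 4-line block from Biopython
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def _format_value(v: object) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return f"{v:.6f}"
    if v is None:
        return "NA"
    return str(v)


def write_table(
    records: Iterable[Mapping[str, object]],
    path: str | Path,
    schema: Sequence[str],
) -> None:
    """Write records as TSV with deterministic column and row order.

    Rows are sorted by the first schema column; floats are fixed to six
    decimals. Missing keys are an error (records must conform to schema).
    """
    path = Path(path)
    rows = []
    for rec in records:
        missing = [c for c in schema if c not in rec]
        if missing:
            raise ValueError(f"record missing schema columns {missing}")
        rows.append(tuple(_format_value(rec[c]) for c in schema))
    rows.sort(key=lambda r: r[0])
    with path.open("w") as fh:
        fh.write("\t".join(schema) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV written by write_table back into string-valued dicts."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [
            dict(zip(header, line.rstrip("\n").split("\t"), strict=True))
            for line in fh
            if line.strip()
        ]
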