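"""Readers, writers and dataset assembly for methylation modeling.

The on-disk formats are deliberately minimal: FASTA for amplicon/promoter
sequences, a tab-separated per-CpG-site methylation table, BED6 for segment
configurations and JSON for fitted models.  All genomic coordinates are
0-based half-open; a CpG site is addressed by the position of its C on the
forward strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MethylationRecord",
    "AmpliconRecord",
    "Dataset",
    "FastaParseError",
    "DuplicateRecordError",
    "ValidationError",
    "read_fasta",
    "read_methylation_table",
    "write_methylation_table",
    "assemble_dataset",
    "write_segments_bed",
]


class FastaParseError(ValueError):
    """Malformed FASTA input (names the offending line where possible)."""


class DuplicateRecordError(ValueError):
    """Two records share an identifier or address the same measurement."""


class ValidationError(ValueError):
    """A field value violates its documented domain."""


TSV_COLUMNS = ["chrom", "pos", "strand", "level", "coverage", "cell_type"]


@dataclass(frozen=True)
class MethylationRecord:
    """One CpG site's measured methylation level in one cell type.

    ``level`` is the fraction of bisulfite reads (or clones) methylated at
    the site, a real number in [0, 1].  ``pos`` is the 0-based genomic
    position of the C of the CpG dinucleotide.
    """

    chrom: str
    pos: int
    strand: str
    level: float
    cell_type: str
    coverage: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValidationError(
                f"methylation level {self.level} outside [0, 1] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.coverage is not None and self.coverage < 0:
            raise ValidationError(f"negative coverage {self.coverage}")


@dataclass
class AmpliconRecord:
    """A promoter/amplicon sequence with its CpG-site offsets.

    ``cpg_offsets`` holds the 0-based offsets (into ``sequence``) of the C
    of every CpG dinucleotide; the amplicon is the modeling unit inside
    which segments live.
    """

    id: str
    chrom: str
    start: int
    end: int
    sequence: str
    cpg_offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.end - self.start != len(self.sequence):
            raise ValidationError(
                f"amplicon {self.id}: span {self.start}-{self.end} does not "
                f"match sequence length {len(self.sequence)}"
            )
        if not self.cpg_offsets:
            self.cpg_offsets = find_cpg_offsets(self.sequence)
        for o in self.cpg_offsets:
            if self.sequence[o : o + 2] != "CG":
                raise ValidationError(
                    f"amplicon {self.id}: offset {o} is not a CpG"
                )

    def genomic_position(self, offset: int) -> int:
        return self.start + offset


@dataclass
class Dataset:
    """Amplicons joined with per-cell-type methylation measurements.

    ``sites`` maps ``(amplicon_id, cell_type)`` to an offset-sorted list of
    ``(cpg_offset, level)`` pairs.  ``n_dropped`` counts input records that
    matched no amplicon CpG and were discarded during assembly.
    """

    amplicons: list[AmpliconRecord]
    sites: dict[tuple[str, str], list[tuple[int, float]]]
    cell_types: list[str]
    n_dropped: int = 0

    def amplicon_by_id(self, amplicon_id: str) -> AmpliconRecord:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def sites_for(self, amplicon_id: str, cell_type: str) -> list[tuple[int, float]]:
        return self.sites.get((amplicon_id, cell_type), [])


def find_cpg_offsets(sequence: str) -> list[int]:
    """Offsets of every CG dinucleotide in ``sequence`` (forward strand)."""
    seq = sequence.upper()
    offsets = []
    i = seq.find("CG")
    while i != -1:
        offsets.append(i)
        i = seq.find("CG", i + 1)
    return offsets


def _parse_fasta_header(description: str) -> tuple[str, str, Optional[int], Optional[int]]:
    # header convention: "id chrom:start-end"; coordinates optional
    parts = description.split(None, 1)
    rec_id = parts[0]
    chrom, start, end = "synthetic", None, None
    if len(parts) == 2 and ":" in parts[1]:
        loc = parts[1].split()[0]
        chrom, span = loc.rsplit(":", 1)
        if "-" in span:
            a, b = span.split("-", 1)
            try:
                start, end = int(a), int(b)
            except ValueError as exc:
                raise FastaParseError(
                    f"bad coordinate span {span!r} in header {description!r}"
                ) from exc
    return rec_id, chrom, start, end


def read_fasta(path: str) -> list[AmpliconRecord]:
    """Read amplicon sequences, uppercasing and scanning for CpG sites.

    Headers follow ``>id chrom:start-end``; without coordinates the record
    is placed on chromosome "synthetic" starting at 0.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header, "
                    f"got {line.strip()[:40]!r}"
                )
            break
    records: list[AmpliconRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        rec_id, chrom, start, end = _parse_fasta_header(rec.description)
        if rec_id in seen:
            raise DuplicateRecordError(f"duplicate FASTA record id {rec_id!r}")
        seen.add(rec_id)
        seq = str(rec.seq).upper()
        if start is None:
            start, end = 0, len(seq)
        records.append(
            AmpliconRecord(id=rec_id, chrom=chrom, start=start, end=end, sequence=seq)
        )
    return records


def write_fasta(amplicons: Iterable[AmpliconRecord], path: str) -> None:
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(f">{a.id} {a.chrom}:{a.start}-{a.end}\n")
            for i in range(0, len(a.sequence), 70):
                fh.write(a.sequence[i : i + 70] + "\n")


def read_methylation_table(path: str, skip_invalid: bool = False) -> list[MethylationRecord]:
    """Read the tab-separated per-site methylation table.

    Columns: chrom, pos, strand, level, coverage, cell_type.  Levels outside
    [0, 1] abort with the offending row number unless ``skip_invalid``.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "cell_type": str},
        float_precision="round_trip",
    )
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records: list[MethylationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            pos = int(row.pos)
            if pos != float(row.pos):
                raise ValueError
        except (TypeError, ValueError):
            raise ValidationError(f"{path}: row {i}: non-integer position {row.pos!r}")
        cov = None if pd.isna(row.coverage) else int(row.coverage)
        try:
            records.append(
                MethylationRecord(
                    chrom=str(row.chrom),
                    pos=pos,
                    strand=str(row.strand),
                    level=float(row.level),
                    coverage=cov,
                    cell_type=str(row.cell_type),
                )
            )
        except ValidationError as exc:
            if skip_invalid:
                continue
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_methylation_table(records: Iterable[MethylationRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.chrom,
                    r.pos,
                    r.strand,
                    repr(r.level) if isinstance(r.level, float) else r.level,
                    "" if r.coverage is None else r.coverage,
                    r.cell_type,
                ]
            )


def assemble_dataset(
    amplicons: list[AmpliconRecord], records: Iterable[MethylationRecord]
) -> Dataset:
    """Join measurements onto amplicon CpG sites.

    Minus-strand measurements are mapped to the forward-strand C of the same
    CpG dinucleotide (pos - 1) before joining, so a CpG site is one unit.
    Records matching no amplicon CpG are counted and dropped.  A duplicate
    (amplicon, cell type, offset) triple is an error.
    """
    index: dict[tuple[str, int], tuple[str, int]] = {}
    for a in amplicons:
        for o in a.cpg_offsets:
            index[(a.chrom, a.start + o)] = (a.id, o)

    sites: dict[tuple[str, str], dict[int, float]] = {}
    cell_types: list[str] = []
    n_dropped = 0
    for r in records:
        pos = r.pos - 1 if r.strand == "-" else r.pos
        hit = index.get((r.chrom, pos))
        if hit is None:
            n_dropped += 1
            continue
        amp_id, offset = hit
        key = (amp_id, r.cell_type)
        bucket = sites.setdefault(key, {})
        if offset in bucket:
            raise DuplicateRecordError(
                f"duplicate measurement for amplicon {amp_id}, "
                f"cell type {r.cell_type}, offset {offset}"
            )
        bucket[offset] = r.level
        if r.cell_type not in cell_types:
            cell_types.append(r.cell_type)

    sorted_sites = {
        key: sorted(bucket.items()) for key, bucket in sorted(sites.items())
    }
    return Dataset(
        amplicons=list(amplicons),
        sites=sorted_sites,
        cell_types=sorted(cell_types),
        n_dropped=n_dropped,
    )


def write_segments_bed(configuration, path: str, scores=None) -> None:
    """Write one BED6 line per segment of a configuration.

    The genomic span runs from the first CpG's C through the position after
    the last CpG's G (0-based half-open).  ``scores``, when given, are the
    model's predicted levels y-hat per segment; the BED score column is
    round(1000 * y-hat).
    """
    segments = configuration.segments
    with open(path, "w") as fh:
        for i, seg in enumerate(segments):
            yhat = scores[i] if scores is not None else seg.p
            fh.write(
                "\t".join(
                    [
                        seg.chrom,
                        str(seg.genomic_start),
                        str(seg.genomic_end),
                        f"{seg.amplicon_id}.seg{i}",
                        str(int(round(1000 * float(yhat)))),
                        "+",
                    ]
                )
                + "\n"
            )
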