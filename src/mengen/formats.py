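"""Record types and file I/O for the pipeline's tabular formats.

All internal coordinates are 1-based inclusive. BEDPE, whose coordinates are
0-based half-open, is converted at the boundary on ingest and on write.
Chromosome names are normalized by stripping any ``chr`` prefix; autosomes
1-22 plus X and Y are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
AUTOSOMES = tuple(str(i) for i in range(1, 23))

CLASSIFICATIONS = (
    "missense",
    "nonsense",
    "splice_site",
    "frameshift_indel",
    "inframe_indel",
    "silent",
    "noncoding",
)

#: Classes counted as protein-altering ("nonsynonymous") throughout.
NONSYNONYMOUS = frozenset(
    {"missense", "nonsense", "splice_site", "frameshift_indel", "inframe_indel"}
)

# MAF-style variant classifications mapped onto the internal enum.
_CLASSIFICATION_ALIASES = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "nonstop_mutation": "nonsense",
    "splice_site": "splice_site",
    "frame_shift_del": "frameshift_indel",
    "frame_shift_ins": "frameshift_indel",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "silent": "silent",
    "synonymous": "silent",
    "3'utr": "noncoding",
    "5'utr": "noncoding",
    "intron": "noncoding",
    "igr": "noncoding",
    "rna": "noncoding",
    "5'flank": "noncoding",
    "3'flank": "noncoding",
}

SV_CLASSES = ("deletion", "duplication", "inversion", "translocation")

GRADES = ("I", "II", "III")
RADIATION_STATUSES = ("naive", "radiation_induced", "post_adjuvant_RT")


class FormatError(ValueError):
    """A file does not conform to the expected schema (e.g. missing column)."""


class RecordValidationError(ValueError):
    """A row violates a record invariant; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and validate against 1-22, X, Y."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    if c == "24":
        c = "Y"
    if c not in VALID_CHROMS:
        raise RecordValidationError(f"unrecognized chromosome {chrom!r}")
    return c


def normalize_classification(value: str) -> str:
    v = str(value).strip().lower()
    if v in CLASSIFICATIONS:
        return v
    if v in _CLASSIFICATION_ALIASES:
        return _CLASSIFICATION_ALIASES[v]
    raise RecordValidationError(f"unrecognized variant classification {value!r}")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV/indel call in one sample."""

    sample_id: str
    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    classification: str
    t_alt_count: int
    t_depth: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(
            self, "classification", normalize_classification(self.classification)
        )
        if self.pos < 1:
            raise RecordValidationError(f"pos must be >= 1, got {self.pos}")
        if self.t_alt_count < 0 or self.t_depth < 0:
            raise RecordValidationError("read counts must be nonnegative")
        if self.t_alt_count > self.t_depth:
            raise RecordValidationError(
                f"t_alt_count ({self.t_alt_count}) exceeds t_depth ({self.t_depth})"
            )

    @property
    def allele_fraction(self) -> float:
        """Fraction of reads supporting the mutant allele (0 when depth is 0)."""
        return self.t_alt_count / self.t_depth if self.t_depth > 0 else 0.0

    @property
    def is_nonsynonymous(self) -> bool:
        return self.classification in NONSYNONYMOUS

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
            and self.ref != self.alt
        )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Gene-independent identity of the somatic event."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment (log2 ratio, 0 = copy-neutral) for one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    log2_ratio: float

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise RecordValidationError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise RecordValidationError(
                f"segment start {self.start} exceeds end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class JunctionRecord:
    """One rearrangement junction with two breakends plus junction context.

    ``homology_len`` and ``insertion_len`` are mutually exclusive: a junction
    reports either microhomology or a templated insertion (both zero allowed).
    """

    sample_id: str
    chromA: str
    posA: int
    strandA: str
    chromB: str
    posB: int
    strandB: str
    sv_class: str
    homology_len: int = 0
    insertion_len: int = 0
    repeatA: bool = False
    repeatB: bool = False

    def __post_init__(self):
        object.__setattr__(self, "chromA", normalize_chrom(self.chromA))
        object.__setattr__(self, "chromB", normalize_chrom(self.chromB))
        if self.strandA not in "+-" or self.strandB not in "+-":
            raise RecordValidationError("strands must be '+' or '-'")
        if self.posA < 1 or self.posB < 1:
            raise RecordValidationError("breakend positions must be >= 1")
        if self.sv_class not in SV_CLASSES:
            raise RecordValidationError(f"unrecognized sv_class {self.sv_class!r}")
        inter = self.chromA != self.chromB
        if inter != (self.sv_class == "translocation"):
            raise RecordValidationError(
                f"sv_class {self.sv_class!r} inconsistent with chromosome pair "
                f"{self.chromA}/{self.chromB}"
            )
        if self.homology_len < 0 or self.insertion_len < 0:
            raise RecordValidationError("junction context lengths must be >= 0")
        if self.homology_len > 0 and self.insertion_len > 0:
            raise RecordValidationError(
                "a junction reports either microhomology or an insertion, not both"
            )

    @property
    def breakends(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chromA, self.posA), (self.chromB, self.posB))


def intrachromosomal_class(strandA: str, strandB: str) -> str:
    """Derive the intrachromosomal SV class from the breakend strand pair."""
    if (strandA, strandB) == ("+", "-"):
        return "deletion"
    if (strandA, strandB) == ("-", "+"):
        return "duplication"
    return "inversion"  # +/+ or -/-


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical and assay metadata."""

    sample_id: str
    patient_id: str
    resection_index: int
    grade: str
    histology: str
    radiation_status: str
    purity: float
    ploidy: float
    mean_coverage: float

    def __post_init__(self):
        if self.resection_index < 1:
            raise RecordValidationError("resection_index must be >= 1")
        if self.grade not in GRADES:
            raise RecordValidationError(f"unrecognized grade {self.grade!r}")
        if self.radiation_status not in RADIATION_STATUSES:
            raise RecordValidationError(
                f"unrecognized radiation_status {self.radiation_status!r}"
            )
        if not (0 < self.purity <= 1):
            raise RecordValidationError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise RecordValidationError("ploidy must be > 0")


# ---------------------------------------------------------------------------
# Readers / writers. All files are UTF-8, tab-separated, with a header line.
# ---------------------------------------------------------------------------

_MUTATION_COLUMNS = [
    "sample_id",
    "patient_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "classification",
    "t_alt_count",
    "t_depth",
]

_SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "n_probes", "log2_ratio"]

# Canonical SEG headers (as emitted by DNAcopy/ReCapseg-style tools).
_SEG_ALIASES = {
    "id": "sample_id",
    "sample": "sample_id",
    "loc.start": "start",
    "loc.end": "end",
    "num.mark": "n_probes",
    "seg.mean": "log2_ratio",
}

_BEDPE_COLUMNS = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "name",
    "score",
    "strand1",
    "strand2",
    "sample_id",
    "sv_class",
    "HOMLEN",
    "INSLEN",
    "REPEAT_A",
    "REPEAT_B",
]

_META_COLUMNS = [
    "sample_id",
    "patient_id",
    "resection_index",
    "grade",
    "histology",
    "radiation_status",
    "purity",
    "ploidy",
    "mean_coverage",
]


def _read_table(path, required: Sequence[str], aliases: dict | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if aliases:
        df = df.rename(columns=lambda c: aliases.get(c.strip().lower(), c))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_mutations(path, dialect: str = "tsv") -> list[MutationRecord]:
    """Read a MAF-like TSV of somatic mutation calls.

    Every row is validated against the record invariants; a violation raises
    :class:`RecordValidationError` carrying the file line number.
    """
    if dialect not in ("tsv", "maf"):
        raise FormatError(f"unknown dialect {dialect!r}")
    df = _read_table(path, _MUTATION_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            records.append(
                MutationRecord(
                    sample_id=row.sample_id,
                    patient_id=row.patient_id,
                    gene=row.gene,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    classification=row.classification,
                    t_alt_count=int(row.t_alt_count),
                    t_depth=int(row.t_depth),
                )
            )
        except RecordValidationError as e:
            raise RecordValidationError(str(e), line=line) from None
        except ValueError as e:
            raise RecordValidationError(str(e), line=line) from None
    return records


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_MUTATION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    str(getattr(r, c)) for c in _MUTATION_COLUMNS
                )
                + "\n"
            )


def read_segments(path) -> list[SegmentRecord]:
    """Read a SEG file; per-sample per-chromosome segments are sorted and
    checked for overlap."""
    df = _read_table(path, _SEG_COLUMNS, aliases=_SEG_ALIASES)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            records.append(
                SegmentRecord(
                    sample_id=row.sample_id,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    n_probes=int(row.n_probes),
                    log2_ratio=float(row.log2_ratio),
                )
            )
        except (RecordValidationError, ValueError) as e:
            raise RecordValidationError(str(e), line=line) from None
    records.sort(key=lambda r: (r.sample_id, _chrom_sort_key(r.chrom), r.start))
    prev = None
    for r in records:
        if (
            prev is not None
            and prev.sample_id == r.sample_id
            and prev.chrom == r.chrom
            and r.start <= prev.end
        ):
            raise RecordValidationError(
                f"overlapping segments for {r.sample_id} chr{r.chrom}: "
                f"[{prev.start}, {prev.end}] and [{r.start}, {r.end}]"
            )
        prev = r
    return records


def write_segments(records: Iterable[SegmentRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SEG_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                f"{r.n_probes}\t{r.log2_ratio:g}\n"
            )


def _parse_bool(v: str) -> bool:
    return str(v).strip().lower() in ("1", "true", "t", "yes", "y")


def read_junctions(path) -> list[JunctionRecord]:
    """Read rearrangement junctions from BEDPE with junction-context columns.

    BEDPE coordinates are 0-based half-open; breakend positions become
    1-based (``start + 1``) on ingest. When ``sv_class`` is absent (``.``),
    the intrachromosomal class is derived from the strand pair and
    interchromosomal junctions become translocations.
    """
    df = _read_table(path, _BEDPE_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        sv_class = str(row.sv_class).strip()
        chromA, chromB = str(row.chrom1), str(row.chrom2)
        try:
            if sv_class in (".", "", "na"):
                if normalize_chrom(chromA) != normalize_chrom(chromB):
                    sv_class = "translocation"
                else:
                    sv_class = intrachromosomal_class(row.strand1, row.strand2)
            records.append(
                JunctionRecord(
                    sample_id=row.sample_id,
                    chromA=chromA,
                    posA=int(row.start1) + 1,
                    strandA=row.strand1,
                    chromB=chromB,
                    posB=int(row.start2) + 1,
                    strandB=row.strand2,
                    sv_class=sv_class,
                    homology_len=int(row.HOMLEN),
                    insertion_len=int(row.INSLEN),
                    repeatA=_parse_bool(row.REPEAT_A),
                    repeatB=_parse_bool(row.REPEAT_B),
                )
            )
        except (RecordValidationError, ValueError) as e:
            raise RecordValidationError(str(e), line=line) from None
    return records


def write_junctions(records: Iterable[JunctionRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_BEDPE_COLUMNS) + "\n")
        for j in records:
            fh.write(
                "\t".join(
                    [
                        j.chromA,
                        str(j.posA - 1),
                        str(j.posA),
                        j.chromB,
                        str(j.posB - 1),
                        str(j.posB),
                        ".",
                        ".",
                        j.strandA,
                        j.strandB,
                        j.sample_id,
                        j.sv_class,
                        str(j.homology_len),
                        str(j.insertion_len),
                        str(j.repeatA),
                        str(j.repeatB),
                    ]
                )
                + "\n"
            )


def read_sample_meta(path) -> list[SampleMeta]:
    df = _read_table(path, _META_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            records.append(
                SampleMeta(
                    sample_id=row.sample_id,
                    patient_id=row.patient_id,
                    resection_index=int(row.resection_index),
                    grade=row.grade,
                    histology=row.histology,
                    radiation_status=row.radiation_status,
                    purity=float(row.purity),
                    ploidy=float(row.ploidy),
                    mean_coverage=float(row.mean_coverage),
                )
            )
        except (RecordValidationError, ValueError) as e:
            raise RecordValidationError(str(e), line=line) from None
    seen: dict[tuple[str, int], str] = {}
    for m in records:
        key = (m.patient_id, m.resection_index)
        if key in seen:
            raise RecordValidationError(
                f"duplicate resection_index {m.resection_index} for patient "
                f"{m.patient_id} (samples {seen[key]} and {m.sample_id})"
            )
        seen[key] = m.sample_id
    return records


def write_sample_meta(records: Iterable[SampleMeta], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for m in records:
            fh.write(
                f"{m.sample_id}\t{m.patient_id}\t{m.resection_index}\t{m.grade}\t"
                f"{m.histology}\t{m.radiation_status}\t{m.purity:g}\t{m.ploidy:g}\t"
                f"{m.mean_coverage:g}\n"
            )


def _chrom_sort_key(chrom: str) -> int:
    if chrom == "X":
        return 23
    if chrom == "Y":
        return 24
    return int(chrom)
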