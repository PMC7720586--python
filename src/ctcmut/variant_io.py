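"""Mutation callset and cohort-metadata I/O.

Domain types for somatic mutation records from matched lesion pairs
(primary tumor and circulating-tumor-cell sample), plus readers/writers
for a MAF-like TSV dialect, a minimal VCF 4.x dialect, and the cohort
metadata table.

Coordinates are 1-based VCF convention. Mutation identity is exact
``(chrom, pos, ref, alt)``; annotation never enters the key.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Lesion",
    "FuncClass",
    "MutationKey",
    "MutationRecord",
    "PairedCallset",
    "LoadReport",
    "CohortCase",
    "CohortMetadata",
    "ValidationError",
    "ParseError",
    "collapse_strand",
    "reverse_complement",
    "read_maf_table",
    "write_maf_table",
    "group_paired_callsets",
    "read_vcf_pair",
    "write_vcf",
    "read_cohort_metadata",
    "summarize_cohort_metadata",
    "read_gene_list",
    "SUBSTITUTION_CLASSES",
    "CONTEXT_LABELS_96",
    "context_label",
    "context_index",
]


class ValidationError(ValueError):
    """Raised when input content violates a documented contract."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; message names the offending line."""


class Lesion(str, enum.Enum):
    PRIMARY = "primary"
    CTC = "ctc"


class FuncClass(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SILENT = "silent"
    SPLICE = "splice"
    INDEL = "indel"
    OTHER = "other"


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Pyrimidine-referenced single-base substitution classes, canonical order.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 trinucleotide-context labels, ordered (class, 5' base, 3' base).
CONTEXT_LABELS_96 = tuple(
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)

_CONTEXT_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS_96)}


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValidationError(f"non-ACGT base in sequence {seq!r}") from exc


def context_label(substitution_class: str, context: str) -> str:
    """Build the ``A[C>T]G``-style label from a class and pyrimidine context."""
    return f"{context[0]}[{substitution_class}]{context[2]}"


def context_index(label: str) -> int:
    """Position of a 96-context label in the canonical ordering."""
    try:
        return _CONTEXT_INDEX[label]
    except KeyError as exc:
        raise ValidationError(f"unknown context label {label!r}") from exc


def collapse_strand(ref: str, alt: str, context: Optional[str] = None):
    """Collapse a single-base substitution onto the pyrimidine strand.

    Returns ``(substitution_class, pyrimidine_context)`` where the class is
    one of the six C/T-referenced classes. Purine-referenced calls are
    reverse-complemented (class and context alike). ``context`` may be
    omitted, in which case the second element is ``None``.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValidationError(f"collapse_strand requires single-base alleles, got {ref!r}>{alt!r}")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValidationError(f"non-ACGT allele in {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref equals alt: {ref!r}")
    if context is not None:
        if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
            raise ValidationError(f"context must be a 3-mer over ACGT, got {context!r}")
        if context[1] != ref:
            raise ValidationError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref in "CT":
        return f"{ref}>{alt}", context
    flipped_ref = _COMPLEMENT[ref]
    flipped_alt = _COMPLEMENT[alt]
    flipped_ctx = reverse_complement(context) if context is not None else None
    return f"{flipped_ref}>{flipped_alt}", flipped_ctx


@dataclass(frozen=True, order=True)
class MutationKey:
    """Genomic identity of a mutation; equality defines cross-lesion matching."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call in one lesion of one case."""

    case_id: str
    lesion: Lesion
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    func_class: FuncClass = FuncClass.OTHER
    context: Optional[str] = None
    alt_depth: Optional[int] = None
    ref_depth: Optional[int] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref equals alt at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError(f"empty allele at {self.chrom}:{self.pos}")
        is_indel = len(self.ref) != len(self.alt)
        if is_indel != (self.func_class is FuncClass.INDEL):
            raise ValidationError(
                f"func_class {self.func_class.value!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )
        if self.context is not None:
            if len(self.context) != 3 or any(b not in _COMPLEMENT for b in self.context):
                raise ValidationError(f"bad context {self.context!r} at {self.chrom}:{self.pos}")
            if self.is_snv and self.context[1] != self.ref:
                raise ValidationError(
                    f"context middle base {self.context[1]!r} != ref {self.ref!r} "
                    f"at {self.chrom}:{self.pos}"
                )
        for name in ("alt_depth", "ref_depth"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> MutationKey:
        return MutationKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PairedCallset:
    """A case's primary and CTC mutation sets, keys unique within each lesion."""

    case_id: str
    primary: list[MutationRecord] = field(default_factory=list)
    ctc: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self):
        for lesion, records in (("primary", self.primary), ("ctc", self.ctc)):
            seen = Counter(r.key for r in records)
            dups = [k for k, n in seen.items() if n > 1]
            if dups:
                raise ValidationError(
                    f"case {self.case_id}: duplicate mutation key(s) in {lesion} set: "
                    f"{dups[0].chrom}:{dups[0].pos} {dups[0].ref}>{dups[0].alt}"
                )

    def records(self, lesion: Lesion) -> list[MutationRecord]:
        return self.primary if lesion is Lesion.PRIMARY else self.ctc

    def keys(self, lesion: Lesion) -> set[MutationKey]:
        return {r.key for r in self.records(lesion)}

    def by_key(self, lesion: Lesion) -> dict[MutationKey, MutationRecord]:
        return {r.key: r for r in self.records(lesion)}

    def all_records(self) -> list[MutationRecord]:
        return list(self.primary) + list(self.ctc)


@dataclass
class LoadReport:
    """Bookkeeping for records dropped or skipped during a load."""

    n_loaded: int = 0
    n_filtered: int = 0
    filter_values: Counter = field(default_factory=Counter)


# ---------------------------------------------------------------------------
# MAF-like TSV dialect
# ---------------------------------------------------------------------------

_MAF_REQUIRED = ("case_id", "lesion", "chrom", "pos", "ref", "alt")
_MAF_OPTIONAL = ("gene", "func_class", "context", "alt_depth", "ref_depth")


def _parse_int(value: str, what: str, line_no: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"line {line_no}: cannot parse {what} {value!r} as integer") from None


def read_maf_table(path: str | os.PathLike) -> list[MutationRecord]:
    """Read a MAF-like TSV into mutation records.

    The header must name at least ``case_id lesion chrom pos ref alt``;
    ``gene func_class context alt_depth ref_depth`` are optional. Empty
    optional cells yield absent fields. Duplicate (case, lesion, key) rows
    are rejected.
    """
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, no header") from None
        missing = [c for c in _MAF_REQUIRED if c not in header]
        if missing:
            raise ParseError(f"{path}: header missing required column(s) {missing}")
        col = {name: header.index(name) for name in header}
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue

            def cell(name: str) -> str:
                i = col.get(name)
                return row[i].strip() if i is not None and i < len(row) else ""

            pos = _parse_int(cell("pos"), "pos", line_no)
            kwargs: dict = {}
            if cell("gene"):
                kwargs["gene"] = cell("gene")
            if cell("func_class"):
                try:
                    kwargs["func_class"] = FuncClass(cell("func_class"))
                except ValueError:
                    raise ParseError(
                        f"line {line_no}: unknown func_class {cell('func_class')!r}"
                    ) from None
            elif len(cell("ref")) != len(cell("alt")):
                kwargs["func_class"] = FuncClass.INDEL
            if cell("context"):
                kwargs["context"] = cell("context")
            for depth in ("alt_depth", "ref_depth"):
                if cell(depth):
                    kwargs[depth] = _parse_int(cell(depth), depth, line_no)
            try:
                lesion = Lesion(cell("lesion"))
            except ValueError:
                raise ParseError(f"line {line_no}: unknown lesion {cell('lesion')!r}") from None
            try:
                rec = MutationRecord(
                    case_id=cell("case_id"),
                    lesion=lesion,
                    chrom=cell("chrom"),
                    pos=pos,
                    ref=cell("ref"),
                    alt=cell("alt"),
                    **kwargs,
                )
            except ValidationError as exc:
                raise ParseError(f"line {line_no}: {exc}") from None
            ident = (rec.case_id, rec.lesion, rec.key)
            if ident in seen:
                raise ValidationError(
                    f"line {line_no}: duplicate mutation for case {rec.case_id} "
                    f"lesion {rec.lesion.value}: {rec.chrom}:{rec.pos} {rec.ref}>{rec.alt}"
                )
            seen.add(ident)
            records.append(rec)
    return records


def write_maf_table(records: Iterable[MutationRecord], path: str | os.PathLike) -> None:
    """Write records to the MAF-like TSV dialect (all columns, empty = absent)."""
    columns = _MAF_REQUIRED + _MAF_OPTIONAL
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for r in records:
            writer.writerow(
                [
                    r.case_id,
                    r.lesion.value,
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.gene,
                    r.func_class.value,
                    r.context or "",
                    "" if r.alt_depth is None else r.alt_depth,
                    "" if r.ref_depth is None else r.ref_depth,
                ]
            )


def group_paired_callsets(records: Iterable[MutationRecord]) -> list[PairedCallset]:
    """Group a flat record collection into per-case paired callsets.

    Cases are returned sorted by case_id.
    """
    by_case: dict[str, dict[Lesion, list[MutationRecord]]] = {}
    for r in records:
        by_case.setdefault(r.case_id, {Lesion.PRIMARY: [], Lesion.CTC: []})[r.lesion].append(r)
    return [
        PairedCallset(case_id=cid, primary=sets[Lesion.PRIMARY], ctc=sets[Lesion.CTC])
        for cid, sets in sorted(by_case.items())
    ]


# ---------------------------------------------------------------------------
# Minimal VCF 4.x dialect
# ---------------------------------------------------------------------------

_FUNC_ALIASES = {f.value: f for f in FuncClass}


def _allelic_depths(ad) -> Optional[list[int]]:
    """Normalize cyvcf2's AD field (typed array, or string when undeclared)."""
    if ad is None:
        return None
    first = ad[0]
    if isinstance(first, (bytes, str)):
        text = first.decode() if isinstance(first, bytes) else first
        try:
            return [int(x) for x in text.split(",")]
        except ValueError:
            return None
    try:
        return [int(x) for x in first]
    except (TypeError, ValueError):
        return None


def _read_vcf_one(path, case_id, lesion, strip_chr_prefix, report):
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise IOError(f"VCF file not found: {path}")
    records: list[MutationRecord] = []
    vcf = VCF(str(path))
    try:
        for variant in vcf:
            if variant.FILTER is not None:  # cyvcf2: None means PASS or '.'
                report.n_filtered += 1
                report.filter_values[variant.FILTER] += 1
                continue
            chrom = variant.CHROM
            if strip_chr_prefix and chrom.startswith("chr"):
                chrom = chrom[3:]
            gene = variant.INFO.get("GENE") or ""
            func = variant.INFO.get("FUNC")
            ctx = variant.INFO.get("CTX")
            try:
                ad = variant.format("AD")
            except KeyError:
                ad = None
            depths = _allelic_depths(ad)
            for i, alt in enumerate(variant.ALT):
                is_indel = len(variant.REF) != len(alt)
                if is_indel:
                    func_class = FuncClass.INDEL
                elif func and func in _FUNC_ALIASES:
                    func_class = _FUNC_ALIASES[func]
                else:
                    func_class = FuncClass.OTHER
                alt_depth = ref_depth = None
                if depths is not None and len(depths) > i + 1:
                    ref_depth, alt_depth = depths[0], depths[i + 1]
                    if ref_depth < 0 or alt_depth < 0:  # htslib missing sentinel
                        ref_depth = alt_depth = None
                records.append(
                    MutationRecord(
                        case_id=case_id,
                        lesion=lesion,
                        chrom=chrom,
                        pos=variant.POS,
                        ref=variant.REF,
                        alt=alt,
                        gene=gene,
                        func_class=func_class,
                        context=ctx if (ctx and not is_indel) else None,
                        alt_depth=alt_depth,
                        ref_depth=ref_depth,
                    )
                )
            report.n_loaded = len(records)
    finally:
        vcf.close()
    return records


def read_vcf_pair(
    primary_path: str | os.PathLike,
    ctc_path: str | os.PathLike,
    case_id: str,
    strip_chr_prefix: bool = False,
) -> tuple[PairedCallset, LoadReport]:
    """Read one case's primary and CTC VCFs into a paired callset.

    Multi-allelic ALTs are split into one record per alternate allele.
    Records whose FILTER is anything other than PASS or '.' are dropped and
    counted in the returned :class:`LoadReport`. Allelic depths come from the
    sample AD field when present; annotation from INFO keys GENE/FUNC/CTX.
    """
    report = LoadReport()
    primary = _read_vcf_one(primary_path, case_id, Lesion.PRIMARY, strip_chr_prefix, report)
    ctc = _read_vcf_one(ctc_path, case_id, Lesion.CTC, strip_chr_prefix, report)
    report.n_loaded = len(primary) + len(ctc)
    return PairedCallset(case_id=case_id, primary=primary, ctc=ctc), report


def write_vcf(records: Sequence[MutationRecord], path: str | os.PathLike) -> None:
    """Write one lesion's records as a minimal single-sample VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide context">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            info = []
            if r.gene:
                info.append(f"GENE={r.gene}")
            info.append(f"FUNC={r.func_class.value}")
            if r.context:
                info.append(f"CTX={r.context}")
            if r.alt_depth is not None and r.ref_depth is not None:
                fmt, sample = "AD", f"{r.ref_depth},{r.alt_depth}"
            else:
                fmt, sample = "GT", "./."
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\t{fmt}\t{sample}\n"
            )


# ---------------------------------------------------------------------------
# Cohort metadata (clinical table transcription)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortCase:
    """One row of the clinical/immunophenotype cohort table."""

    case_id: str
    t_stage: str
    lvi: bool
    vein_invasion: bool
    vim_pos_ck_neg: int
    vim_neg_ck_pos: int
    vim_pos_ck_pos: int
    total_ctc: int

    @property
    def phenotype_sum(self) -> int:
        return self.vim_pos_ck_neg + self.vim_neg_ck_pos + self.vim_pos_ck_pos

    @property
    def stage_group(self) -> str:
        """Major T stage: sub-stage letters after a digit are dropped (T3a -> T3)."""
        stage = self.t_stage
        if len(stage) >= 2 and stage[1].isdigit():
            return stage[:2]
        return stage


CohortMetadata = list[CohortCase]

_BOOL = {"pos": True, "neg": False, "yes": True, "no": False, "1": True, "0": False}


def read_cohort_metadata(path: str | os.PathLike) -> CohortMetadata:
    cases: list[CohortCase] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line_no, row in enumerate(reader, start=2):
            try:
                cases.append(
                    CohortCase(
                        case_id=row["case_id"].strip(),
                        t_stage=row["t_stage"].strip(),
                        lvi=_BOOL[row["lvi"].strip().lower()],
                        vein_invasion=_BOOL[row["vein_invasion"].strip().lower()],
                        vim_pos_ck_neg=int(row["vim_pos_ck_neg"]),
                        vim_neg_ck_pos=int(row["vim_neg_ck_pos"]),
                        vim_pos_ck_pos=int(row["vim_pos_ck_pos"]),
                        total_ctc=int(row["total_ctc"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"line {line_no}: bad cohort metadata row: {exc}") from None
    return cases


def summarize_cohort_metadata(metadata: CohortMetadata) -> dict:
    """Stage-group counts, totals, and a per-case phenotype-consistency report.

    Inconsistent rows (phenotype counts not summing to the printed total)
    are reported, never fatal.
    """
    stage_counts = Counter(c.stage_group for c in metadata)
    consistency = {c.case_id: c.phenotype_sum == c.total_ctc for c in metadata}
    return {
        "n_cases": len(metadata),
        "stage_counts": dict(sorted(stage_counts.items())),
        "total_ctc_sum": sum(c.total_ctc for c in metadata),
        "phenotype_consistent": consistency,
        "inconsistent_cases": sorted(k for k, ok in consistency.items() if not ok),
    }


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks and '#' lines skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
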