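"""Allele-frequency clonality comparisons and cancer-gene recurrence tables."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .concordance import RegionalClassification
from .variant_io import FuncClass, Lesion, MutationRecord, PairedCallset, ValidationError

__all__ = [
    "VafGroup",
    "VafComparison",
    "VafSummary",
    "GeneRecurrenceRow",
    "vaf",
    "compare_vaf_by_category",
    "recurrent_gene_table",
]


def vaf(record: MutationRecord) -> float:
    """Variant allele frequency: alt / (alt + ref) read depth."""
    if record.alt_depth is None or record.ref_depth is None:
        raise ValidationError(f"depths absent at {record.chrom}:{record.pos}")
    total = record.alt_depth + record.ref_depth
    if total == 0:
        raise ValidationError(f"zero total depth at {record.chrom}:{record.pos}")
    return record.alt_depth / total


@dataclass
class VafGroup:
    """Per-category per-lesion VAF sample with summary statistics."""

    label: str
    values: np.ndarray
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.n else math.nan

    @property
    def iqr(self) -> tuple[float, float]:
        if not self.n:
            return (math.nan, math.nan)
        return tuple(np.percentile(self.values, [25, 75]))


@dataclass
class VafComparison:
    """Two-sided Mann-Whitney comparison of specific vs common VAFs."""

    lesion: str
    specific: VafGroup
    common: VafGroup
    u_statistic: Optional[float] = None
    p_value: Optional[float] = None
    skipped_reason: Optional[str] = None


@dataclass
class VafSummary:
    case_ids: tuple[str, ...]
    comparisons: list[VafComparison]


def _collect_vafs(records: Iterable[MutationRecord], label: str) -> VafGroup:
    values, skipped = [], 0
    for r in records:
        try:
            values.append(vaf(r))
        except ValidationError:
            skipped += 1
    return VafGroup(label=label, values=np.array(values, dtype=float), n_skipped=skipped)


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # normal approximation with tie correction, no continuity correction so
    # identical samples give p = 1 exactly
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def compare_vaf_by_category(
    classification: RegionalClassification, pair: PairedCallset
) -> VafSummary:
    """Compare region-specific vs common VAFs within each lesion.

    A common mutation contributes its primary-lesion VAF to the primary
    comparison and its CTC-lesion VAF to the CTC comparison. Records without
    usable depths are skipped and counted; an empty group skips the
    comparison with a reason rather than failing.
    """
    comparisons: list[VafComparison] = []
    for lesion, specific_keys in (
        (Lesion.PRIMARY, classification.primary_specific),
        (Lesion.CTC, classification.ctc_specific),
    ):
        by_key = pair.by_key(lesion)
        specific = _collect_vafs(
            (by_key[k] for k in specific_keys if k in by_key),
            f"{lesion.value}_specific",
        )
        common = _collect_vafs(
            (by_key[k] for k in classification.common if k in by_key),
            f"common_in_{lesion.value}",
        )
        comp = VafComparison(lesion=lesion.value, specific=specific, common=common)
        if specific.n == 0 or common.n == 0:
            comp.skipped_reason = (
                f"empty group ({specific.label}: n={specific.n}, {common.label}: n={common.n})"
            )
        else:
            comp.u_statistic, comp.p_value = _mannwhitney(specific.values, common.values)
        comparisons.append(comp)
    return VafSummary(case_ids=(classification.case_id,), comparisons=comparisons)


@dataclass(frozen=True)
class GeneRecurrenceRow:
    """Cases carrying >= 1 mutation of a listed gene within one category."""

    gene: str
    category: str  # common | primary_specific | ctc_specific | any
    n_cases: int
    n_missense: int
    n_nonsense: int
    n_other: int


def recurrent_gene_table(
    classifications: Sequence[RegionalClassification],
    records: Iterable[MutationRecord],
    gene_list: Sequence[str],
    min_cases: int = 3,
) -> list[GeneRecurrenceRow]:
    """Tabulate listed genes mutated in at least ``min_cases`` distinct cases.

    Counting is per case (duplicated mutations within a case never inflate
    n_cases) and per category; an across-category ``any`` row is emitted as
    well. Consequence counts are per distinct mutation (a common mutation's
    two lesion records count once). Genes not on the list are ignored.
    """
    genes = set(gene_list)
    by_case = {c.case_id: c for c in classifications}
    # (gene, category) -> case -> set of keys (for consequence dedup)
    seen: dict[tuple[str, str], dict[str, dict]] = {}
    for r in records:
        if r.gene not in genes or r.case_id not in by_case:
            continue
        try:
            category = by_case[r.case_id].category_of(r.key)
        except KeyError:
            continue
        for cat in (category, "any"):
            per_case = seen.setdefault((r.gene, cat), {})
            per_case.setdefault(r.case_id, {})[r.key] = r.func_class

    rows: list[GeneRecurrenceRow] = []
    for (gene, category), per_case in seen.items():
        if len(per_case) < min_cases:
            continue
        funcs = [f for case_muts in per_case.values() for f in case_muts.values()]
        rows.append(
            GeneRecurrenceRow(
                gene=gene,
                category=category,
                n_cases=len(per_case),
                n_missense=sum(f is FuncClass.MISSENSE for f in funcs),
                n_nonsense=sum(f is FuncClass.NONSENSE for f in funcs),
                n_other=sum(f not in (FuncClass.MISSENSE, FuncClass.NONSENSE) for f in funcs),
            )
        )
    category_order = {"common": 0, "primary_specific": 1, "ctc_specific": 2, "any": 3}
    rows.sort(key=lambda r: (category_order[r.category], -r.n_cases, r.gene))
    return rows
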