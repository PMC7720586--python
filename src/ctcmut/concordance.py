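"""Regional classification of paired callsets and concordance statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .variant_io import Lesion, MutationKey, PairedCallset, ValidationError

__all__ = [
    "RegionalClassification",
    "CaseSummary",
    "CohortSummary",
    "classify_regional",
    "concordance_fraction",
    "abundance_correlation",
    "summarize_cohort",
]


@dataclass
class RegionalClassification:
    """Disjoint partition of one case's mutations by lesion membership."""

    case_id: str
    common: frozenset[MutationKey]
    primary_specific: frozenset[MutationKey]
    ctc_specific: frozenset[MutationKey]

    @property
    def union(self) -> frozenset[MutationKey]:
        return self.common | self.primary_specific | self.ctc_specific

    def category_of(self, key: MutationKey) -> str:
        if key in self.common:
            return "common"
        if key in self.primary_specific:
            return "primary_specific"
        if key in self.ctc_specific:
            return "ctc_specific"
        raise KeyError(f"key not classified: {key}")


def classify_regional(pair: PairedCallset) -> RegionalClassification:
    """Exact set algebra on mutation keys.

    Common mutations are present in both lesions' callsets; specific
    mutations in exactly one. Per-key annotation stays retrievable from the
    lesions' records (common mutations keep both lesions' depth fields).
    """
    primary_keys = pair.keys(Lesion.PRIMARY)
    ctc_keys = pair.keys(Lesion.CTC)
    return RegionalClassification(
        case_id=pair.case_id,
        common=frozenset(primary_keys & ctc_keys),
        primary_specific=frozenset(primary_keys - ctc_keys),
        ctc_specific=frozenset(ctc_keys - primary_keys),
    )


Denominator = Literal["union", "primary", "ctc"]


def concordance_fraction(
    classification: RegionalClassification,
    denominator: Denominator = "union",
) -> float:
    """|common| / |denominator set|, in [0, 1].

    The default denominator is the union of both lesions' mutations; the
    per-lesion alternatives are also supported and reported side by side by
    the pipeline.
    """
    n_common = len(classification.common)
    if denominator == "union":
        denom = len(classification.union)
    elif denominator == "primary":
        denom = n_common + len(classification.primary_specific)
    elif denominator == "ctc":
        denom = n_common + len(classification.ctc_specific)
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValidationError(
            f"case {classification.case_id}: empty {denominator} set, concordance undefined"
        )
    return n_common / denom


def abundance_correlation(
    pairs: Sequence[PairedCallset], method: str = "pearson"
) -> tuple[float, float]:
    """Correlate per-case primary vs CTC mutation totals across the cohort.

    Totals count all exonic mutations (SNVs and indels) per lesion. Returns
    Pearson's r with the two-sided p-value from the t transform on n-2
    degrees of freedom (Spearman available as an option).
    """
    if len(pairs) < 3:
        raise ValidationError(f"need >= 3 cases for a correlation, got {len(pairs)}")
    x = np.array([len(p.primary) for p in pairs], dtype=float)
    y = np.array([len(p.ctc) for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in per-lesion totals; correlation undefined")
    if method == "pearson":
        result = stats.pearsonr(x, y)
    elif method == "spearman":
        result = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(result.statistic), float(result.pvalue)


@dataclass
class CaseSummary:
    case_id: str
    n_primary: int
    n_ctc: int
    n_common: int
    concordance_union: float
    concordance_primary: float
    concordance_ctc: float


@dataclass
class CohortSummary:
    cases: list[CaseSummary]
    pearson_r: float
    pearson_p: float


def summarize_cohort(pairs: Sequence[PairedCallset]) -> CohortSummary:
    """Per-case abundance/concordance rows plus the cohort abundance correlation."""
    rows = []
    for pair in pairs:
        rc = classify_regional(pair)
        rows.append(
            CaseSummary(
                case_id=pair.case_id,
                n_primary=len(pair.primary),
                n_ctc=len(pair.ctc),
                n_common=len(rc.common),
                concordance_union=concordance_fraction(rc, "union"),
                concordance_primary=concordance_fraction(rc, "primary"),
                concordance_ctc=concordance_fraction(rc, "ctc"),
            )
        )
    r, p = abundance_correlation(pairs)
    return CohortSummary(cases=rows, pearson_r=r, pearson_p=p)
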