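"""Trunk-branch synthetic cohort generator.

Each simulated case carries one set of trunk mutations (present in both
lesions) and two sets of lesion-private branch mutations. Trinucleotide
contexts are drawn from per-category signature mixtures, true cell
fractions from per-category Beta distributions, and observation passes
through a Poisson-depth / binomial-reads / alt-read-threshold detection
model with an optional extra Bernoulli sensitivity term.

The closed-form twin :func:`expected_concordance` predicts the mean
observed concordance fraction and serves as an independent oracle for the
sampler.
"""

from __future__ import annotations

import dataclasses
import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, stats

from .spectra_signatures import SignatureCatalog, toy_catalog
from .variant_io import (
    CohortCase,
    CohortMetadata,
    FuncClass,
    Lesion,
    MutationRecord,
    PairedCallset,
    ValidationError,
    reverse_complement,
)

__all__ = [
    "CATEGORIES",
    "SimulationConfig",
    "TruthRow",
    "simulate_case",
    "simulate_cohort",
    "expected_concordance",
    "detection_probability",
    "write_truth_table",
    "read_truth_table",
]

#: Regional categories, in the order used throughout the pipeline.
CATEGORIES = ("common", "primary_specific", "ctc_specific")

_TRUTH_CATEGORY = {
    "common": "trunk",
    "primary_specific": "primary_branch",
    "ctc_specific": "ctc_branch",
}

_DEFAULT_MIX = {
    "common": {"flat": 0.5, "apobec_like": 0.25, "cpg_deamination": 0.25},
    "primary_specific": {"apobec_like": 0.6, "flat": 0.4},
    "ctc_specific": {"ct_rich": 0.6, "flat": 0.4},
}

_DEFAULT_VAF_BETA = {
    "common": (2.0, 6.0),
    "primary_specific": (6.0, 3.0),
    "ctc_specific": (6.0, 3.0),
}

_DEFAULT_FUNC_PROBS = {
    "missense": 0.55,
    "silent": 0.20,
    "nonsense": 0.05,
    "splice": 0.03,
    "indel": 0.12,
    "other": 0.05,
}

_CONTIG = "simC"
_CONTIG_LENGTH = 200_000_000


@dataclass
class SimulationConfig:
    """Generative parameters for a trunk-branch cohort."""

    n_cases: int = 20
    trunk_bounds: tuple[int, int] = (10, 150)
    branch_bounds_primary: tuple[int, int] = (20, 1400)
    branch_bounds_ctc: tuple[int, int] = (20, 1400)
    signature_mix_by_category: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MIX.items()})
    vaf_beta_by_category: dict = field(default_factory=lambda: dict(_DEFAULT_VAF_BETA))
    depth_mean: float = 100.0
    min_alt_reads: int = 3
    detect_prob: float = 1.0
    func_class_probs: dict = field(default_factory=lambda: dict(_DEFAULT_FUNC_PROBS))
    gene_pool_size: int = 500
    seed: int = 0

    def validate(self, catalog: Optional[SignatureCatalog] = None) -> None:
        if self.n_cases < 1:
            raise ValidationError(f"n_cases must be >= 1, got {self.n_cases}")
        for name, (lo, hi) in (
            ("trunk_bounds", self.trunk_bounds),
            ("branch_bounds_primary", self.branch_bounds_primary),
            ("branch_bounds_ctc", self.branch_bounds_ctc),
        ):
            if lo <= 0 or hi < lo:
                raise ValidationError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if self.depth_mean <= 0:
            raise ValidationError(f"depth_mean must be positive, got {self.depth_mean}")
        if self.min_alt_reads < 0:
            raise ValidationError(f"min_alt_reads must be >= 0, got {self.min_alt_reads}")
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValidationError(f"detect_prob must be in [0, 1], got {self.detect_prob}")
        for cat in CATEGORIES:
            mix = self.signature_mix_by_category.get(cat)
            if not mix:
                raise ValidationError(f"signature mix missing category {cat!r}")
            if any(w < 0 for w in mix.values()):
                raise ValidationError(f"negative signature weight in category {cat!r}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValidationError(f"signature mix for {cat!r} must sum to 1")
            if catalog is not None:
                unknown = set(mix) - set(catalog.names)
                if unknown:
                    raise ValidationError(f"mix for {cat!r} names unknown signature(s) {sorted(unknown)}")
            a, b = self.vaf_beta_by_category.get(cat, (0, 0))
            if a <= 0 or b <= 0:
                raise ValidationError(f"Beta parameters for {cat!r} must be positive, got ({a}, {b})")
        probs = self.func_class_probs
        valid = {f.value for f in FuncClass}
        if set(probs) - valid:
            raise ValidationError(f"unknown func_class in probs: {sorted(set(probs) - valid)}")
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValidationError("func_class_probs must be non-negative and sum to 1")
        if self.gene_pool_size < 1:
            raise ValidationError("gene_pool_size must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for name in ("trunk_bounds", "branch_bounds_primary", "branch_bounds_ctc"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        if "vaf_beta_by_category" in kwargs:
            kwargs["vaf_beta_by_category"] = {
                k: tuple(v) for k, v in kwargs["vaf_beta_by_category"].items()
            }
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one simulated mutation."""

    case_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    category: str  # trunk | primary_branch | ctc_branch
    true_vaf: float
    detected_primary: bool
    detected_ctc: bool


def _case_rng(config: SimulationConfig, case_id: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, zlib.crc32(case_id.encode())])


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    value = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    return min(max(value, lo), hi)


def _sample_positions(rng: np.random.Generator, n: int, used: set[int]) -> list[int]:
    out: list[int] = []
    while len(out) < n:
        pos = int(rng.integers(1, _CONTIG_LENGTH + 1))
        if pos not in used:
            used.add(pos)
            out.append(pos)
    return out


def _sample_alleles(rng, config: SimulationConfig, catalog: SignatureCatalog, category: str):
    """Draw (ref, alt, context, func_class) for one mutation of a category."""
    probs = config.func_class_probs
    if rng.random() < probs.get("indel", 0.0):
        base = "ACGT"[rng.integers(4)]
        extra = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
        if rng.random() < 0.5:
            ref, alt = base, base + extra
        else:
            ref, alt = base + extra, base
        return ref, alt, None, FuncClass.INDEL
    mix = config.signature_mix_by_category[category]
    sig_names = sorted(mix)
    weights = np.array([mix[s] for s in sig_names])
    sig = sig_names[rng.choice(len(sig_names), p=weights / weights.sum())]
    cell = int(rng.choice(96, p=catalog.row(sig)))
    cls_idx, rest = divmod(cell, 16)
    five, three = "ACGT"[rest // 4], "ACGT"[rest % 4]
    cls = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")[cls_idx]
    ref, alt = cls[0], cls[2]
    context = five + ref + three
    if rng.random() < 0.5:  # emit on the purine strand half the time
        ref, alt = reverse_complement(ref), reverse_complement(alt)
        context = reverse_complement(context)
    snv_classes = [f for f in ("missense", "silent", "nonsense", "splice", "other") if probs.get(f, 0) > 0]
    p = np.array([probs[f] for f in snv_classes])
    func = FuncClass(snv_classes[rng.choice(len(snv_classes), p=p / p.sum())])
    return ref, alt, context, func


def _observe(rng, config: SimulationConfig, vaf: float) -> tuple[bool, int, int]:
    """One lesion's detection trial: (detected, alt_reads, total_depth)."""
    depth = int(rng.poisson(config.depth_mean))
    alt = int(rng.binomial(depth, vaf)) if depth > 0 else 0
    detected = alt >= config.min_alt_reads
    if detected and config.detect_prob < 1.0:
        detected = rng.random() < config.detect_prob
    return detected, alt, depth


def simulate_case(
    config: SimulationConfig,
    case_id: str,
    catalog: Optional[SignatureCatalog] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PairedCallset, list[TruthRow]]:
    """Simulate one case's paired callset and its per-mutation ground truth.

    The RNG is derived deterministically from ``(config.seed, case_id)``
    unless one is supplied; identical config and case id give byte-identical
    output.
    """
    catalog = catalog if catalog is not None else toy_catalog()
    config.validate(catalog)
    rng = rng if rng is not None else _case_rng(config, case_id)

    counts = {
        "common": _log_uniform_int(rng, *config.trunk_bounds),
        "primary_specific": _log_uniform_int(rng, *config.branch_bounds_primary),
        "ctc_specific": _log_uniform_int(rng, *config.branch_bounds_ctc),
    }
    used_positions: set[int] = set()
    primary: list[MutationRecord] = []
    ctc: list[MutationRecord] = []
    truth: list[TruthRow] = []

    for category in CATEGORIES:
        n = counts[category]
        positions = _sample_positions(rng, n, used_positions)
        a, b = config.vaf_beta_by_category[category]
        for pos in positions:
            ref, alt, context, func = _sample_alleles(rng, config, catalog, category)
            vaf = float(rng.beta(a, b))
            gene = f"G{int(rng.integers(config.gene_pool_size)):04d}"
            lesions = (
                (Lesion.PRIMARY, Lesion.CTC)
                if category == "common"
                else (Lesion.PRIMARY,)
                if category == "primary_specific"
                else (Lesion.CTC,)
            )
            detected = {Lesion.PRIMARY: False, Lesion.CTC: False}
            for lesion in lesions:
                hit, alt_reads, depth = _observe(rng, config, vaf)
                detected[lesion] = hit
                if hit:
                    rec = MutationRecord(
                        case_id=case_id,
                        lesion=lesion,
                        chrom=_CONTIG,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        gene=gene,
                        func_class=func,
                        context=context,
                        alt_depth=alt_reads,
                        ref_depth=depth - alt_reads,
                    )
                    (primary if lesion is Lesion.PRIMARY else ctc).append(rec)
            truth.append(
                TruthRow(
                    case_id=case_id,
                    chrom=_CONTIG,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    category=_TRUTH_CATEGORY[category],
                    true_vaf=vaf,
                    detected_primary=detected[Lesion.PRIMARY],
                    detected_ctc=detected[Lesion.CTC],
                )
            )
    return PairedCallset(case_id=case_id, primary=primary, ctc=ctc), truth


_STAGE_CYCLE = ("Ta", "T1", "T2a", "T3a", "T4a")


def simulate_cohort(
    config: SimulationConfig,
    catalog: Optional[SignatureCatalog] = None,
) -> tuple[list[PairedCallset], list[TruthRow], CohortMetadata]:
    """Simulate ``config.n_cases`` independent cases plus a metadata stub."""
    catalog = catalog if catalog is not None else toy_catalog()
    config.validate(catalog)
    pairs: list[PairedCallset] = []
    truth: list[TruthRow] = []
    metadata: CohortMetadata = []
    width = max(2, len(str(config.n_cases)))
    for i in range(config.n_cases):
        case_id = f"SIM{i + 1:0{width}d}"
        pair, case_truth = simulate_case(config, case_id, catalog=catalog)
        pairs.append(pair)
        truth.extend(case_truth)
        meta_rng = np.random.default_rng([config.seed, zlib.crc32(case_id.encode()), 7])
        counts = [int(meta_rng.integers(0, 20)) for _ in range(3)]
        metadata.append(
            CohortCase(
                case_id=case_id,
                t_stage=_STAGE_CYCLE[i % len(_STAGE_CYCLE)],
                lvi=bool(meta_rng.integers(2)),
                vein_invasion=bool(meta_rng.integers(2)),
                vim_pos_ck_neg=counts[0],
                vim_neg_ck_pos=counts[1],
                vim_pos_ck_pos=counts[2],
                total_ctc=sum(counts),
            )
        )
    return pairs, truth, metadata


def expected_concordance(trunk: float, branch_p: float, branch_c: float, dp: float, dc: float) -> float:
    """Closed-form expected concordance fraction (union denominator).

    ``dp``/``dc`` are the overall per-mutation detection probabilities in
    the primary and CTC lesions. A trunk mutation is common when detected in
    both lesions and lesion-specific when detected in exactly one; branch
    mutations enter the union only via their own lesion.
    """
    if min(trunk, branch_p, branch_c) < 0 or max(trunk, branch_p, branch_c) <= 0:
        raise ValidationError("counts must be non-negative and not all zero")
    if not (0 <= dp <= 1 and 0 <= dc <= 1):
        raise ValidationError("detection probabilities must be in [0, 1]")
    union = trunk * (1.0 - (1.0 - dp) * (1.0 - dc)) + branch_p * dp + branch_c * dc
    if union == 0:
        raise ValidationError("expected union is zero; concordance undefined")
    return trunk * dp * dc / union


def detection_probability(
    vaf_alpha: float,
    vaf_beta: float,
    depth_mean: float,
    min_alt_reads: int,
    detect_prob: float = 1.0,
) -> float:
    """Overall per-mutation detection probability under the observation model.

    With depth ~ Poisson(lambda) and alt reads ~ Binomial(depth, v), the alt
    count is Poisson(lambda*v) by thinning, so the threshold probability is
    integrated over the Beta VAF density numerically.
    """
    if min_alt_reads <= 0:
        return detect_prob

    def integrand(v):
        return stats.beta.pdf(v, vaf_alpha, vaf_beta) * stats.poisson.sf(
            min_alt_reads - 1, depth_mean * v
        )

    value, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return detect_prob * float(value)


_TRUTH_COLUMNS = (
    "case_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "category",
    "true_vaf",
    "detected_primary",
    "detected_ctc",
)


def write_truth_table(truth: list[TruthRow], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                f"{t.case_id}\t{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{t.category}\t"
                f"{t.true_vaf:.10g}\t{int(t.detected_primary)}\t{int(t.detected_ctc)}\n"
            )


def read_truth_table(path: str | os.PathLike) -> list[TruthRow]:
    import csv

    rows: list[TruthRow] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                TruthRow(
                    case_id=row["case_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    category=row["category"],
                    true_vaf=float(row["true_vaf"]),
                    detected_primary=row["detected_primary"] == "1",
                    detected_ctc=row["detected_ctc"] == "1",
                )
            )
    return rows
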