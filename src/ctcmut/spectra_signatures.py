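"""Consequence tables, substitution spectra, signature refitting, clustering.

Spectra are pyrimidine-strand-collapsed counts over 6 substitution classes
or 96 trinucleotide contexts. Exposures are obtained by non-negative least
squares against a fixed signature catalog; profiles are compared by
average-linkage hierarchical clustering on Euclidean distance.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .variant_io import (
    CONTEXT_LABELS_96,
    SUBSTITUTION_CLASSES,
    FuncClass,
    MutationRecord,
    ValidationError,
    collapse_strand,
    context_index,
    context_label,
)

__all__ = [
    "SpectrumVector",
    "SignatureCatalog",
    "ExposureVector",
    "ClusterResult",
    "consequence_table",
    "spectrum",
    "refit_exposures",
    "cluster_exposures",
    "load_signature_catalog",
    "toy_catalog",
    "LOW_CONFIDENCE_MIN_SNVS",
]

#: Exposures fitted on spectra with fewer SNVs than this are flagged.
LOW_CONFIDENCE_MIN_SNVS = 50


# ---------------------------------------------------------------------------
# Functional consequences
# ---------------------------------------------------------------------------


def consequence_table(
    records_by_category: Mapping[str, Iterable[MutationRecord]],
    include_nonsense: bool = False,
) -> dict[str, dict]:
    """Per-category functional-class proportions and the NS/S ratio.

    The NS/S numerator is the missense count (optionally missense+nonsense);
    the denominator is the silent count. A zero silent count yields a NaN
    sentinel, not an exception.
    """
    out: dict[str, dict] = {}
    for category, records in records_by_category.items():
        records = list(records)
        counts = {f: 0 for f in FuncClass}
        for r in records:
            counts[r.func_class] += 1
        n = len(records)
        numerator = counts[FuncClass.MISSENSE]
        if include_nonsense:
            numerator += counts[FuncClass.NONSENSE]
        silent = counts[FuncClass.SILENT]
        ratio = numerator / silent if silent > 0 else math.nan
        out[category] = {
            "n": n,
            "counts": {f.value: c for f, c in counts.items()},
            "proportions": {f.value: (c / n if n else 0.0) for f, c in counts.items()},
            "ns_s_ratio": ratio,
        }
    return out


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass
class SpectrumVector:
    """Strand-collapsed substitution counts over 6 or 96 classes."""

    counts: np.ndarray
    labels: tuple[str, ...]
    n_skipped: int = 0
    empty: bool = False

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise ValidationError("cannot normalize an all-zero spectrum")
        return self.counts / total


def spectrum(records: Iterable[MutationRecord], n_classes: int = 6) -> SpectrumVector:
    """Tally SNVs into a 6- or 96-class spectrum.

    Indels are always skipped; for the 96-class spectrum, SNVs lacking a
    trinucleotide context are skipped too. Skips are counted, and an empty
    usable input yields a flagged zero vector.
    """
    if n_classes not in (6, 96):
        raise ValidationError(f"n_classes must be 6 or 96, got {n_classes}")
    labels = SUBSTITUTION_CLASSES if n_classes == 6 else CONTEXT_LABELS_96
    counts = np.zeros(n_classes, dtype=float)
    n_skipped = 0
    n_used = 0
    for r in records:
        if not r.is_snv:
            n_skipped += 1
            continue
        if n_classes == 96:
            if r.context is None:
                n_skipped += 1
                continue
            cls, ctx = collapse_strand(r.ref, r.alt, r.context)
            counts[context_index(context_label(cls, ctx))] += 1
        else:
            cls, _ = collapse_strand(r.ref, r.alt, r.context)
            counts[SUBSTITUTION_CLASSES.index(cls)] += 1
        n_used += 1
    return SpectrumVector(counts=counts, labels=tuple(labels), n_skipped=n_skipped, empty=n_used == 0)


# ---------------------------------------------------------------------------
# Signature catalog and exposure refitting
# ---------------------------------------------------------------------------


@dataclass
class SignatureCatalog:
    """Named signatures as rows of probabilities over the 96 contexts."""

    names: tuple[str, ...]
    matrix: np.ndarray  # shape (n_signatures, 96), rows sum to 1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(self.names) < 1:
            raise ValidationError("catalog must contain at least one signature")
        if self.matrix.shape != (len(self.names), 96):
            raise ValidationError(
                f"catalog matrix shape {self.matrix.shape} != ({len(self.names)}, 96)"
            )
        if np.any(self.matrix < 0):
            raise ValidationError("catalog probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        bad = [self.names[i] for i in np.nonzero(np.abs(sums - 1.0) > 1e-6)[0]]
        if bad:
            raise ValidationError(f"signature row(s) do not sum to 1: {bad}")

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]


def load_signature_catalog(path: str | os.PathLike) -> SignatureCatalog:
    """Read a catalog TSV: first column context labels, one column per signature.

    Rows may come in any order; they must cover all 96 contexts exactly once.
    """
    import csv

    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        names = tuple(header[1:])
        values: dict[str, list[float]] = {}
        for row in reader:
            if not row:
                continue
            values[row[0]] = [float(x) for x in row[1:]]
    missing = [lab for lab in CONTEXT_LABELS_96 if lab not in values]
    if missing or len(values) != 96:
        raise ValidationError(
            f"catalog must cover all 96 contexts exactly once "
            f"({len(values)} rows, {len(missing)} missing)"
        )
    matrix = np.array([[values[lab][j] for lab in CONTEXT_LABELS_96] for j in range(len(names))])
    return SignatureCatalog(names=names, matrix=matrix)


def toy_catalog() -> SignatureCatalog:
    """The packaged 5-signature toy catalog (flat, APOBEC-like, CpG, C>T, C>G)."""
    with resources.as_file(resources.files("ctcmut.data") / "toy_signatures.tsv") as p:
        return load_signature_catalog(p)


@dataclass
class ExposureVector:
    """Non-negative per-signature weights fitted to one 96-class spectrum."""

    names: tuple[str, ...]
    weights: np.ndarray  # mutation-count units
    residual: float  # euclidean norm of reconstruction error
    cosine: float  # cosine similarity of spectrum vs reconstruction
    low_confidence: bool = False

    def proportions(self) -> np.ndarray:
        total = self.weights.sum()
        if total == 0:
            return np.zeros_like(self.weights)
        return self.weights / total

    def weight(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])


def refit_exposures(spectrum96: SpectrumVector | np.ndarray, catalog: SignatureCatalog) -> ExposureVector:
    """Fit non-negative signature exposures to a 96-class count spectrum.

    Solves ``min ||S^T e - v||_2, e >= 0`` where S is the catalog matrix and
    v the count vector. Exposures are in mutation-count units.
    """
    if isinstance(spectrum96, SpectrumVector):
        if len(spectrum96.counts) != 96:
            raise ValidationError("refit_exposures requires a 96-class spectrum")
        v = np.asarray(spectrum96.counts, dtype=float)
    else:
        v = np.asarray(spectrum96, dtype=float)
        if v.shape != (96,):
            raise ValidationError(f"expected a length-96 vector, got shape {v.shape}")
    if v.sum() <= 0:
        raise ValidationError("cannot refit exposures on an empty spectrum")
    weights, residual = nnls(catalog.matrix.T, v)
    recon = catalog.matrix.T @ weights
    denom = np.linalg.norm(v) * np.linalg.norm(recon)
    cosine = float(v @ recon / denom) if denom > 0 else 0.0
    return ExposureVector(
        names=catalog.names,
        weights=weights,
        residual=float(residual),
        cosine=cosine,
        low_confidence=bool(v.sum() < LOW_CONFIDENCE_MIN_SNVS),
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering of exposure profiles
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: tuple[str, ...]  # input order after deterministic label sort
    linkage_matrix: np.ndarray  # scipy linkage format
    leaf_order: tuple[str, ...]
    newick: str


def _to_newick(node, labels: Sequence[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    parts = []
    for child in (node.get_left(), node.get_right()):
        length = node.dist - child.dist
        parts.append(f"{_to_newick(child, labels)}:{length:.10g}")
    return f"({','.join(parts)})"


def cluster_exposures(
    exposures: Mapping[str, ExposureVector] | Mapping[str, np.ndarray],
) -> ClusterResult:
    """Average-linkage / Euclidean clustering of proportion-normalized exposures.

    Profiles are sorted by label before clustering so that leaf order is
    deterministic with ties broken by label.
    """
    if len(exposures) < 2:
        raise ValidationError("clustering requires at least 2 profiles")
    labels = tuple(sorted(exposures))
    rows = []
    for lab in labels:
        e = exposures[lab]
        vec = e.proportions() if isinstance(e, ExposureVector) else np.asarray(e, dtype=float)
        rows.append(vec)
    matrix = np.vstack(rows)
    z = linkage(pdist(matrix, metric="euclidean"), method="average")
    order = tuple(labels[i] for i in leaves_list(z))
    newick = _to_newick(to_tree(z), labels) + ";"
    return ClusterResult(labels=labels, linkage_matrix=z, leaf_order=order, newick=newick)
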