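import itertools
import math

import numpy as np
import pytest

from ctcmut.spectra_signatures import (
    SignatureCatalog,
    SpectrumVector,
    cluster_exposures,
    consequence_table,
    load_signature_catalog,
    refit_exposures,
    spectrum,
)
from ctcmut.variant_io import (
    CONTEXT_LABELS_96,
    FuncClass,
    Lesion,
    MutationRecord,
    ValidationError,
    collapse_strand,
    context_index,
    context_label,
)

from conftest import make_snv


# ---------------------------------------------------------------------------
# consequence_table
# ---------------------------------------------------------------------------


class TestConsequenceTable:
    def test_direct_ratio(self):
        records = [make_snv(pos=i, func_class=FuncClass.MISSENSE) for i in range(1, 7)]
        records += [make_snv(pos=i, func_class=FuncClass.SILENT) for i in range(10, 12)]
        table = consequence_table({"common": records})
        assert table["common"]["ns_s_ratio"] == pytest.approx(3.0)
        assert table["common"]["n"] == 8
        assert table["common"]["proportions"]["missense"] == pytest.approx(6 / 8)

    def test_zero_silent_sentinel(self):
        table = consequence_table({"x": [make_snv(func_class=FuncClass.MISSENSE)]})
        assert math.isnan(table["x"]["ns_s_ratio"])

    def test_include_nonsense_option(self):
        records = [
            make_snv(pos=1, func_class=FuncClass.MISSENSE),
            make_snv(pos=2, func_class=FuncClass.NONSENSE),
            make_snv(pos=3, func_class=FuncClass.SILENT),
        ]
        assert consequence_table({"x": records})["x"]["ns_s_ratio"] == pytest.approx(1.0)
        assert consequence_table({"x": records}, include_nonsense=True)["x"][
            "ns_s_ratio"
        ] == pytest.approx(2.0)

    def test_simulated_ratio_within_binomial_error(self, catalog):
        from ctcmut.synthetic_cohort import SimulationConfig, simulate_case

        probs = {"missense": 0.5, "silent": 0.2, "nonsense": 0.1, "splice": 0.1,
                 "other": 0.1, "indel": 0.0}
        config = SimulationConfig(
            trunk_bounds=(1000, 1000), branch_bounds_primary=(1, 1),
            branch_bounds_ctc=(1, 1), min_alt_reads=0, func_class_probs=probs, seed=19,
        )
        pair, _ = simulate_case(config, "S1", catalog)
        table = consequence_table({"all": pair.primary})
        ratio = table["all"]["ns_s_ratio"]
        n = table["all"]["n"]
        se = math.sqrt(0.5 * 0.5 / n) / 0.2 + math.sqrt(0.2 * 0.8 / n) * 0.5 / 0.2**2
        assert abs(ratio - 2.5) < 3 * se


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


class TestSpectrum:
    def test_single_class_both_strands(self):
        records = [make_snv(pos=1, ref="C", alt="T", context="ACA"),
                   make_snv(pos=2, ref="G", alt="A", context="AGT")]
        spec = spectrum(records, 6)
        assert spec.counts[spec.labels.index("C>T")] == 2
        assert spec.total == 2

    def test_empty_input_flagged(self):
        spec = spectrum([], 6)
        assert spec.empty and spec.total == 0
        with pytest.raises(ValidationError):
            spec.normalized()

    def test_indels_and_missing_context_skipped(self):
        indel = MutationRecord(case_id="A", lesion=Lesion.PRIMARY, chrom="1", pos=9,
                               ref="C", alt="CA", func_class=FuncClass.INDEL)
        no_ctx = MutationRecord(case_id="A", lesion=Lesion.PRIMARY, chrom="1", pos=10,
                                ref="C", alt="T", func_class=FuncClass.MISSENSE)
        snv = make_snv(pos=11, context="ACA")
        spec96 = spectrum([indel, no_ctx, snv], 96)
        assert spec96.total == 1 and spec96.n_skipped == 2
        spec6 = spectrum([indel, no_ctx, snv], 6)
        assert spec6.total == 2 and spec6.n_skipped == 1

    def test_counts_match_enumeration_oracle(self):
        rng = np.random.default_rng(43)
        records = []
        for i in range(300):
            ref = "ACGT"[rng.integers(4)]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            ctx = "ACGT"[rng.integers(4)] + ref + "ACGT"[rng.integers(4)]
            records.append(make_snv(pos=i + 1, ref=ref, alt=str(alt), context=ctx))
        spec = spectrum(records, 96)
        oracle = {lab: 0 for lab in CONTEXT_LABELS_96}
        for r in records:
            cls, ctx = collapse_strand(r.ref, r.alt, r.context)
            oracle[context_label(cls, ctx)] += 1
        for lab in CONTEXT_LABELS_96:
            assert spec.counts[context_index(lab)] == oracle[lab]

    def test_union_additivity(self):
        rng = np.random.default_rng(47)
        def rand_records(n, offset):
            out = []
            for i in range(n):
                ref = "CT"[rng.integers(2)]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                ctx = "ACGT"[rng.integers(4)] + ref + "ACGT"[rng.integers(4)]
                out.append(make_snv(pos=offset + i, ref=ref, alt=str(alt), context=ctx))
            return out
        a, b = rand_records(40, 1), rand_records(40, 1000)
        np.testing.assert_array_equal(
            spectrum(a + b, 96).counts, spectrum(a, 96).counts + spectrum(b, 96).counts
        )


# ---------------------------------------------------------------------------
# refit_exposures
# ---------------------------------------------------------------------------


class TestRefitExposures:
    def test_noiseless_single_source(self, catalog):
        v = 100.0 * catalog.row("apobec_like")
        exp = refit_exposures(v, catalog)
        assert exp.weight("apobec_like") == pytest.approx(100.0, abs=1e-6)
        others = exp.weights.sum() - exp.weight("apobec_like")
        assert others <= 1e-6 * exp.weights.sum()
        assert exp.cosine == pytest.approx(1.0, abs=1e-9)

    def test_two_signature_mixture_recovery(self, catalog):
        sig_a, sig_b = catalog.row("apobec_like"), catalog.row("cg_rich")
        v = 1000.0 * (0.7 * sig_a + 0.3 * sig_b)
        # closed-form least-squares oracle on the 2 x 96 system
        basis = np.vstack([sig_a, sig_b]).T
        coef_oracle, *_ = np.linalg.lstsq(basis, v, rcond=None)
        exp = refit_exposures(v, catalog)
        recovered = np.array([exp.weight("apobec_like"), exp.weight("cg_rich")])
        np.testing.assert_allclose(recovered, coef_oracle, atol=1e-6)
        props = recovered / recovered.sum()
        np.testing.assert_allclose(props, [0.7, 0.3], atol=1e-6)

    def test_one_signature_grid_search_oracle(self):
        rng = np.random.default_rng(53)
        sig = rng.dirichlet(np.ones(96))
        catalog = SignatureCatalog(names=("only",), matrix=sig[None, :])
        v = rng.uniform(0.5, 5.0, size=96)
        exp = refit_exposures(v, catalog)
        grid = np.linspace(0, 2 * v.sum(), 200_001)
        residuals = np.linalg.norm(v[None, :] - grid[:, None] * sig[None, :], axis=1)
        best = grid[residuals.argmin()]
        assert exp.weights[0] == pytest.approx(best, abs=1e-4 * max(1.0, best))

    def test_residual_never_worse_than_zero_solution(self, catalog):
        rng = np.random.default_rng(59)
        for _ in range(20):
            v = rng.poisson(5.0, size=96).astype(float)
            if v.sum() == 0:
                continue
            exp = refit_exposures(v, catalog)
            assert exp.residual <= np.linalg.norm(v) + 1e-9

    def test_noiseless_mixture_recovery_property(self, catalog):
        rng = np.random.default_rng(61)
        for _ in range(10):
            weights = rng.dirichlet(np.ones(len(catalog.names))) * 500.0
            v = weights @ catalog.matrix
            exp = refit_exposures(v, catalog)
            np.testing.assert_allclose(exp.weights, weights, atol=1e-6)

    def test_empty_spectrum_rejected(self, catalog):
        with pytest.raises(ValidationError):
            refit_exposures(np.zeros(96), catalog)

    def test_low_confidence_flag(self, catalog):
        v = 10.0 * catalog.row("flat")
        assert refit_exposures(v, catalog).low_confidence
        v = 100.0 * catalog.row("flat")
        assert not refit_exposures(v, catalog).low_confidence

    def test_invalid_catalog_rejected(self):
        with pytest.raises(ValidationError):
            SignatureCatalog(names=("bad",), matrix=np.full((1, 96), 0.5))
        with pytest.raises(ValidationError):
            SignatureCatalog(names=(), matrix=np.zeros((0, 96)))


# ---------------------------------------------------------------------------
# cluster_exposures
# ---------------------------------------------------------------------------


def brute_force_average_linkage(matrix, labels):
    """O(n^3) agglomerative average-linkage oracle; returns merge heights."""
    clusters = {i: [i] for i in range(len(labels))}
    heights = []
    dist = lambda a, b: float(np.linalg.norm(matrix[a] - matrix[b]))
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist(a, b) for a in clusters[i] for b in clusters[j]])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters.pop(j)
    return heights


class TestClusterExposures:
    def test_identical_pair_merges_first_at_zero(self):
        profiles = {
            "a": np.array([1.0, 0.0, 0.0]),
            "b": np.array([1.0, 0.0, 0.0]),
            "c": np.array([0.0, 0.0, 1.0]),
        }
        result = cluster_exposures(profiles)
        assert result.linkage_matrix[0, 2] == pytest.approx(0.0)
        first_pair = {int(result.linkage_matrix[0, 0]), int(result.linkage_matrix[0, 1])}
        assert {result.labels[i] for i in first_pair} == {"a", "b"}

    def test_two_profiles_single_merge(self):
        profiles = {"x": np.array([0.0, 1.0]), "y": np.array([1.0, 0.0])}
        result = cluster_exposures(profiles)
        assert result.linkage_matrix.shape == (1, 4)
        assert result.linkage_matrix[0, 2] == pytest.approx(np.sqrt(2))
        assert result.newick.endswith(";")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(67)
        matrix = rng.uniform(size=(4, 5))
        labels = ["p0", "p1", "p2", "p3"]
        result = cluster_exposures({lab: matrix[i] for i, lab in enumerate(labels)})
        oracle_heights = brute_force_average_linkage(matrix, labels)
        np.testing.assert_allclose(result.linkage_matrix[:, 2], oracle_heights, atol=1e-12)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(71)
        profiles = {f"p{i}": rng.uniform(size=6) for i in range(8)}
        heights = cluster_exposures(profiles).linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_single_profile_rejected(self):
        with pytest.raises(ValidationError):
            cluster_exposures({"only": np.array([1.0])})

    def test_leaf_order_deterministic(self):
        rng = np.random.default_rng(73)
        profiles = {f"p{i}": rng.uniform(size=4) for i in range(5)}
        a = cluster_exposures(profiles)
        b = cluster_exposures(dict(reversed(list(profiles.items()))))
        assert a.leaf_order == b.leaf_order
        assert a.newick == b.newick


# ---------------------------------------------------------------------------
# direction property on synthetic cohorts
# ---------------------------------------------------------------------------


def test_apobec_direction_on_synthetic_cohort(catalog):
    from ctcmut.synthetic_cohort import SimulationConfig, simulate_cohort
    from ctcmut.cli import _category_records

    config = SimulationConfig(
        n_cases=8, trunk_bounds=(60, 60), branch_bounds_primary=(150, 150),
        branch_bounds_ctc=(150, 150), min_alt_reads=0, seed=79,
        func_class_probs={"missense": 0.8, "silent": 0.2, "indel": 0.0,
                          "nonsense": 0.0, "splice": 0.0, "other": 0.0},
    )
    pairs, _, _ = simulate_cohort(config, catalog)
    pooled = _category_records(pairs)
    exposures = {
        cat: refit_exposures(spectrum(records, 96), catalog)
        for cat, records in pooled.items()
    }
    apobec = {cat: e.proportions()[list(e.names).index("apobec_like")]
              for cat, e in exposures.items()}
    assert apobec["primary_specific"] > apobec["ctc_specific"]


def test_catalog_fixture_valid(catalog):
    assert len(catalog.names) == 5
    assert np.allclose(catalog.matrix.sum(axis=1), 1.0, atol=1e-6)
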