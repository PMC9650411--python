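"""Sharing test, canonical correlations, SCC, null model, identification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spongemod.bundle import TargetMatrix
from spongemod.network import ModuleAssignment
from spongemod.simulate import ModuleSpec, SimulationSpec, generate_bundle
from spongemod.sponge import (
    NullModel,
    SharingCounts,
    SpongeError,
    canonical_correlation,
    extract_interactions,
    hypergeom_sharing_pvalue,
    identify_sponge_modules,
    lncrna_outdegree,
    partial_cc,
    sensitivity_cc,
    sharing_counts,
)

from oracles import bh_adjust, first_cc_eigen, hypergeom_tail_exact, partial_corr_residual


def targets_from_edges(mirnas, lncrnas, mrnas, edges):
    lnc = pd.DataFrame(0, index=mirnas, columns=lncrnas, dtype=np.int8)
    mr = pd.DataFrame(0, index=mirnas, columns=mrnas, dtype=np.int8)
    for mir, tgt in edges:
        if tgt in lncrnas:
            lnc.loc[mir, tgt] = 1
        else:
            mr.loc[mir, tgt] = 1
    return TargetMatrix(mrna_targets=mr, lncrna_targets=lnc)


class TestSharing:
    def test_no_edges(self):
        t = targets_from_edges(["m1", "m2"], ["A"], ["B"], [])
        c = sharing_counts(["A"], ["B"], t, ["m1", "m2"])
        assert (c.m1, c.k1, c.l1) == (0, 0, 0)
        assert hypergeom_sharing_pvalue(c) == 1.0

    def test_single_shared_mirna(self):
        mirnas = [f"m{i}" for i in range(35)]
        t = targets_from_edges(mirnas, ["A"], ["B"], [("m0", "A"), ("m0", "B")])
        c = sharing_counts(["A"], ["B"], t, mirnas)
        assert (c.n1, c.m1, c.k1, c.l1) == (35, 1, 1, 1)
        assert c.shared_ids == ("m0",)

    def test_planted_module_shares_at_least_planted_count(self, default_study):
        bundle, targets, truth = default_study
        c = sharing_counts(
            truth.members(1, "lncrna"), truth.members(1, "mrna"),
            targets, list(bundle.mirna.index),
        )
        assert c.l1 >= 3

    def test_worked_example_against_enumeration(self):
        # N1=10, M1=4, K1=5, L1=3: (C(4,3)C(6,2) + C(4,4)C(6,1)) / C(10,5)
        c = SharingCounts(n1=10, m1=4, k1=5, l1=3)
        assert hypergeom_sharing_pvalue(c) == pytest.approx(66 / 252, abs=1e-12)
        assert hypergeom_tail_exact(10, 4, 5, 3) == pytest.approx(66 / 252)

    def test_all_mirnas_target_lncrnas(self):
        c = SharingCounts(n1=8, m1=8, k1=3, l1=1)
        assert hypergeom_sharing_pvalue(c) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(SpongeError, match="inconsistent"):
            SharingCounts(n1=10, m1=2, k1=3, l1=4)
        with pytest.raises(SpongeError):
            sharing_counts([], ["B"], targets_from_edges(["m"], ["A"], ["B"], []), ["m"])
        with pytest.raises(SpongeError, match="universe"):
            sharing_counts(["A"], ["B"], targets_from_edges(["m"], ["A"], ["B"], []), [])


class TestCanonicalCorrelation:
    def test_scalar_case_is_absolute_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = -0.7 * x + rng.normal(size=60)
        cc = canonical_correlation(x, y).cc
        assert cc == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-10)

    def test_invariance_under_invertible_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 4))
        y = rng.normal(size=(80, 3)) + x[:, :3]
        base = canonical_correlation(x, y).cc
        r = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        q = rng.normal(size=(3, 3)) + 4 * np.eye(3)
        assert canonical_correlation(x @ r, y @ q).cc == pytest.approx(base, abs=1e-8)

    def test_linear_image_has_unit_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 3))
        r = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        assert canonical_correlation(x, x @ r).cc == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_generalized_eigenproblem_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(100, 3))
        y = rng.normal(size=(100, 2)) + 0.5 * x[:, :2]
        cc = canonical_correlation(x, y).cc
        assert cc == pytest.approx(first_cc_eigen(x, y), abs=1e-8)

    def test_dimension_guard_prevents_trivial_unit_cc(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 50))
        y = rng.normal(size=(30, 50))
        res = canonical_correlation(x, y)
        assert res.dims == (10, 10)  # floor(30 / 3)
        assert res.cc < 1.0

    def test_constant_column_and_sample_guards(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 2))
        bad = x.copy()
        bad[:, 1] = 5.0
        with pytest.raises(SpongeError, match="constant column"):
            canonical_correlation(bad, x)
        with pytest.raises(SpongeError, match="3 samples"):
            canonical_correlation(x[:2], x[:2])


class TestPartialAndSensitivityCC:
    def test_hand_arithmetic_example(self):
        # (0.9 - 0.3) / sqrt(0.64 * 0.75)
        assert partial_cc(0.9, 0.6, 0.5) == pytest.approx(0.866025, abs=1e-6)

    def test_uncorrelated_conditioning_gives_zero_scc(self):
        assert partial_cc(0.73, 0.0, 0.0) == 0.73

    def test_unit_conditioning_rejected(self):
        with pytest.raises(SpongeError, match="magnitude 1"):
            partial_cc(0.5, 1.0, 0.2)

    def test_scalar_groups_reduce_to_classical_partial_correlation(self):
        # ceRNA-like sign pattern: z represses both x and y
        rng = np.random.default_rng(5)
        z = rng.normal(size=300)
        x = -0.6 * z + rng.normal(size=300)
        y = -0.6 * z + 0.4 * x + rng.normal(size=300)
        parts = sensitivity_cc(x[:, None], y[:, None], z[:, None])
        assert parts.pcc == pytest.approx(partial_corr_residual(x, y, z), abs=1e-10)

    def test_scc_identity_exact(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(100, 4))
        y = rng.normal(size=(100, 5)) + x[:, :4] @ rng.normal(size=(4, 5)) * 0.3
        z = rng.normal(size=(100, 2))
        parts = sensitivity_cc(x, y, z)
        assert parts.scc == parts.cc_lnc_mr - parts.pcc

    def test_decoy_module_scc_near_zero(self):
        spec = SimulationSpec(
            n_samples=200, n_mrna=50, n_lncrna=10, n_mirna=3,
            modules=(ModuleSpec(10, 50, 3, 1.0, 0.0),),
            background_target_density=0.0, seed=0,
        )
        bundle, _, truth = generate_bundle(spec)
        parts = sensitivity_cc(
            bundle.lncrna.loc[truth.members(1, "lncrna")].T.to_numpy(),
            bundle.mrna.loc[truth.members(1, "mrna")].T.to_numpy(),
            bundle.mirna.loc[truth.shared_mirnas[1]].T.to_numpy(),
        )
        assert abs(parts.scc) < 0.1

    def test_mediated_module_scc_clearly_positive(self):
        # miRNA-dominated sponge module: most of the group covariance flows
        # through the shared miRNAs, so partialling them out collapses CC
        spec = SimulationSpec(
            n_samples=200, n_mrna=50, n_lncrna=10, n_mirna=3,
            modules=(ModuleSpec(10, 50, 3, 0.3, 0.8),),
            background_target_density=0.0, seed=0,
        )
        bundle, _, truth = generate_bundle(spec)
        parts = sensitivity_cc(
            bundle.lncrna.loc[truth.members(1, "lncrna")].T.to_numpy(),
            bundle.mrna.loc[truth.members(1, "mrna")].T.to_numpy(),
            bundle.mirna.loc[truth.shared_mirnas[1]].T.to_numpy(),
        )
        assert parts.scc > 0.1


class TestNullModel:
    def test_zero_scc_is_never_significant(self):
        nm = NullModel(n_null=2000, seed=1)
        assert nm.pvalue(5, 5, 2, 100, 0.5, 0.0) > 0.05

    def test_extreme_observation_gets_minimal_pvalue(self):
        nm = NullModel(n_null=500, seed=2)
        assert nm.pvalue(5, 5, 2, 100, 0.5, 5.0) == pytest.approx(1 / 501)

    def test_distribution_cached_per_geometry(self):
        nm = NullModel(n_null=200, seed=3)
        a = nm.null_scc(5, 8, 2, 60, 0.51)
        b = nm.null_scc(5, 8, 2, 60, 0.52)  # same 0.05-bin
        assert a is b

    def test_requires_minimum_draws(self):
        with pytest.raises(SpongeError):
            NullModel(n_null=10)


def single_module_bundle(alpha, beta, seed, n=200):
    # a 35-miRNA universe of which only the 3 planted ones target the module,
    # so the sharing test is informative
    spec = SimulationSpec(
        n_samples=n, n_mrna=50, n_lncrna=10, n_mirna=35,
        modules=(ModuleSpec(10, 50, 3, alpha, beta),),
        background_target_density=0.0, seed=seed,
    )
    return generate_bundle(spec)


class TestIdentifySpongeModules:
    def test_power_on_planted_sponges(self):
        # sensitivity over 20 seeds at miRNA loading 0.8, 3 shared miRNAs
        nm = NullModel(n_null=2000, seed=0)
        flagged = 0
        for seed in range(20):
            bundle, targets, truth = single_module_bundle(0.6, 0.8, seed)
            ma = ModuleAssignment(
                pd.Series(
                    {g: l for g, l in truth.module_labels.items()}
                ).reindex(bundle.coding_noncoding().index)
            )
            results = identify_sponge_modules(
                bundle, ma, targets, null_model=nm
            )
            flagged += results[0].is_sponge
        assert flagged >= 15  # sensitivity >= 0.75

    def test_zero_edge_targets_pass_nothing(self, default_study):
        bundle, _, truth = default_study
        mirnas = list(bundle.mirna.index)
        empty = targets_from_edges(
            mirnas, list(bundle.lncrna.index), list(bundle.mrna.index), []
        )
        ma = ModuleAssignment(
            pd.Series(truth.module_labels).reindex(bundle.coding_noncoding().index)
        )
        results = identify_sponge_modules(
            bundle, ma, empty, null_model=NullModel(n_null=200, seed=0)
        )
        assert results and all(r.sharing_p == 1.0 for r in results)
        assert not any(r.is_sponge for r in results)

    def test_bh_adjustment_matches_independent_implementation(
        self, default_pipeline_run
    ):
        result, _ = default_pipeline_run
        tested = [r for r in result.sponge_results if np.isfinite(r.null_p)]
        expected = bh_adjust([r.null_p for r in tested])
        for r, e in zip(tested, expected):
            assert r.adj_p == pytest.approx(e, abs=1e-12)

    def test_results_report_scc_identity(self, default_pipeline_run):
        result, _ = default_pipeline_run
        for r in result.sponge_results:
            if np.isfinite(r.scc):
                assert r.scc == r.cc_lnc_mr - r.pcc


class TestInteractions:
    def test_single_mirna_fanout(self):
        t = targets_from_edges(
            ["m1"], ["A", "D"], ["B", "C"],
            [("m1", "A"), ("m1", "B"), ("m1", "C")],
        )
        out = extract_interactions(["A", "D"], ["B", "C"], ["m1"], t)
        assert out == [("A", "B", ("m1",)), ("A", "C", ("m1",))]

    def test_lncrna_only_mirna_yields_nothing(self):
        t = targets_from_edges(["m1"], ["A"], ["B"], [("m1", "A")])
        assert extract_interactions(["A"], ["B"], ["m1"], t) == []

    def test_fully_connected_module_pair_count(self):
        lncs = [f"L{i}" for i in range(5)]
        mrs = [f"R{i}" for i in range(20)]
        mirs = ["m1", "m2", "m3"]
        edges = [(m, g) for m in mirs for g in lncs + mrs]
        t = targets_from_edges(mirs, lncs, mrs, edges)
        out = extract_interactions(lncs, mrs, mirs, t)
        assert len(out) == 100
        assert all(m == ("m1", "m2", "m3") for _, _, m in out)

    def test_outdegree_ranking(self):
        inter = [("A", "B", ("m",)), ("A", "C", ("m",)), ("D", "B", ("m",))]
        table = lncrna_outdegree(inter)
        assert list(table.itertuples(index=False, name=None)) == [
            ("A", 2), ("D", 1)
        ]
        assert lncrna_outdegree([]).empty

    def test_tied_outdegree_ordered_by_id(self):
        lncs = [f"L{i}" for i in range(5)]
        mrs = [f"R{i}" for i in range(20)]
        edges = [("m1", g) for g in lncs + mrs]
        t = targets_from_edges(["m1"], lncs, mrs, edges)
        table = lncrna_outdegree(extract_interactions(lncs, mrs, ["m1"], t))
        assert list(table.lncrna) == lncs
        assert (table.out_degree == 20).all()
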