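"""Partial-correlation formula, edge classification, duplication filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathdyn import synthetic
from pathdyn.datasets import profile_matrix
from pathdyn.network import (
    NetworkError,
    PartialCorrelationRow,
    ThresholdSet,
    build_network,
    calibrate_thresholds,
    classify_edge,
    evaluate_experiment,
    partial_correlation,
    partial_correlation_row,
    select_environment,
)


def pc_oracle(r_xy, r_xz, r_yz):
    """Residual-correlation brute force: invert the 3x3 correlation matrix."""
    S = np.array([[1.0, r_xy, r_xz], [r_xy, 1.0, r_yz], [r_xz, r_yz, 1.0]])
    P = np.linalg.inv(S)
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


def valid_triples(n, seed=0):
    """Positive-definite (r_xy, r_xz, r_yz) triples."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        r = rng.uniform(-0.99, 0.99, 3)
        det = 1 + 2 * r[0] * r[1] * r[2] - r[0] ** 2 - r[1] ** 2 - r[2] ** 2
        if det > 1e-6:
            out.append(tuple(r))
    return out


class TestPartialCorrelation:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.8, 0.0, 0.0), 0.8),  # no conditioning effect
            ((0.72, 0.9, 0.8), 0.0),  # exact mediation: r_xy = r_xz * r_yz
            ((0.9, 0.9, 0.9), 0.09 / 0.19),  # hand-evaluated
        ],
    )
    def test_reference_values(self, triple, expected):
        assert partial_correlation(*triple) == pytest.approx(expected, abs=1e-12)

    def test_undefined_at_unit_conditioning_correlation(self):
        with pytest.raises(NetworkError):
            partial_correlation(0.5, 1.0, 0.3)

    def test_matches_residual_correlation_oracle(self):
        for triple in valid_triples(1000, seed=1):
            assert partial_correlation(*triple) == pytest.approx(
                pc_oracle(*triple), abs=1e-10
            )

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.floats(-0.95, 0.95),
        st.floats(-0.95, 0.95),
        st.floats(-0.95, 0.95),
    )
    def test_symmetric_in_x_and_y(self, r_xy, r_xz, r_yz):
        assert partial_correlation(r_xy, r_xz, r_yz) == pytest.approx(
            partial_correlation(r_xy, r_yz, r_xz), abs=1e-12
        )

    def test_gaussian_sample_cross_check(self):
        """Formula on sample correlations equals correlation of regression
        residuals computed directly on a large Gaussian sample."""
        rng = np.random.default_rng(2)
        z = rng.standard_normal(200000)
        x = 0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(z.size)
        y = 0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(z.size)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        assert partial_correlation(r_xy, r_xz, r_yz) == pytest.approx(
            np.corrcoef(rx, ry)[0, 1], abs=1e-6
        )


class TestEnvironment:
    def _corr(self, mat, genes):
        return pd.DataFrame(mat, index=genes, columns=genes)

    def test_uncorrelated_gene_has_empty_environment(self):
        genes = list("xyz")
        corr = self._corr(np.eye(3), genes)
        assert select_environment("x", corr, 0.6) == []

    def test_zero_threshold_takes_everything(self):
        genes = list("xyz")
        m = np.array([[1.0, 0.3, -0.2], [0.3, 1.0, 0.1], [-0.2, 0.1, 1.0]])
        assert set(select_environment("x", self._corr(m, genes), 1e-12)) == {"y", "z"}

    def test_chain_environment_contains_mediator_and_endpoint(self, default_run):
        truth, nm, rm = default_run["truth"], default_run["nm"], default_run["rm"]
        x, y, z = truth.true_indirect_pairs[0]
        genes = truth.dynamic_genes
        prof = profile_matrix(nm.values.loc[genes], rm.meta, "control", 1)
        corr = pd.DataFrame(
            np.corrcoef(prof.to_numpy()), index=genes, columns=genes
        )
        env = select_environment(x, corr, 0.6)
        assert {y, z} <= set(env)


class TestRowAndClassification:
    def test_empty_environment_falls_back_to_raw_correlation(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(8)
        prof = pd.DataFrame(
            [base, 0.9 * base + 0.1 * rng.standard_normal(8)], index=["x", "y"],
            columns=range(8),
        )
        row = partial_correlation_row("x", "y", ["y"], prof)
        assert row.entries == {}
        assert row.pc_m == row.pc_a == pytest.approx(abs(row.r_xy))

    def test_identical_profiles_rejected(self):
        base = np.arange(8.0)
        prof = pd.DataFrame(
            [base, base, base], index=["x", "y", "z"], columns=range(8)
        )
        row = partial_correlation_row("x", "y", ["y", "z"], prof)
        # a perfect-copy conditioner carries no information and is dropped,
        # leaving the fallback statistics
        assert row.entries == {}
        prof.loc["z"] = 0.0
        with pytest.raises(NetworkError, match="constant"):
            partial_correlation_row("x", "y", ["y", "z"], prof)

    def test_planted_chain_row_has_single_hole_at_mediator(self, default_run):
        truth, nm, rm = default_run["truth"], default_run["nm"], default_run["rm"]
        for x, y, z in truth.true_indirect_pairs:
            found = False
            for grp in ("control", "case"):
                cols = rm.columns_for(group=grp)
                prof = nm.values.loc[truth.dynamic_genes, cols]
                corr = pd.DataFrame(
                    np.corrcoef(prof.to_numpy()),
                    index=truth.dynamic_genes,
                    columns=truth.dynamic_genes,
                )
                env = select_environment(x, corr, 0.6)
                if y not in env:
                    continue
                row = partial_correlation_row(x, y, env, prof, t_m=0.6)
                if row.holes == [z]:
                    found = True
            assert found, f"chain ({x}, {z}, {y}): mediator hole not detected"

    def _row(self, entries, t_m=0.6, x="x", y="y", r=0.9):
        abs_e = [abs(v) for v in entries.values()]
        holes = [k for k, v in entries.items() if abs(v) < t_m]
        pc_m = min(abs_e) if abs_e else abs(r)
        pc_a = float(np.mean(abs_e)) if abs_e else abs(r)
        return PartialCorrelationRow(x, y, r, entries, pc_m, pc_a, holes, t_m)

    def test_uniform_row_is_essential(self):
        row = self._row({"a": 0.8, "b": 0.8, "c": 0.8})
        ts = ThresholdSet(0.5, 0.6, 0.8)
        assert classify_edge(row, {}, ts).kind == "essential"

    def test_single_hole_without_reciprocal_is_indirect(self):
        row = self._row({"a": 0.8, "b": 0.8, "z": 0.2})
        row_xz = self._row({"a": 0.9, "y": 0.8}, x="x", y="z")
        cl = classify_edge(row, {"z": row_xz}, ThresholdSet(0.5, 0.6, 0.8))
        assert cl.kind == "indirect" and cl.via == "z"

    def test_reciprocal_hole_makes_triangle(self):
        row = self._row({"a": 0.8, "z": 0.2})
        row_xz = self._row({"a": 0.9, "y": 0.3}, x="x", y="z")
        cl = classify_edge(row, {"z": row_xz}, ThresholdSet(0.5, 0.6, 0.8))
        assert cl.kind == "triangle" and cl.keeps_edge

    def test_two_holes_is_no_edge(self):
        row = self._row({"a": 0.2, "b": 0.3, "c": 0.9})
        assert classify_edge(row, {}, ThresholdSet(0.5, 0.6, 0.8)).kind == "none"

    def test_mutually_coupled_trio_never_indirect(self):
        """Three genes sharing one driver are all pairwise directly coupled
        (true partial correlation 1/2 per pair for equal noise); no pair may
        be explained away as indirect.  A long series keeps the sample
        partial correlations near their population value."""
        rng = np.random.default_rng(5)
        t = rng.standard_normal(400)
        profs = {g: t + 0.2 * rng.standard_normal(400) for g in "xyz"}
        prof = pd.DataFrame(profs).T
        res = evaluate_experiment(prof, ThresholdSet(0.6, 0.4, 0.4))
        assert len(res) == 3
        for pair, (cl, _) in res.items():
            assert cl.kind in ("essential", "triangle"), (pair, cl)


class TestBuildNetwork:
    def _experiments(self, seed=0, coupled_groups=("control", "case")):
        rng = np.random.default_rng(seed)
        exps = {}
        for grp in ("control", "case"):
            dups = []
            for _ in range(2):
                t = rng.standard_normal(8)
                x = t + 0.1 * rng.standard_normal(8)
                if grp in coupled_groups:
                    y = t + 0.1 * rng.standard_normal(8)
                else:
                    y = rng.standard_normal(8)
                dups.append(
                    pd.DataFrame([x, y], index=["x", "y"], columns=range(8))
                )
            exps[grp] = dups
        return exps

    def test_edge_in_single_duplicate_dropped(self):
        rng = np.random.default_rng(6)
        t = rng.standard_normal(8)
        dup1 = pd.DataFrame(
            [t, t + 0.05 * rng.standard_normal(8)], index=["x", "y"], columns=range(8)
        )
        dup2 = pd.DataFrame(
            rng.standard_normal((2, 8)), index=["x", "y"], columns=range(8)
        )
        edges = build_network({"control": [dup1, dup2]}, ThresholdSet(0.6, 0.4, 0.4))
        assert edges == []

    def test_shared_edge_has_both_provenance(self):
        edges = build_network(self._experiments(7), ThresholdSet(0.6, 0.4, 0.4))
        assert len(edges) == 1 and edges[0].provenance == "both"

    def test_group_specific_edge_provenance(self):
        edges = build_network(
            self._experiments(8, coupled_groups=("case",)),
            ThresholdSet(0.6, 0.4, 0.4),
        )
        assert [e.provenance for e in edges] == ["case_only"]

    def test_planted_group_edges_recovered_with_provenance(self, default_run):
        truth, nm, rm = default_run["truth"], default_run["nm"], default_run["rm"]
        genes = truth.dynamic_genes
        experiments = {
            grp: [
                profile_matrix(nm.values.loc[genes], rm.meta, grp, d) for d in (1, 2)
            ]
            for grp in ("control", "case")
        }
        edges = build_network(experiments, ThresholdSet.duplicated())
        found = {tuple(sorted((e.x, e.y))): (e.sign, e.provenance) for e in edges}
        expected_prov = {"both": "both", "case": "case_only", "control": "control_only"}
        for a, b, sign, grp in truth.true_edges:
            pair = tuple(sorted((a, b)))
            assert pair in found, f"planted edge {pair} missing"
            assert found[pair] == (sign, expected_prov[grp])

    def test_mismatched_gene_universe_rejected(self):
        p1 = pd.DataFrame(np.random.default_rng(0).standard_normal((2, 8)), index=["a", "b"])
        p2 = pd.DataFrame(np.random.default_rng(1).standard_normal((2, 8)), index=["a", "c"])
        with pytest.raises(NetworkError, match="universe"):
            build_network({"control": [p1, p2]}, ThresholdSet(0.6, 0.4, 0.4))


class TestCalibration:
    def test_unreachable_thresholds_give_zero(self):
        res = calibrate_thresholds(
            50, 8, ThresholdSet(0.99, 0.99, 0.99), 5, False, seed=0
        )
        assert res.fp_rate == pytest.approx(0.0, abs=1e-9)

    def test_duplication_reduces_false_positive_rate(self):
        ts = ThresholdSet.duplicated()
        single = calibrate_thresholds(100, 8, ts, 20, False, seed=3)
        dup = calibrate_thresholds(100, 8, ts, 20, True, seed=3)
        assert dup.fp_rate <= single.fp_rate

    def test_deterministic_per_seed(self):
        a = calibrate_thresholds(80, 8, ThresholdSet.single(), 3, False, seed=9)
        b = calibrate_thresholds(80, 8, ThresholdSet.single(), 3, False, seed=9)
        assert a.per_sim == b.per_sim

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(NetworkError):
            ThresholdSet(0.0, 0.5, 0.5)
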