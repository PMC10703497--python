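import numpy as np
import pandas as pd
import pytest

from celltics.markers import (
    MarkerScores,
    aggregate_by_type,
    compute_scores,
    high_specificity_scores,
    low_specificity_scores,
    select_markers,
)


def _profile(values, types=None, genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    types = types or [f"t{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=types, columns=genes)


def _loop_scores(expr):
    """Entry-by-entry reference implementation of all six measures."""
    n, G = expr.shape
    xhat = np.empty_like(expr)
    zhat = np.empty_like(expr)
    for g in range(G):
        mx, mn = expr[:, g].max(), expr[:, g].min()
        for t in range(n):
            xhat[t, g] = (expr[t, g] + 1) / (mx + 1)
            zhat[t, g] = (mn + 1) / (expr[t, g] + 1)
    tau = np.array([(1 - xhat[:, g]).sum() / (n - 1) for g in range(G)])
    omega = np.array([(1 - zhat[:, g]).sum() / (n - 1) for g in range(G)])
    return tau[None, :] * xhat, tau, xhat, omega[None, :] * zhat, omega, zhat


class TestAggregate:
    def test_mean_over_cells_of_type(self):
        norm = pd.DataFrame({"c1": [1.0], "c2": [3.0], "c3": [5.0]}, index=["g"])
        annot = pd.DataFrame({"cell_type": ["A", "A", "B"]}, index=["c1", "c2", "c3"])
        profile = aggregate_by_type(norm, annot)
        assert profile.loc["A", "g"] == 2.0
        assert profile.loc["B", "g"] == 5.0

    def test_single_label_raises(self):
        norm = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["g"])
        annot = pd.DataFrame({"cell_type": ["A", "A"]}, index=["c1", "c2"])
        with pytest.raises(ValueError, match=">= 2"):
            aggregate_by_type(norm, annot)

    def test_missing_label_raises(self):
        norm = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["g"])
        annot = pd.DataFrame({"cell_type": ["A", None]}, index=["c1", "c2"])
        with pytest.raises(ValueError, match="without"):
            aggregate_by_type(norm, annot)


class TestSpecificityFormulas:
    @pytest.mark.parametrize(
        "expr,xhat,tau,phi",
        [
            ([3, 0], [1.0, 0.25], 0.75, [0.75, 0.1875]),
            ([9, 4], [1.0, 0.5], 0.5, [0.5, 0.25]),
        ],
    )
    def test_high_measure_two_types(self, expr, xhat, tau, phi):
        phi_df, tau_s, xhat_df = high_specificity_scores(_profile(np.array(expr).reshape(-1, 1)))
        np.testing.assert_allclose(xhat_df.iloc[:, 0], xhat)
        assert tau_s.iloc[0] == pytest.approx(tau)
        np.testing.assert_allclose(phi_df.iloc[:, 0], phi)

    def test_low_measure_two_types(self):
        rho, omega, zhat = low_specificity_scores(_profile([[0.0], [7.0]]))
        np.testing.assert_allclose(zhat.iloc[:, 0], [1.0, 0.125])
        assert omega.iloc[0] == pytest.approx(0.875)
        np.testing.assert_allclose(rho.iloc[:, 0], [0.875, 0.109375])

    def test_uniform_gene_has_no_specificity(self):
        profile = _profile([[2.0, 5.0], [2.0, 5.0], [2.0, 5.0]])
        phi, tau, _ = high_specificity_scores(profile)
        rho, omega, _ = low_specificity_scores(profile)
        assert (tau == 0).all() and (phi.to_numpy() == 0).all()
        assert (omega == 0).all() and (rho.to_numpy() == 0).all()

    def test_matches_loop_oracle_and_bounds(self, rng):
        expr = rng.uniform(0, 10, size=(5, 40))
        profile = _profile(expr)
        phi, tau, xhat = high_specificity_scores(profile)
        rho, omega, zhat = low_specificity_scores(profile)
        o_phi, o_tau, o_xhat, o_rho, o_omega, o_zhat = _loop_scores(expr)
        np.testing.assert_allclose(phi.to_numpy(), o_phi, atol=1e-12)
        np.testing.assert_allclose(tau.to_numpy(), o_tau, atol=1e-12)
        np.testing.assert_allclose(rho.to_numpy(), o_rho, atol=1e-12)
        np.testing.assert_allclose(omega.to_numpy(), o_omega, atol=1e-12)
        assert ((phi.to_numpy() >= 0) & (phi.to_numpy() <= 1)).all()
        assert ((rho.to_numpy() >= 0) & (rho.to_numpy() <= 1)).all()
        assert ((xhat.to_numpy() > 0) & (xhat.to_numpy() <= 1)).all()
        assert ((zhat.to_numpy() > 0) & (zhat.to_numpy() <= 1)).all()

    def test_phi_equals_tau_at_argmax_and_rho_equals_omega_at_argmin(self, rng):
        expr = rng.uniform(0, 10, size=(4, 25))
        profile = _profile(expr)
        phi, tau, _ = high_specificity_scores(profile)
        rho, omega, _ = low_specificity_scores(profile)
        argmax = expr.argmax(axis=0)
        argmin = expr.argmin(axis=0)
        for j in range(25):
            assert phi.iloc[argmax[j], j] == pytest.approx(tau.iloc[j], abs=1e-12)
            assert (phi.iloc[:, j] <= tau.iloc[j] + 1e-12).all()
            assert rho.iloc[argmin[j], j] == pytest.approx(omega.iloc[j], abs=1e-12)

    def test_type_permutation_equivariance(self, rng):
        expr = rng.uniform(0, 8, size=(5, 12))
        base = compute_scores(_profile(expr))
        perm = rng.permutation(5)
        permuted = compute_scores(
            _profile(expr[perm], types=[f"t{i}" for i in perm])
        )
        np.testing.assert_allclose(
            base.phi.iloc[perm].to_numpy(), permuted.phi.to_numpy(), atol=1e-14
        )
        np.testing.assert_allclose(base.tau.to_numpy(), permuted.tau.to_numpy(), atol=1e-14)


class TestSelection:
    @staticmethod
    def _scores(phi_rows, rho_rows=None):
        types = [f"t{i}" for i in range(len(phi_rows))]
        genes = [f"gene{j + 1}" for j in range(len(phi_rows[0]))]
        phi = pd.DataFrame(phi_rows, index=types, columns=genes)
        rho = pd.DataFrame(rho_rows if rho_rows is not None else np.zeros_like(phi_rows),
                           index=types, columns=genes)
        zeros = pd.DataFrame(np.zeros_like(phi), index=types, columns=genes)
        return MarkerScores(phi=phi, tau=phi.iloc[0] * 0, xhat=zeros,
                            rho=rho, omega=phi.iloc[0] * 0, zhat=zeros)

    def test_strictly_above_median(self):
        ms = select_markers(self._scores([[0.9, 0.5, 0.1], [0.0, 0.0, 0.0]]), alpha=0.5, beta=0.0)
        assert ms.high["t0"] == ["gene1"]  # 0.5 ties the median and is excluded

    def test_quantile_above_all_values_selects_nothing(self):
        ms = select_markers(self._scores([[0.2, 0.2, 0.2], [0.2, 0.2, 0.2]]), alpha=0.99, beta=0.99)
        assert ms.high["t0"] == [] and ms.low["t0"] == []

    def test_union_of_disjoint_top_genes(self):
        ms = select_markers(
            self._scores([[0.9, 0.0, 0.0, 0.0], [0.0, 0.8, 0.0, 0.0]]), alpha=0.6, beta=0.0
        )
        assert ms.high["t0"] == ["gene1"] and ms.high["t1"] == ["gene2"]
        assert ms.combined == ["gene1", "gene2"]

    def test_raising_alpha_never_enlarges_selection(self, rng):
        expr = rng.uniform(0, 10, size=(4, 30))
        scores = compute_scores(_profile(expr))
        prev_high = prev_low = None
        for q in [0.0, 0.3, 0.6, 0.9, 0.99]:
            ms = select_markers(scores, alpha=q, beta=q)
            if prev_high is not None:
                for t in ms.high:
                    assert set(ms.high[t]) <= prev_high[t]
                    assert set(ms.low[t]) <= prev_low[t]
            prev_high = {t: set(v) for t, v in ms.high.items()}
            prev_low = {t: set(v) for t, v in ms.low.items()}

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            select_markers(self._scores([[0.1], [0.2]]), alpha=1.0)
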