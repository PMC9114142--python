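"""Multivariate REML: likelihood oracle, closed-form checks and recovery."""

import numpy as np
import pandas as pd
import pytest

from corrbreak import kinship, mtmm


def _one_way(rng, q=40, r=5, sigma_u=0.7, sigma_e=1.3):
    u = rng.normal(0, np.sqrt(sigma_u), q)
    gid = np.repeat([f"g{i}" for i in range(q)], r)
    y = np.repeat(u, r) + rng.normal(0, np.sqrt(sigma_e), q * r)
    return pd.DataFrame({"genotype_id": gid, "y": y})


def _bivariate(rng, q=150, r=3, rg=-0.4):
    L = np.linalg.cholesky(np.array([[1.0, rg], [rg, 1.0]]))
    u = rng.standard_normal((q, 2)) @ L.T
    idx = np.repeat(np.arange(q), r)
    y = u[idx] + rng.standard_normal((q * r, 2))
    return pd.DataFrame(
        {"genotype_id": [f"g{i}" for i in idx], "t1": y[:, 0], "t2": y[:, 1]}
    )


class TestStandardize:
    def test_unit_variance_per_site(self, rng):
        ph = pd.DataFrame(
            {
                "site": np.repeat(["S1", "S2"], 50),
                "x": np.concatenate([rng.normal(5, 2, 50), rng.normal(-1, 0.3, 50)]),
            }
        )
        out = mtmm.standardize_by_site(ph, ["x"])
        for _, grp in out.groupby("site"):
            assert grp["x"].mean() == pytest.approx(0.0, abs=1e-10)
            assert grp["x"].std(ddof=0) == pytest.approx(1.0)

    def test_constant_stratum_rejected(self):
        ph = pd.DataFrame({"site": ["S1", "S1"], "x": [3.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            mtmm.standardize_by_site(ph, ["x"])


class TestModelSpec:
    def test_needs_terms(self):
        with pytest.raises(ValueError):
            mtmm.ModelSpec(traits=["y"], terms=[])

    def test_presets_define_expected_terms(self):
        rel = kinship.RelationshipMatrix(
            ids=np.array(["a", "b"], dtype=object), values=np.eye(2), kind="G"
        )
        tm = mtmm.training_model(["y"], rel)
        assert [t.name for t in tm.terms] == [
            "additive",
            "nonadditive",
            "replicate",
            "set_in_rep",
        ]
        pm = mtmm.prediction_model(["y"], rel)
        assert "incomplete_block" in [t.name for t in pm.terms]

    def test_add_design_factors(self):
        ph = pd.DataFrame({"site": ["A"], "rep": [2], "set_or_block": [3]})
        out = mtmm.add_design_factors(ph)
        assert out.loc[0, "rep_factor"] == "A:2"
        assert out.loc[0, "group_factor"] == "A:2:3"


class TestUnivariateClosedForm:
    def test_matches_balanced_anova_reml(self, rng):
        """Balanced one-way REML has the classical mean-squares solution."""
        ph = _one_way(rng)
        q, r = 40, 5
        spec = mtmm.ModelSpec(
            traits=["y"], terms=[mtmm.RandomTerm("additive", "genotype_id", None)]
        )
        vc = mtmm.reml_fit(spec, ph)
        means = ph.groupby("genotype_id")["y"].mean()
        grand = ph["y"].mean()
        msb = 5 * ((means - grand) ** 2).sum() / (q - 1)
        mse = ((ph["y"] - means.loc[ph["genotype_id"]].to_numpy()) ** 2).sum() / (
            q * (r - 1)
        )
        np.testing.assert_allclose(vc.residual[0, 0], mse, rtol=1e-4)
        np.testing.assert_allclose(
            vc.components["additive"][0, 0], (msb - mse) / r, rtol=1e-3
        )


class TestLikelihoodOracle:
    def test_internal_likelihood_matches_dense_formula(self, rng):
        """-2 logL from the MME equals log|V| + log|X'V^-1 X| + y'Py."""
        q = 12
        ids = np.array([f"g{i}" for i in range(q)], dtype=object)
        M = rng.standard_normal((q, q))
        K = M @ M.T / q + 0.5 * np.eye(q)
        rel = kinship.RelationshipMatrix(ids=ids, values=K, kind="A")
        r = 3
        gid = np.repeat(ids, r)
        batch = np.array([f"b{k % 4}" for k in range(q * r)])
        Y = rng.standard_normal((q * r, 2))
        ph = pd.DataFrame(
            {"genotype_id": gid, "batch": batch, "t1": Y[:, 0], "t2": Y[:, 1]}
        )
        spec = mtmm.ModelSpec(
            traits=["t1", "t2"],
            terms=[
                mtmm.RandomTerm("additive", "genotype_id", rel),
                mtmm.RandomTerm("batch", "batch", None),
            ],
        )
        vc = mtmm.reml_fit(spec, ph)

        # dense-matrix oracle at the fitted parameters
        ws = mtmm._Workspace(spec, ph)
        N, t = ws.N, ws.t
        y = ws.Y.T.reshape(-1)  # trait-major
        X = np.kron(np.eye(t), np.ones((N, 1)))
        V = np.kron(vc.residual, np.eye(N))
        for name in ws.term_names:
            sl = ws.term_slice(name)
            Z = ws.B[:, sl]
            V += np.kron(vc.components[name], Z @ ws.K[name] @ Z.T)
        Vinv = np.linalg.inv(V)
        XtVX = X.T @ Vinv @ X
        P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
        m2ll = (
            np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtVX)[1]
            + float(y @ P @ y)
        )
        assert -2.0 * vc.loglik == pytest.approx(m2ll, abs=1e-6)


class TestBivariateRecovery:
    def test_recovers_h2_and_rg(self, rng):
        ph = _bivariate(rng, q=250)
        spec = mtmm.ModelSpec(
            traits=["t1", "t2"],
            terms=[mtmm.RandomTerm("additive", "genotype_id", None)],
        )
        vc = mtmm.reml_fit(spec, ph)
        assert vc.converged
        gp = mtmm.genetic_params(vc)
        for h2 in gp.h2["h2"]:
            assert h2 == pytest.approx(0.5, abs=0.15)
        assert gp.rg["rg"].iloc[0] == pytest.approx(-0.4, abs=0.2)
        # delta-method SEs are finite and positive at an interior optimum
        assert (gp.h2["se"] > 0).all() and (gp.rg["se"] > 0).all()

    def test_blups_and_ebv_track_truth(self, rng):
        ph = _bivariate(rng, q=200)
        spec = mtmm.ModelSpec(
            traits=["t1", "t2"],
            terms=[mtmm.RandomTerm("additive", "genotype_id", None)],
        )
        vc = mtmm.reml_fit(spec, ph)
        ebv = mtmm.extract_ebv(vc, "additive")
        assert ebv.shape == (200, 2)
        # BLUPs should correlate strongly with genotype phenotype means
        means = ph.groupby("genotype_id")["t1"].mean().loc[ebv.index]
        acc = mtmm.prediction_accuracy(ebv["t1"], means - means.mean())
        assert acc > 0.95


class TestGeneticParams:
    def _vc(self):
        comps = {"additive": np.array([[0.4, -0.12], [-0.12, 0.36]])}
        resid = np.array([[0.6, 0.0], [0.0, 0.24]])
        names = [
            "additive:t1:t1",
            "additive:t1:t2",
            "additive:t2:t2",
            "residual:t1:t1",
            "residual:t1:t2",
            "residual:t2:t2",
        ]
        return mtmm.VarianceComponents(
            components=comps,
            residual=resid,
            loglik=0.0,
            ai_matrix=None,
            param_names=names,
            traits=["t1", "t2"],
            n_records=10,
            converged=True,
        )

    def test_hand_values(self):
        gp = mtmm.genetic_params(self._vc())
        assert gp.h2["h2"].tolist() == pytest.approx([0.4, 0.6])
        assert gp.rg["rg"].iloc[0] == pytest.approx(-0.12 / np.sqrt(0.4 * 0.36))
        # no AI matrix -> SEs unavailable
        assert gp.h2["se"].isna().all()

    def test_zero_additive_variance_gives_missing_rg(self):
        vc = self._vc()
        vc.components["additive"][0, 0] = 0.0
        gp = mtmm.genetic_params(vc)
        assert np.isnan(gp.rg["rg"].iloc[0])


class TestConvergenceControl:
    def test_iteration_budget_exhaustion_raises(self, rng):
        ph = _bivariate(rng, q=60)
        spec = mtmm.ModelSpec(
            traits=["t1", "t2"],
            terms=[mtmm.RandomTerm("additive", "genotype_id", None)],
        )
        with pytest.raises(mtmm.ConvergenceError):
            mtmm.reml_fit(spec, ph, em_iterations=1, max_iterations=1, tol=1e-14)

    def test_missing_relationship_levels_detected(self, rng):
        ph = _bivariate(rng, q=10)
        rel = kinship.RelationshipMatrix(
            ids=np.array(["g0", "g1"], dtype=object), values=np.eye(2), kind="G"
        )
        spec = mtmm.ModelSpec(
            traits=["t1", "t2"],
            terms=[mtmm.RandomTerm("additive", "genotype_id", rel)],
        )
        with pytest.raises(ValueError, match="missing"):
            mtmm.reml_fit(spec, ph)
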