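"""REML engine: likelihood oracles, EM/AI updates, fit properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pedreml import (
    ModelSpec,
    Pedigree,
    VarianceComponents,
    ai_update,
    build_design,
    convergence_criterion,
    em_update,
    fit,
    fit_constrained,
    restricted_log_likelihood,
)
from pedreml.aireml import ParameterMap, build_workspace
from pedreml.pedigree import build_A, build_A_inverse
from pedreml.synthetic import drop_breeding_values

# ---------------------------------------------------------------------------
# independent dense-formula REML likelihood (the oracle)
# ---------------------------------------------------------------------------


def dense_reml_loglik(y, X, V):
    """Straight evaluation of the error-contrast likelihood from dense V."""
    n, p = X.shape
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtVX)[1]
        + float(y @ P @ y)
        + (n - p) * np.log(2 * np.pi)
    )


def toy_univariate(n_offspring=8, seed=0, h2=0.6):
    """Two sires x two dams, full-sib litters; phenotypes on offspring."""
    recs = [("S1", "", ""), ("S2", "", ""), ("D1", "", ""), ("D2", "", "")]
    parents = [("S1", "D1"), ("S1", "D2"), ("S2", "D1"), ("S2", "D2")]
    for k in range(n_offspring):
        s, d = parents[k % 4]
        recs.append((f"O{k}", s, d))
    ped = Pedigree.from_records(recs)
    rng = np.random.default_rng(seed)
    u = drop_breeding_values(ped, [[h2]], rng)
    offspring = [a for a in ped.ids if a.startswith("O")]
    y = [
        10.0 + u[ped.position(a), 0] + rng.normal(0, np.sqrt(1 - h2))
        for a in offspring
    ]
    ph = pd.DataFrame({"animal": offspring, "Y": y})
    dm = build_design(ph, ped, ModelSpec(traits=("Y",), class_effects=()))
    rel = build_A_inverse(ped)
    A = build_A(ped).A
    idx = dm.block("Y").animal_index
    return dm, rel, A[np.ix_(idx, idx)], np.asarray(y)


def test_loglik_matches_dense_formula_univariate():
    dm, rel, A_phi, y = toy_univariate(6, seed=1)
    X = dm.block("Y").X
    for s2g, s2e in [(0.5, 0.5), (0.2, 1.3), (1.7, 0.4)]:
        V = s2g * A_phi + s2e * np.eye(len(y))
        expected = dense_reml_loglik(y, X, V)
        got = restricted_log_likelihood(
            VarianceComponents([[s2g]], [[s2e]]), dm, rel
        )
        assert got == pytest.approx(expected, abs=1e-8)


def test_loglik_translation_invariant():
    dm, rel, _, _ = toy_univariate(8, seed=2)
    vc = VarianceComponents([[0.6]], [[0.7]])
    base = restricted_log_likelihood(vc, dm, rel)
    blk = dm.block("Y")
    blk.y = blk.y + 37.5  # intercept absorbs the shift
    assert restricted_log_likelihood(vc, dm, rel) == pytest.approx(base, abs=1e-8)


def disjoint_support_bivariate(seed=3):
    """Two traits recorded on disjoint halves of the offspring."""
    recs = [(f"F{k}", "", "") for k in range(8)]
    for k in range(24):
        recs.append((f"O{k}", f"F{2 * (k % 4)}", f"F{2 * (k % 4) + 1}"))
    ped = Pedigree.from_records(recs)
    rng = np.random.default_rng(seed)
    u = drop_breeding_values(ped, [[1.0, 0.0], [0.0, 1.0]], rng)
    rows = []
    for k in range(24):
        a = f"O{k}"
        val = u[ped.position(a), k % 2] + rng.normal(0, 1)
        rows.append(
            {
                "animal": a,
                "X": val if k % 2 == 0 else np.nan,
                "Y": val if k % 2 == 1 else np.nan,
            }
        )
    return ped, pd.DataFrame(rows)


def test_zero_cov_disjoint_support_factorises():
    ped, ph = disjoint_support_bivariate()
    rel = build_A_inverse(ped)
    dm2 = build_design(ph, ped, ModelSpec(traits=("X", "Y"), class_effects=()))
    G = np.diag([0.8, 1.2])
    R = np.diag([1.1, 0.9])
    joint = restricted_log_likelihood(VarianceComponents(G, R), dm2, rel)
    sep = 0.0
    for k, t in enumerate(("X", "Y")):
        dm1 = build_design(
            ph[ph[t].notna()], ped, ModelSpec(traits=(t,), class_effects=())
        )
        sep += restricted_log_likelihood(
            VarianceComponents([[G[k, k]]], [[R[k, k]]]), dm1, rel
        )
    assert joint == pytest.approx(sep, abs=1e-8)


def test_eigen_and_dense_workspaces_agree(bivariate_data):
    ds, dm, rel = bivariate_data
    ws_e = build_workspace(dm, rel, prefer_eigen=True)
    ws_d = build_workspace(dm, rel, prefer_eigen=False)
    assert type(ws_e).__name__ != type(ws_d).__name__
    G = np.array([[3.0, 1.0], [1.0, 4.0]])
    R = np.array([[5.0, 2.0], [2.0, 6.0]])
    se, sd = ws_e.state(G, R), ws_d.state(G, R)
    assert se.logL == pytest.approx(sd.logL, abs=1e-6)
    pmap = ParameterMap(2)
    ge, aie = se.score_ai(pmap)
    gd, aid = sd.score_ai(pmap)
    np.testing.assert_allclose(ge, gd, rtol=1e-6, atol=1e-8)
    np.testing.assert_allclose(aie, aid, rtol=1e-6, atol=1e-8)
    Ge, Re = se.em_step(pmap)
    Gd, Rd = sd.em_step(pmap)
    np.testing.assert_allclose(Ge, Gd, rtol=1e-8)
    np.testing.assert_allclose(Re, Rd, rtol=1e-8)


# ---------------------------------------------------------------------------
# convergence criterion
# ---------------------------------------------------------------------------


def test_convergence_criterion_arithmetic():
    assert convergence_criterion([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert convergence_criterion([2.0], [1.0]) == pytest.approx(0.25)
    assert convergence_criterion([1.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0)


def test_convergence_criterion_errors():
    with pytest.raises(ValueError):
        convergence_criterion([0.0, 0.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        convergence_criterion([1.0], [1.0, 2.0])


def test_convergence_criterion_scale_invariant():
    rng = np.random.default_rng(4)
    for _ in range(20):
        th = rng.normal(size=4)
        thp = rng.normal(size=4)
        c = convergence_criterion(th, thp)
        for a in (1e-3, 7.7, 1e4):
            assert convergence_criterion(a * th, a * thp) == pytest.approx(c)


# ---------------------------------------------------------------------------
# EM update
# ---------------------------------------------------------------------------


def grid_refine_optimum(dm, rel, A_phi, y):
    """Brute-force maximiser of the dense-formula likelihood (oracle)."""
    X = dm.block("Y").X
    n = len(y)

    def nll(log_theta):
        s2g, s2e = np.exp(log_theta)
        return -dense_reml_loglik(y, X, s2g * A_phi + s2e * np.eye(n))

    vy = np.var(y, ddof=1)
    grid = vy * np.array([0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0, 1.5])
    best = min(
        ((g, e) for g in grid for e in grid),
        key=lambda p: nll(np.log(p)),
    )
    res = optimize.minimize(
        nll, np.log(best), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 4000},
    )
    return np.exp(res.x)


def test_em_fixed_point_at_oracle_optimum():
    dm, rel, A_phi, y = toy_univariate(16, seed=7)
    s2g, s2e = grid_refine_optimum(dm, rel, A_phi, y)
    vc = VarianceComponents([[s2g]], [[s2e]])
    new = em_update(vc, dm, rel)
    move = np.abs(
        np.r_[new.G[0, 0] - s2g, new.R[0, 0] - s2e]
    ) / np.r_[s2g, s2e]
    assert move.max() < 1e-5


def test_em_monotone_from_inflated_start(bivariate_data):
    ds, dm, rel = bivariate_data
    vc = VarianceComponents(np.diag([30.0, 30.0]), np.diag([30.0, 30.0]))
    lls = []
    for _ in range(5):
        lls.append(restricted_log_likelihood(vc, dm, rel))
        vc = em_update(vc, dm, rel)
    lls.append(restricted_log_likelihood(vc, dm, rel))
    assert np.all(np.diff(lls) > 0)


def test_em_shrinks_genetic_variance_without_signal():
    """Founders only, pure-noise phenotypes: no relationship information,
    so EM drains the additive variance toward zero."""
    ped = Pedigree.from_records([(f"F{k}", "", "") for k in range(60)])
    rng = np.random.default_rng(6)
    ph = pd.DataFrame(
        {"animal": [f"F{k}" for k in range(60)], "Y": rng.normal(0, 1, 60)}
    )
    dm = build_design(ph, ped, ModelSpec(traits=("Y",), class_effects=()))
    rel = build_A_inverse(ped)
    vc = VarianceComponents([[0.5]], [[0.5]])
    g_path = [vc.G[0, 0]]
    for _ in range(8):
        vc = em_update(vc, dm, rel)
        g_path.append(vc.G[0, 0])
    assert np.all(np.diff(g_path) < 0)


# ---------------------------------------------------------------------------
# AI update
# ---------------------------------------------------------------------------


def test_ai_stationary_at_oracle_optimum():
    dm, rel, A_phi, y = toy_univariate(16, seed=7)
    s2g, s2e = grid_refine_optimum(dm, rel, A_phi, y)
    ws = build_workspace(dm, rel)
    state = ws.state(np.array([[s2g]]), np.array([[s2e]]))
    grad, AI = state.score_ai(ParameterMap(1))
    assert np.abs(grad).max() < 1e-5
    vc_new, _ = ai_update(VarianceComponents([[s2g]], [[s2e]]), dm, rel)
    assert abs(vc_new.G[0, 0] - s2g) / s2g < 1e-4
    assert abs(vc_new.R[0, 0] - s2e) / s2e < 1e-4


def test_ai_converges_much_faster_than_em(bivariate_data):
    ds, dm, rel = bivariate_data
    f_ai = fit(dm, rel, tol=1e-12, em_warmup=1, max_iter=30)
    f_em = fit(dm, rel, tol=1e-12, method="em", max_iter=100)
    assert f_ai.converged and f_ai.n_iterations <= 15
    assert not f_em.converged  # EM still grinding after 100 sweeps


def test_theta_cov_is_inverse_of_final_ai(bivariate_fit, bivariate_data):
    ds, dm, rel = bivariate_data
    ws = build_workspace(dm, rel)
    _, AI = ws.state(bivariate_fit.vc.G, bivariate_fit.vc.R).score_ai(
        ParameterMap(2)
    )
    np.testing.assert_allclose(
        bivariate_fit.theta_cov @ AI, np.eye(6), atol=1e-6
    )


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------


def test_fit_matches_grid_search_oracle_8_records():
    dm, rel, A_phi, y = toy_univariate(8, seed=7)
    f = fit(dm, rel)
    s2g, s2e = grid_refine_optimum(dm, rel, A_phi, y)
    assert f.converged
    assert f.vc.G[0, 0] == pytest.approx(s2g, rel=1e-4)
    assert f.vc.R[0, 0] == pytest.approx(s2e, rel=1e-4)


def test_fit_half_sib_matches_anova_estimator():
    """Balanced paternal half-sib design: the animal-model heritability
    must sit within the sampling error of the classical sire-variance
    ANOVA estimator 4 sigma2_s / (sigma2_s + sigma2_w)."""
    n_sires, n_prog, h2 = 50, 20, 0.4
    recs = [(f"S{i}", "", "") for i in range(n_sires)]
    for i in range(n_sires):
        for j in range(n_prog):
            recs.append((f"P{i}_{j}", f"S{i}", ""))
    ped = Pedigree.from_records(recs)
    rng = np.random.default_rng(8)
    u = drop_breeding_values(ped, [[h2]], rng)
    rows = []
    groups = []
    for i in range(n_sires):
        vals = []
        for j in range(n_prog):
            a = f"P{i}_{j}"
            yv = 5.0 + u[ped.position(a), 0] + rng.normal(0, np.sqrt(1 - h2))
            rows.append({"animal": a, "Y": yv})
            vals.append(yv)
        groups.append(vals)
    ph = pd.DataFrame(rows)
    dm = build_design(ph, ped, ModelSpec(traits=("Y",), class_effects=()))
    f = fit(dm, rel=build_A_inverse(ped))
    h2_reml = f.vc.G[0, 0] / (f.vc.G[0, 0] + f.vc.R[0, 0])

    # closed-form one-way ANOVA oracle
    g = np.array(groups)
    grand = g.mean()
    msb = n_prog * ((g.mean(axis=1) - grand) ** 2).sum() / (n_sires - 1)
    msw = ((g - g.mean(axis=1, keepdims=True)) ** 2).sum() / (n_sires * (n_prog - 1))
    s2s = (msb - msw) / n_prog
    h2_anova = 4 * s2s / (s2s + msw)
    t = s2s / (s2s + msw)
    se_h2 = 4 * np.sqrt(
        2 * (1 - t) ** 2 * (1 + (n_prog - 1) * t) ** 2
        / (n_prog * (n_prog - 1) * (n_sires - 1))
    )
    assert abs(h2_reml - h2_anova) < 2 * se_h2


def test_bivariate_zero_cov_equals_sum_of_univariates(bivariate_data):
    ds, dm, rel = bivariate_data
    both = fit_constrained(dm, rel, "zero-both-cov")
    spec1 = ModelSpec(
        traits=("X",), class_effects=("slaughter_date",), covariates=("slaughter_age",)
    )
    spec2 = ModelSpec(
        traits=("Y",), class_effects=("slaughter_date",), covariates=("slaughter_age",)
    )
    f1 = fit(build_design(ds.phenotypes, ds.pedigree, spec1), rel)
    f2 = fit(build_design(ds.phenotypes, ds.pedigree, spec2), rel)
    assert both.loglik == pytest.approx(f1.loglik + f2.loglik, abs=1e-6)
    np.testing.assert_allclose(
        np.diag(both.vc.G), [f1.vc.G[0, 0], f2.vc.G[0, 0]], rtol=1e-5
    )


def test_constrained_theta_excludes_fixed_parameters(bivariate_data):
    ds, dm, rel = bivariate_data
    red = fit_constrained(dm, rel, "zero-genetic-cov", max_iter=50)
    assert len(red.theta) == 5
    assert red.theta_cov.shape == (5, 5)
    assert red.vc.G[0, 1] == 0.0
    with pytest.raises(ValueError):
        spec = ModelSpec(traits=("X",), class_effects=("slaughter_date",))
        dm1 = build_design(ds.phenotypes, ds.pedigree, spec)
        fit_constrained(dm1, rel, "zero-genetic-cov")


def test_fit_scaling_property(bivariate_data):
    """y -> c y scales variances by c^2, leaves h2 and correlations fixed."""
    ds, dm, rel = bivariate_data
    sub = ds.phenotypes.head(250).copy()
    spec = ModelSpec(traits=("X", "Y"), class_effects=("slaughter_date",))
    f1 = fit(build_design(sub, ds.pedigree, spec), rel)
    c = 3.7
    scaled = sub.copy()
    scaled[["X", "Y"]] = scaled[["X", "Y"]] * c
    f2 = fit(build_design(scaled, ds.pedigree, spec), rel)
    np.testing.assert_allclose(f2.vc.G, c**2 * f1.vc.G, rtol=1e-5)
    np.testing.assert_allclose(f2.vc.R, c**2 * f1.vc.R, rtol=1e-5)


def test_fit_invariant_to_animal_relabelling(bivariate_data):
    ds, dm, rel = bivariate_data
    sub = ds.phenotypes.head(200).copy()
    spec = ModelSpec(traits=("X", "Y"), class_effects=("slaughter_date",))
    f1 = fit(build_design(sub, ds.pedigree, spec), rel)
    # rename every animal; pedigree rebuilt from renamed records
    rename = {a: f"zz_{a}" for a in ds.pedigree.ids}
    recs = [
        (
            rename[ds.pedigree.ids[i]],
            None if ds.pedigree.sire[i] < 0 else rename[ds.pedigree.ids[ds.pedigree.sire[i]]],
            None if ds.pedigree.dam[i] < 0 else rename[ds.pedigree.ids[ds.pedigree.dam[i]]],
        )
        for i in range(ds.pedigree.n)
    ]
    ped2 = Pedigree.from_records(recs)
    sub2 = sub.assign(animal=sub["animal"].map(rename))
    f2 = fit(build_design(sub2, ped2, spec), build_A_inverse(ped2))
    np.testing.assert_allclose(f1.theta, f2.theta, rtol=1e-8)


def test_theta_cov_sane(bivariate_fit):
    d = np.diag(bivariate_fit.theta_cov)
    assert (d >= 0).all()
    corr = bivariate_fit.theta_cov / np.sqrt(np.outer(d, d))
    assert np.abs(corr).max() <= 1 + 1e-8


def test_fit_trace_records_convergence(bivariate_fit):
    assert bivariate_fit.converged
    assert bivariate_fit.trace[-1]["C"] < 1e-12
    assert bivariate_fit.trace[0]["step"] == "start"
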