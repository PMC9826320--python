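import math

import numpy as np
import pandas as pd
import pytest

from urbanvar import effect_sizes as es
from urbanvar import meta_engine as me
from urbanvar.phylo import PhyloCorrelation, correlation_from_newick


# --------------------------------------------------------------------------
# brute-force oracles
# --------------------------------------------------------------------------


def brute_force_V(df, s2_study_by_trait, s2_pop, s2_phy, s2_sp, s2_obs_by_trait, A):
    """Element-by-element covariance assembly from first principles."""
    k = len(df)
    V = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            ri, rj = df.iloc[i], df.iloc[j]
            if ri.study_id == rj.study_id and ri.trait == rj.trait:
                V[i, j] += s2_study_by_trait[ri.trait]
            if ri.population_pair_id == rj.population_pair_id:
                V[i, j] += s2_pop
            si, sj = A.species.index(ri.species), A.species.index(rj.species)
            V[i, j] += s2_phy * A.matrix[si, sj]
            if ri.species == rj.species:
                V[i, j] += s2_sp
            if i == j:
                V[i, j] += s2_obs_by_trait[ri.trait] + ri.vi
    return V


def brute_force_loglik(y, X, V, reml):
    """Direct multivariate-normal evaluation with numpy only."""
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    r = y - X @ beta
    k, p = len(y), X.shape[1]
    ll = -0.5 * (k * math.log(2 * math.pi) + np.linalg.slogdet(V)[1] + r @ Vinv @ r)
    if reml:
        ll += 0.5 * (
            p * math.log(2 * math.pi)
            + np.linalg.slogdet(X.T @ X)[1]
            - np.linalg.slogdet(X.T @ Vinv @ X)[1]
        )
    return ll


TRAITS3 = ("clutch_size", "laying_date", "n_fledglings")


def random_effects_frame(rng, k=8, n_studies=3, n_species=3):
    tree = "(" + ",".join(
        f"Sp{i}" if i < 2 else f"Sp{i}" for i in range(n_species)
    ) + ");"
    A = correlation_from_newick("((Sp0,Sp1),Sp2);")
    df = pd.DataFrame({
        "record_id": [f"r{i}" for i in range(k)],
        "study_id": rng.choice([f"s{i}" for i in range(n_studies)], k),
        "population_pair_id": rng.choice(["p0", "p1", "p2", "p3"], k),
        "species": rng.choice(A.species, k),
        "trait": rng.choice(TRAITS3, k),
        "season": 2000,
        "measure": "lnCVR",
        "yi": rng.normal(0, 0.5, k),
        "vi": rng.uniform(0.01, 0.2, k),
        "effective_n": 50.0,
        "publication_year": 2000,
    })
    return df, A


@pytest.mark.parametrize("reml", [False, True])
def test_loglik_matches_brute_force_over_random_draws(reml):
    """Engine likelihood equals first-principles multivariate-normal
    evaluation with an independently assembled covariance matrix."""
    rng = np.random.default_rng(123)
    spec = me.MetaModelSpec(
        fixed="trait", vcv_structure="diagonal", obs_by_trait=True,
        method="REML" if reml else "ML",
    )
    for _ in range(50):
        df, A = random_effects_frame(rng)
        if df["trait"].nunique() < 3:
            continue
        design = me.build_design(df, spec, A)
        s2_study = dict(zip(design.trait_levels, np.exp(rng.normal(-2, 1, 3))))
        s2_obs = dict(zip(design.trait_levels, np.exp(rng.normal(-2, 1, 3))))
        s2_pop, s2_phy, s2_sp = np.exp(rng.normal(-2, 1, 3))
        theta = np.concatenate([
            [math.log(s2_study[t]) for t in design.trait_levels],
            [math.log(s2_pop), math.log(s2_phy), math.log(s2_sp)],
            [math.log(s2_obs[t]) for t in design.trait_levels],
        ])
        ll = me.loglik(design, theta)
        V = brute_force_V(df, s2_study, s2_pop, s2_phy, s2_sp, s2_obs, A)
        expected = brute_force_loglik(design.y, design.X, V, reml)
        assert ll == pytest.approx(expected, abs=1e-8)


def test_unstructured_block_matches_hand_built_6x6():
    """2 studies x 3 traits: the study-by-trait block of V must equal a
    hand-assembled matrix T[t_i, t_j] * 1[same study]."""
    df = pd.DataFrame({
        "record_id": [f"r{i}" for i in range(6)],
        "study_id": ["s1"] * 3 + ["s2"] * 3,
        "population_pair_id": ["p1"] * 3 + ["p2"] * 3,
        "species": ["A"] * 6,
        "trait": list(TRAITS3) * 2,
        "season": 2000, "measure": "lnCVR",
        "yi": np.arange(6) * 0.1, "vi": np.full(6, 0.05),
        "effective_n": 50.0, "publication_year": 2000,
    })
    spec = me.MetaModelSpec(fixed="trait", vcv_structure="unstructured",
                            obs_by_trait=True,
                            random=("study_trait", "observation"))
    design = me.build_design(df, spec)
    # Cholesky parameters: log-diagonal then row-wise sub-diagonal
    ld = np.array([math.log(0.3), math.log(0.5), math.log(0.4)])
    off = np.array([0.2, -0.1, 0.15])
    obs = np.full(3, -30.0)  # negligible observation variances
    theta = np.concatenate([ld, off, obs])
    L = np.diag(np.exp(ld))
    L[1, 0], L[2, 0], L[2, 1] = off
    T = L @ L.T
    V = design.build_V(theta)
    expected = np.diag(df["vi"]).astype(float)
    for i in range(6):
        for j in range(6):
            if df.study_id[i] == df.study_id[j]:
                ti = design.trait_levels.index(df.trait[i])
                tj = design.trait_levels.index(df.trait[j])
                expected[i, j] += T[ti, tj]
    np.testing.assert_allclose(V, expected, atol=1e-12)


def test_trait_factor_design_matrix():
    rng = np.random.default_rng(0)
    df, A = random_effects_frame(rng, k=12)
    spec = me.MetaModelSpec(fixed="trait", vcv_structure="diagonal", obs_by_trait=True)
    design = me.build_design(df, spec, A)
    assert design.X.shape[1] == df["trait"].nunique()
    np.testing.assert_allclose(design.X.sum(axis=1), 1.0)


def test_missing_species_raises():
    rng = np.random.default_rng(1)
    df, A = random_effects_frame(rng)
    A_small = PhyloCorrelation(A.species[:2], A.matrix[:2, :2])
    spec = me.MetaModelSpec(fixed="intercept")
    with pytest.raises(ValueError, match="species"):
        me.build_design(df, spec, A_small)


# --------------------------------------------------------------------------
# closed-form and limiting cases
# --------------------------------------------------------------------------


def balanced_frame(y, v):
    k = len(y)
    return pd.DataFrame({
        "record_id": [f"r{i}" for i in range(k)],
        "study_id": [f"s{i}" for i in range(k)],
        "population_pair_id": [f"p{i}" for i in range(k)],
        "species": ["A"] * k,
        "trait": ["laying_date"] * k,
        "season": 2000, "measure": "lnCVR",
        "yi": y, "vi": np.full(k, v),
        "effective_n": 50.0, "publication_year": 2000,
    })


def test_reml_matches_balanced_closed_form():
    """Equal vi and a single observation-level component: REML gives
    mu = mean(y) and sigma2 = S^2_y - v (interior case)."""
    rng = np.random.default_rng(2024)
    y = rng.normal(0.3, 0.5, size=40)
    v = 0.02
    df = balanced_frame(y, v)
    spec = me.MetaModelSpec(fixed="intercept", random=("observation",), method="REML")
    fit = me.fit_meta(df, spec, gtol=1e-10)
    s2_expected = float(np.var(y, ddof=1)) - v
    assert fit.coef["intercept"] == pytest.approx(float(y.mean()), abs=1e-6)
    assert fit.variance_components["observation"] == pytest.approx(s2_expected, abs=1e-6)


def test_zero_components_reduce_to_inverse_variance_weighting():
    rng = np.random.default_rng(3)
    k = 25
    y = rng.normal(0.2, 0.3, k)
    df = balanced_frame(y, 0.05)
    df["vi"] = rng.uniform(0.01, 0.3, k)
    spec = me.MetaModelSpec(fixed="intercept", random=("observation",))
    design = me.build_design(df, spec)
    theta = np.array([-60.0])  # variance component forced to ~0
    V = design.build_V(theta)
    _, beta, _, _, _ = me._loglik_parts(design, V, reml=False)
    w = 1.0 / df["vi"].to_numpy()
    assert beta[0] == pytest.approx(float(np.sum(w * y) / np.sum(w)), abs=1e-10)


def test_reml_invariant_to_location_shift():
    rng = np.random.default_rng(9)
    df, A = random_effects_frame(rng, k=30, n_studies=6)
    spec = me.MetaModelSpec(fixed="intercept", vcv_structure="single_var_zero_cov",
                            random=("study_trait", "observation"), method="REML")
    fit1 = me.fit_meta(df, spec)
    df2 = df.copy()
    df2["yi"] = df2["yi"] + 5.0
    fit2 = me.fit_meta(df2, spec)
    assert fit2.coef["intercept"] == pytest.approx(fit1.coef["intercept"] + 5.0, abs=1e-5)
    for name in fit1.variance_components:
        assert fit2.variance_components[name] == pytest.approx(
            fit1.variance_components[name], abs=1e-5)


def test_aic_invariant_to_row_permutation():
    rng = np.random.default_rng(17)
    df, A = random_effects_frame(rng, k=24, n_studies=4)
    spec = me.MetaModelSpec(fixed="intercept", method="ML",
                            random=("study_trait", "observation"))
    fit1 = me.fit_meta(df, spec, A)
    perm = rng.permutation(len(df))
    fit2 = me.fit_meta(df.iloc[perm].reset_index(drop=True), spec, A)
    assert fit2.aic == pytest.approx(fit1.aic, abs=1e-5)


# Fitted values obtained independently with metafor::rma.mv on the frozen
# CSV fixture (random = list(~1|study_id, ~1|obs) and the DIAG trivariate
# variant), used as an end-to-end estimation oracle.
def test_fit_matches_metafor_univariate(datadir=None):
    import pathlib

    path = pathlib.Path(__file__).parent / "data" / "oracle_effects.csv"
    df = pd.read_csv(path)
    df["trait"] = "laying_date"
    df["population_pair_id"] = df["obs"]
    df["species"] = "X"
    df["measure"] = "lnCVR"
    expected = {
        "REML": (0.08648844, 0.07175101, 0.05203557, 0.00595347, -9.10212858),
        "ML": (0.08682368, 0.06856500, 0.04666035, 0.00602975, -9.41066352),
    }
    for method, (b, se, s2s, s2o, ll) in expected.items():
        spec = me.MetaModelSpec(fixed="intercept", method=method,
                                random=("study_trait", "observation"))
        fit = me.fit_meta(df, spec)
        assert fit.coef["intercept"] == pytest.approx(b, abs=2e-6)
        assert fit.se["intercept"] == pytest.approx(se, abs=2e-6)
        assert fit.variance_components["study"] == pytest.approx(s2s, abs=2e-5)
        assert fit.variance_components["observation"] == pytest.approx(s2o, abs=2e-5)
        assert fit.loglik == pytest.approx(ll, abs=1e-5)


def test_fit_matches_metafor_trivariate_diag():
    import pathlib

    path = pathlib.Path(__file__).parent / "data" / "oracle_effects.csv"
    df = pd.read_csv(path)
    df["trait"] = ["laying_date", "clutch_size", "n_fledglings"] * 20
    df["population_pair_id"] = df["obs"]
    df["species"] = "X"
    df["measure"] = "lnCVR"
    spec = me.MetaModelSpec(fixed="trait", vcv_structure="diagonal",
                            obs_by_trait=False, method="REML",
                            random=("study_trait", "observation"))
    fit = me.fit_meta(df, spec)
    assert fit.coef["mu:clutch_size"] == pytest.approx(0.04077711, abs=1e-5)
    assert fit.coef["mu:laying_date"] == pytest.approx(0.05449627, abs=1e-5)
    assert fit.coef["mu:n_fledglings"] == pytest.approx(0.14264628, abs=1e-5)
    assert fit.variance_components["study:clutch_size"] == pytest.approx(0.01956111, abs=2e-5)
    assert fit.variance_components["study:laying_date"] == pytest.approx(0.05603864, abs=2e-5)
    assert fit.loglik == pytest.approx(-14.93707099, abs=1e-5)


# --------------------------------------------------------------------------
# model comparison, heterogeneity, R2
# --------------------------------------------------------------------------


def test_vcv_nesting_and_parameter_counts(small_dataset, small_A):
    records, _ = small_dataset
    eff = es.compute_effects(records, "lnCVR")
    table = me.compare_vcv_structures(eff, small_A)
    assert set(table["structure"]) == set(me.VCV_STRUCTURES)
    counts = dict(zip(table["structure"], table["n_params"]))
    assert counts == me.VCV_N_PARAMS
    lls = dict(zip(table["structure"], table["loglik"]))
    for s in me.VCV_STRUCTURES:
        assert lls["unstructured"] >= lls[s] - 1e-4
    assert table["delta_aic"].min() == 0.0


def test_single_trait_only_single_variance_structure(small_dataset, small_A):
    records, _ = small_dataset
    records = [r for r in records if r.trait == "clutch_size"]
    eff = es.compute_effects(records, "lnCVR")
    table = me.compare_vcv_structures(eff, small_A)
    assert list(table["structure"]) == ["single_var_zero_cov"]


def test_i2_equal_vi_gives_typical_variance_v():
    rng = np.random.default_rng(5)
    df = balanced_frame(rng.normal(0, 0.4, 30), 0.07)
    spec = me.MetaModelSpec(fixed="intercept", random=("observation",))
    fit = me.fit_meta(df, spec)
    dec = me.i2_decomposition(fit)
    assert dec.typical_sampling_variance == pytest.approx(0.07)
    assert 0 <= dec.i2_total <= 100
    assert sum(dec.i2_components.values()) == pytest.approx(dec.i2_total)


def test_i2_zero_components_and_fifty_percent():
    fit = me.MetaFit(
        spec=me.MetaModelSpec(), k=10, coef={}, se={}, ci_low={}, ci_high={},
        variance_components={"observation": 0.0}, correlations={},
        loglik=0.0, aic=0.0, n_theta=1, converged=True,
        _vi=np.full(10, 0.05),
    )
    assert me.i2_decomposition(fit).i2_total == 0.0
    fit.variance_components = {"observation": 0.05}
    assert me.i2_decomposition(fit).i2_total == pytest.approx(50.0)


def test_r2_marginal_limits():
    base = dict(
        spec=me.MetaModelSpec(fixed="trait"), k=10, coef={}, se={},
        ci_low={}, ci_high={}, correlations={}, loglik=0.0, aic=0.0,
        n_theta=1, converged=True, _vi=np.full(4, 0.05),
    )
    flat = me.MetaFit(**base, variance_components={"observation": 0.3},
                      )
    flat._fitted = np.zeros(4)
    assert me.r2_marginal(flat) == 0.0
    perfect = me.MetaFit(**base, variance_components={"observation": 0.0})
    perfect._fitted = np.array([0.0, 1.0, 0.0, 1.0])
    assert me.r2_marginal(perfect) == pytest.approx(100.0)
    intercept_only = me.MetaFit(**{**base, "spec": me.MetaModelSpec(fixed="intercept")},
                                variance_components={})
    intercept_only._fitted = None
    with pytest.raises(ValueError):
        me.r2_marginal(intercept_only)


def test_wald_ci():
    lo, hi = me.wald_ci(0.0, 1.0)
    assert (round(lo, 2), round(hi, 2)) == (-1.96, 1.96)
    assert me.wald_ci(0.3, 0.0) == (0.3, 0.3)
    lo, hi = me.wald_ci(0.176, 0.0469)
    assert lo == pytest.approx(0.084, abs=5e-3)
    assert hi == pytest.approx(0.268, abs=5e-3)


def test_adjusted_intervals_widen_and_validate(small_dataset, small_A):
    """Kenward-Roger-style intervals must contain the Wald intervals (the
    variance-component uncertainty can only add) and reject structures
    whose covariance is not linear in the components."""
    records, _ = small_dataset
    eff = es.compute_effects(records, "lnCVR")
    spec = me.MetaModelSpec(fixed="trait", vcv_structure="diagonal",
                            obs_by_trait=True, method="REML")
    plain = me.fit_meta(eff, spec, small_A)
    adj = me.fit_meta(eff, spec, small_A, ci_method="adjusted")
    for name in plain.coef:
        assert adj.coef[name] == pytest.approx(plain.coef[name], abs=1e-8)
        assert adj.se[name] >= plain.se[name] * 0.999
        assert adj.ci_high[name] - adj.ci_low[name] >= (
            plain.ci_high[name] - plain.ci_low[name]) * 0.999
    with pytest.raises(ValueError, match="correlation-free"):
        me.fit_meta(eff, me.MetaModelSpec(fixed="trait",
                                          vcv_structure="unstructured",
                                          obs_by_trait=True),
                    small_A, ci_method="adjusted")


# --------------------------------------------------------------------------
# arm-based model
# --------------------------------------------------------------------------


def simulate_arm_rows(rng, n_studies=30, beta1=0.0, beta2=0.0, s2_study=0.01,
                      s2_noise=0.005, n_per_arm=40):
    rows = []
    for s in range(n_studies):
        study = f"s{s}"
        u = rng.normal(0, math.sqrt(s2_study))
        ln_mean_base = rng.normal(2.0, 0.4)
        for habitat in ("urban", "nonurban"):
            ln_mean = ln_mean_base + rng.normal(0, 0.1)
            ln_sd = (
                0.5 + beta2 * ln_mean + beta1 * (habitat == "urban") + u
                + rng.normal(0, math.sqrt(s2_noise))
                + rng.normal(0, math.sqrt(1 / (2 * (n_per_arm - 1))))
            )
            rows.append(es.ArmRow(
                record_id=f"r{s}", study_id=study, population_pair_id=f"p{s}",
                species="A", trait="laying_date", habitat=habitat,
                ln_sd=ln_sd, ln_mean=ln_mean,
                v_ln_sd=1 / (2 * (n_per_arm - 1)), n=n_per_arm,
            ))
    return rows


def test_arm_based_recovers_mean_variance_slope():
    rng = np.random.default_rng(31)
    rows = simulate_arm_rows(rng, n_studies=80, beta2=0.4)
    fit = me.fit_arm_based(rows)
    assert fit.coef["ln_mean"] == pytest.approx(0.4, abs=0.08)


def test_arm_based_recovers_urban_sd_inflation():
    rng = np.random.default_rng(32)
    rows = simulate_arm_rows(rng, n_studies=80, beta1=0.2)
    fit = me.fit_arm_based(rows)
    assert fit.coef["habitat_urban"] == pytest.approx(0.2, abs=0.06)
    assert fit.ci_low["habitat_urban"] > 0


def test_arm_based_null_habitat_effect_ci_coverage():
    rng = np.random.default_rng(33)
    covered = 0
    reps = 20
    for _ in range(reps):
        rows = simulate_arm_rows(rng, n_studies=30)
        fit = me.fit_arm_based(rows)
        if fit.ci_low["habitat_urban"] <= 0 <= fit.ci_high["habitat_urban"]:
            covered += 1
    assert covered >= int(0.9 * reps)


def test_arm_based_input_validation():
    rng = np.random.default_rng(34)
    rows = [r for r in simulate_arm_rows(rng, n_studies=5) if r.habitat == "urban"]
    with pytest.raises(ValueError, match="habitat"):
        me.fit_arm_based(rows)


# --------------------------------------------------------------------------
# publication bias
# --------------------------------------------------------------------------


def test_publication_bias_null_and_injected_asymmetry(small_dataset, small_A):
    records, _ = small_dataset
    eff = es.compute_effects(records, "lnRR")
    out = me.publication_bias_tests(eff, small_A)
    assert set(out) == {"small_study", "decline"}
    for res in out.values():
        assert np.isfinite(res["slope"]) and 0 <= res["r2_marginal"] <= 100
    # inject a strong small-study effect: yi inflated in proportion to the
    # imprecision 1/sqrt(n_eff) of each comparison
    df = es.effects_to_frame(eff)
    df["yi"] = df["yi"] + 5.0 * np.sqrt(1.0 / df["effective_n"])
    biased = me.publication_bias_tests(df, small_A)
    assert biased["small_study"]["slope"] > 0
    assert biased["small_study"]["fit"].ci_low["sqrt_inv_n_eff"] > 0


def test_year_moderator_is_centred(small_dataset, small_A):
    records, _ = small_dataset
    eff = es.effects_to_frame(es.compute_effects(records, "lnRR"))
    year = eff["publication_year"].to_numpy(dtype=float)
    assert abs((year - year.mean()).mean()) < 1e-9
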