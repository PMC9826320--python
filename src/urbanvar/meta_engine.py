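"""Multilevel phylogenetic meta-analytic models, estimated by ML or REML.

The marginal model for a vector of effect sizes y (one row per urban/
non-urban comparison) is

    y ~ Normal(X beta, V(theta)),
    V(theta) = sum_u sigma2_u Z_u G_u Z_u' + D_obs(theta) + diag(vi),

where the random terms u are: study-by-trait deviations with a structured
3x3 among-trait covariance T (five candidate structures, from a single
shared variance up to fully unstructured), population-pair intercepts,
phylogenetic species effects with correlation matrix A from shared ancestry,
non-phylogenetic species intercepts, and observation-level deviations with
either a single variance or one variance per trait. diag(vi) holds the known
sampling variances of the effect sizes.

Estimation maximises the (restricted) log-likelihood over transformed
parameters (log variances; correlations through sigmoid/tanh maps; the
unstructured block through its Cholesky factor, which keeps it positive
semi-definite throughout). Gradients use the standard mixed-model identity
d l / d theta_j = -1/2 [tr(Q dV) - r' V^-1 dV V^-1 r] with Q the REML
projection (or V^-1 under ML) and dV obtained by differencing the cheap
covariance assembly, so each iteration needs a single Cholesky factorisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from urbanvar.effect_sizes import ArmRow, EffectSize, effects_to_frame
from urbanvar.phylo import PhyloCorrelation

Z975 = 1.959963984540054

VCV_STRUCTURES = (
    "single_var_zero_cov",
    "compound_symmetric",
    "heteroscedastic_cs",
    "diagonal",
    "unstructured",
)

#: Free study-by-trait parameters per structure (3 traits).
VCV_N_PARAMS = {
    "single_var_zero_cov": 1,
    "compound_symmetric": 2,
    "heteroscedastic_cs": 4,
    "diagonal": 3,
    "unstructured": 6,
}

RANDOM_TERMS = ("study_trait", "population", "phylogeny", "species", "observation")


@dataclass
class MetaModelSpec:
    """Declarative description of one meta-analytic model.

    ``fixed`` is "intercept" (overall mean), "trait" (one cell mean per
    trait) or "trait+moderators"; ``moderators`` names continuous moderator
    columns added to the fixed part. ``vcv_structure`` constrains the
    study-by-trait covariance block; for single-trait data or intercept-only
    models only "single_var_zero_cov" is meaningful. ``obs_by_trait`` selects
    per-trait observation-level variances (the trivariate models) versus a
    single one (the univariate models).
    """

    measure: str = "lnCVR"
    fixed: str = "trait"
    moderators: tuple[str, ...] = ()
    random: tuple[str, ...] = RANDOM_TERMS
    vcv_structure: str = "single_var_zero_cov"
    obs_by_trait: bool = False
    method: str = "REML"

    def __post_init__(self):
        if self.vcv_structure not in VCV_STRUCTURES:
            raise ValueError(f"unknown vcv structure {self.vcv_structure!r}")
        if self.fixed not in ("intercept", "trait", "trait+moderators"):
            raise ValueError(f"unknown fixed part {self.fixed!r}")
        if self.method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        unknown = set(self.random) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms {sorted(unknown)}")


@dataclass
class MetaFit:
    """A fitted meta-analytic model: coefficients, components, fit statistics."""

    spec: MetaModelSpec
    k: int
    coef: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    variance_components: dict[str, float]
    correlations: dict[str, float]
    loglik: float
    aic: float
    n_theta: int
    converged: bool
    message: str = ""
    fixed_signature: str = ""
    # internals used by downstream statistics
    _vi: np.ndarray | None = None
    _fitted: np.ndarray | None = None
    _theta: np.ndarray | None = None

    @property
    def sigma2_total(self) -> float:
        return float(sum(self.variance_components.values()))

    def to_json(self, path) -> None:
        payload = {
            "measure": self.spec.measure,
            "fixed": self.spec.fixed,
            "moderators": list(self.spec.moderators),
            "vcv_structure": self.spec.vcv_structure,
            "method": self.spec.method,
            "k": self.k,
            "coef": self.coef,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "variance_components": self.variance_components,
            "correlations": self.correlations,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "message": self.message,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class HeterogeneityDecomposition:
    """Total and per-component I2 (%) plus the typical sampling variance."""

    i2_total: float
    i2_components: dict[str, float]
    typical_sampling_variance: float


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald (normal-theory) confidence interval, estimate +/- z * se."""
    if se < 0:
        raise ValueError("se must be non-negative")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


# --------------------------------------------------------------------------
# design assembly
# --------------------------------------------------------------------------


def _codes(values) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(values)
    return cats.codes.astype(np.int64), list(cats.categories)


class Design:
    """Numeric design for one model: y, X, vi and random-term index arrays.

    The marginal covariance assembles as
    V = T[trait_i, trait_j] * [same study] + sigma2_v * [same pair]
      + sigma2_a * A[species_i, species_j] + sigma2_h * [same species]
      + diag(sigma2_eps(trait_i)) + diag(vi),
    with each bracket an indicator over row pairs. The index arrays make the
    assembly a handful of vectorised fancy-indexing operations.
    """

    def __init__(self, y, X, vi, trait_idx, n_traits, masks, A_expanded,
                 coef_names, spec):
        self.y = y
        self.X = X
        self.vi = vi
        self.trait_idx = trait_idx
        self.n_traits = n_traits
        self.masks = masks  # dict name -> k x k bool array (or None)
        self.A_expanded = A_expanded
        self.coef_names = coef_names
        self.spec = spec
        self.k = len(y)
        self.p = X.shape[1]
        self._layout = self._parameter_layout()
        self.n_theta = sum(n for _, n in self._layout)

    def _parameter_layout(self):
        layout = []
        s = self.spec
        if "study_trait" in s.random:
            if self.n_traits == 1 or s.vcv_structure == "single_var_zero_cov":
                n = 1
            elif s.vcv_structure == "compound_symmetric":
                n = 2
            elif s.vcv_structure == "heteroscedastic_cs":
                n = self.n_traits + 1
            elif s.vcv_structure == "diagonal":
                n = self.n_traits
            else:  # unstructured: Cholesky factor of the t x t block
                n = self.n_traits * (self.n_traits + 1) // 2
            layout.append(("study_trait", n))
        for name in ("population", "phylogeny", "species"):
            if name in s.random:
                layout.append((name, 1))
        if "observation" in s.random:
            layout.append(("observation", self.n_traits if s.obs_by_trait else 1))
        return layout

    # -- covariance assembly -------------------------------------------------

    def _study_block(self, params: np.ndarray) -> np.ndarray:
        """3x3 (or t x t) among-trait covariance T for the study term."""
        t = self.n_traits
        s = self.spec.vcv_structure
        if t == 1 or s == "single_var_zero_cov":
            return np.exp(params[0]) * np.eye(t)
        if s == "compound_symmetric":
            v = np.exp(params[0])
            rho = _rho_cs(params[1], t)
            return v * ((1 - rho) * np.eye(t) + rho * np.ones((t, t)))
        if s == "heteroscedastic_cs":
            sd = np.exp(0.5 * params[:t])
            rho = _rho_cs(params[t], t)
            T = rho * np.outer(sd, sd)
            np.fill_diagonal(T, sd**2)
            return T
        if s == "diagonal":
            return np.diag(np.exp(params[:t]))
        # unstructured: Cholesky factor, log-diagonal then free sub-diagonal
        L = np.zeros((t, t))
        L[np.diag_indices(t)] = np.exp(params[:t])
        L[np.tril_indices(t, -1)] = params[t:]
        return L @ L.T

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        V = np.diag(self.vi.copy())
        pos = 0
        for name, n in self._layout:
            params = theta[pos:pos + n]
            pos += n
            if name == "study_trait":
                T = self._study_block(params)
                V += T[self.trait_idx[:, None], self.trait_idx[None, :]] * self.masks["study"]
            elif name == "population":
                V += np.exp(params[0]) * self.masks["population"]
            elif name == "phylogeny":
                V += np.exp(params[0]) * self.A_expanded
            elif name == "species":
                V += np.exp(params[0]) * self.masks["species"]
            elif name == "observation":
                if self.spec.obs_by_trait and self.n_traits > 1:
                    V[np.diag_indices(self.k)] += np.exp(params)[self.trait_idx]
                else:
                    V[np.diag_indices(self.k)] += np.exp(params[0])
        return V

    def dV_list(self, theta: np.ndarray) -> list[np.ndarray]:
        """Per-parameter derivatives of V.

        Scalar variance terms are their own derivative on the log scale;
        the study-by-trait block is differentiated on its small t x t
        parameterisation and then expanded, so no full-size assembly is
        ever differenced.
        """
        mats: list[np.ndarray] = []
        pos = 0
        for name, n in self._layout:
            params = theta[pos:pos + n]
            pos += n
            if name == "study_trait":
                h = 1e-6
                for j in range(n):
                    tp = params.copy(); tp[j] += h
                    tm = params.copy(); tm[j] -= h
                    dT = (self._study_block(tp) - self._study_block(tm)) / (2 * h)
                    mats.append(
                        dT[self.trait_idx[:, None], self.trait_idx[None, :]]
                        * self.masks["study"]
                    )
            elif name == "population":
                mats.append(np.exp(params[0]) * self.masks["population"])
            elif name == "phylogeny":
                mats.append(np.exp(params[0]) * self.A_expanded)
            elif name == "species":
                mats.append(np.exp(params[0]) * self.masks["species"])
            elif name == "observation":
                if self.spec.obs_by_trait and self.n_traits > 1:
                    for j in range(n):
                        d = np.zeros((self.k, self.k))
                        idx = np.where(self.trait_idx == j)[0]
                        d[idx, idx] = np.exp(params[j])
                        mats.append(d)
                else:
                    mats.append(np.exp(params[0]) * np.eye(self.k))
        return mats

    def component_variances(self, theta: np.ndarray):
        """Named variance components and correlations at ``theta``."""
        comps: dict[str, float] = {}
        corrs: dict[str, float] = {}
        pos = 0
        for name, n in self._layout:
            params = theta[pos:pos + n]
            pos += n
            if name == "study_trait":
                T = self._study_block(params)
                if self.n_traits == 1:
                    comps["study"] = float(T[0, 0])
                else:
                    for i, tr in enumerate(self.trait_levels):
                        comps[f"study:{tr}"] = float(T[i, i])
                    for i in range(self.n_traits):
                        for j in range(i + 1, self.n_traits):
                            denom = math.sqrt(T[i, i] * T[j, j])
                            corrs[f"study:{self.trait_levels[i]}-{self.trait_levels[j]}"] = (
                                float(T[i, j] / denom) if denom > 0 else 0.0
                            )
            elif name in ("population", "phylogeny", "species"):
                comps[name] = float(np.exp(params[0]))
            elif name == "observation":
                if self.spec.obs_by_trait and self.n_traits > 1:
                    for i, tr in enumerate(self.trait_levels):
                        comps[f"observation:{tr}"] = float(np.exp(params[i]))
                else:
                    comps["observation"] = float(np.exp(params[0]))
        return comps, corrs


def _rho_cs(z: float, t: int) -> float:
    """Map an unconstrained scalar to a valid compound-symmetry correlation.

    A t x t CS correlation matrix is positive semi-definite iff
    rho in (-1/(t-1), 1); the logistic map covers exactly that interval.
    """
    lo = -1.0 / (t - 1)
    return lo + (1.0 - lo) / (1.0 + math.exp(-z))


def build_design(
    effects: Sequence[EffectSize] | pd.DataFrame,
    spec: MetaModelSpec,
    A: PhyloCorrelation | None = None,
    moderator_data: pd.DataFrame | None = None,
) -> Design:
    """Assemble the numeric design (y, X, vi, random-effect structures)."""
    df = effects if isinstance(effects, pd.DataFrame) else effects_to_frame(effects)
    df = df.reset_index(drop=True)
    if moderator_data is not None:
        df = df.join(moderator_data.reset_index(drop=True))
    y = df["yi"].to_numpy(dtype=float)
    vi = df["vi"].to_numpy(dtype=float)
    if np.any(vi <= 0):
        raise ValueError("all sampling variances must be positive")
    trait_idx, trait_levels = _codes(df["trait"])
    n_traits = len(trait_levels)
    if spec.vcv_structure == "unstructured" and n_traits < 2:
        raise ValueError("unstructured VCV requires at least 2 traits present")

    # fixed part
    if spec.fixed == "intercept":
        X = np.ones((len(df), 1))
        coef_names = ["intercept"]
    else:
        X = np.zeros((len(df), n_traits))
        X[np.arange(len(df)), trait_idx] = 1.0
        coef_names = [f"mu:{t}" for t in trait_levels]
        if spec.fixed == "trait+moderators":
            for m in spec.moderators:
                col = df[m].to_numpy(dtype=float)
                if np.ptp(col) == 0:
                    raise ValueError(f"moderator {m!r} is constant")
                X = np.column_stack([X, col])
                coef_names.append(m)
    if spec.fixed == "intercept" and spec.moderators:
        for m in spec.moderators:
            col = df[m].to_numpy(dtype=float)
            if np.ptp(col) == 0:
                raise ValueError(f"moderator {m!r} is constant")
            X = np.column_stack([X, col])
            coef_names.append(m)

    masks = {}
    study_idx, _ = _codes(df["study_id"])
    pop_idx, _ = _codes(df["population_pair_id"])
    sp_idx, sp_levels = _codes(df["species"])
    masks["study"] = (study_idx[:, None] == study_idx[None, :]).astype(float)
    masks["population"] = (pop_idx[:, None] == pop_idx[None, :]).astype(float)
    masks["species"] = (sp_idx[:, None] == sp_idx[None, :]).astype(float)

    A_expanded = None
    if "phylogeny" in spec.random:
        if A is None:
            raise ValueError("phylogeny random term requires a PhyloCorrelation")
        missing = [s for s in sp_levels if s not in A.species]
        if missing:
            raise ValueError(f"species missing from correlation matrix: {missing}")
        sub = A.submatrix(list(sp_levels))
        A_expanded = sub.matrix[sp_idx[:, None], sp_idx[None, :]]

    design = Design(y, X, vi, trait_idx, n_traits, masks, A_expanded,
                    coef_names, spec)
    design.trait_levels = [str(t) for t in trait_levels]
    design.n_levels = {
        "study": int(study_idx.max()) + 1,
        "population": int(pop_idx.max()) + 1,
        "species": int(sp_idx.max()) + 1,
    }
    return design


# --------------------------------------------------------------------------
# likelihood and fitting
# --------------------------------------------------------------------------

_LOG2PI = math.log(2.0 * math.pi)


def _loglik_parts(design: Design, V: np.ndarray, reml: bool):
    """Return (loglik, beta, XtViX_inv, Vinv_r, cho) for a given V."""
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ViX = linalg.cho_solve(cho, design.X, check_finite=False)
    Viy = linalg.cho_solve(cho, design.y, check_finite=False)
    XtViX = design.X.T @ ViX
    beta = np.linalg.solve(XtViX, design.X.T @ Viy)
    r = design.y - design.X @ beta
    Vir = linalg.cho_solve(cho, r, check_finite=False)
    quad = float(r @ Vir)
    k, p = design.k, design.p
    if reml:
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        # + 0.5 log|X'X| makes the restricted likelihood invariant to
        # linear reparameterisation of X (the usual reporting convention)
        ll = -0.5 * (
            (k - p) * _LOG2PI + logdetV + logdetX + quad
            - np.linalg.slogdet(design.X.T @ design.X)[1]
        )
    else:
        ll = -0.5 * (k * _LOG2PI + logdetV + quad)
    return ll, beta, np.linalg.inv(XtViX), Vir, cho


def loglik(design: Design, theta: np.ndarray, method: str | None = None) -> float:
    """(Restricted) log-likelihood at transformed parameters ``theta``."""
    reml = (method or design.spec.method) == "REML"
    V = design.build_V(np.asarray(theta, dtype=float))
    return _loglik_parts(design, V, reml)[0]


def _neg_ll_and_grad(theta, design: Design, reml: bool, h: float = 1e-5):
    theta = np.asarray(theta, dtype=float)
    V = design.build_V(theta)
    try:
        ll, beta, XtViX_inv, Vir, cho = _loglik_parts(design, V, reml)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    k = design.k
    Vinv = linalg.cho_solve(cho, np.eye(k), check_finite=False)
    if reml:
        ViX = Vinv @ design.X
        Q = Vinv - ViX @ XtViX_inv @ ViX.T
    else:
        Q = Vinv
    grad = np.empty_like(theta)
    if hasattr(design, "dV_list"):
        dVs = design.dV_list(theta)
    else:
        dVs = []
        for j in range(len(theta)):
            tp = theta.copy(); tp[j] += h
            tm = theta.copy(); tm[j] -= h
            dVs.append((design.build_V(tp) - design.build_V(tm)) / (2.0 * h))
    for j, dV in enumerate(dVs):
        grad[j] = -0.5 * (np.sum(Q * dV) - float(Vir @ dV @ Vir))
    return -ll, -grad


def _initial_thetas(design: Design, rng: np.ndarray | None = None):
    """Heuristic start plus dispersed alternates for multi-start."""
    resid_var = max(float(np.var(design.y, ddof=1)) - float(np.mean(design.vi)), 1e-4)
    base = math.log(resid_var / max(len(design._layout), 1))
    starts = []
    theta0 = []
    for name, n in design._layout:
        if name == "study_trait" and design.spec.vcv_structure == "unstructured":
            t = design.n_traits
            theta0.extend([0.5 * base] * t)  # log chol diagonal
            theta0.extend([0.0] * (t * (t - 1) // 2))
        elif name == "study_trait" and design.spec.vcv_structure in (
            "compound_symmetric",
            "heteroscedastic_cs",
        ) and design.n_traits > 1:
            nv = n - 1
            theta0.extend([base] * nv + [0.0])
        else:
            theta0.extend([base] * n)
    starts.append(np.array(theta0))
    rng = np.random.default_rng(0) if rng is None else rng
    for _ in range(4):
        starts.append(starts[0] + rng.uniform(-2.0, 2.0, size=len(theta0)))
    return starts


def _kr_adjusted_cov(
    design: Design, theta: np.ndarray, reml: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Kenward-Roger-style adjusted covariance of the fixed effects,
    with Satterthwaite degrees of freedom per coefficient.

    Adds to the GLS covariance Phi = (X'V^-1X)^-1 the propagation of the
    sampling uncertainty of the variance components:

        Phi_A = Phi + 2 Phi [ sum_ij W_ij (Q_ij - A_i Phi A_j) ] Phi,

    with M_i = dV/dsigma2_i (natural scale, where V is linear in the
    components so second derivatives vanish), A_i = X'V^-1 M_i V^-1 X,
    Q_ij = X'V^-1 M_i V^-1 M_j V^-1 X, and W the inverse of the expected
    information I_ij = tr(P M_i P M_j)/2 of the components.
    """
    V = design.build_V(theta)
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    Vinv = linalg.cho_solve(cho, np.eye(design.k), check_finite=False)
    ViX = Vinv @ design.X
    Phi = np.linalg.inv(design.X.T @ ViX)
    P = Vinv - ViX @ Phi @ ViX.T if reml else Vinv
    # natural-scale derivative matrices; on the log scale dV/dgamma = s2*M
    Ms = [dV / math.exp(t) for dV, t in zip(design.dV_list(theta), theta)]
    m = len(Ms)
    PM = [P @ M for M in Ms]
    info = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            info[i, j] = info[j, i] = 0.5 * np.sum(PM[i] * PM[j].T)
    W = np.linalg.pinv(info)
    C = [M @ ViX for M in Ms]           # k x p each
    A = [ViX.T @ Ci for Ci in C]        # p x p
    B = [Vinv @ Ci for Ci in C]         # k x p
    Lam = np.zeros_like(Phi)
    for i in range(m):
        for j in range(m):
            Qij = ViX.T @ (Ms[i] @ B[j])
            Lam += W[i, j] * (Qij - A[i] @ Phi @ A[j])
    Phi_A = Phi + 2.0 * Phi @ Lam @ Phi
    # Satterthwaite df per coefficient: dPhi/dsigma2_i = -Phi A_i Phi, so
    # var(Phi_jj) ~= sum_ab W_ab v_a[j] v_b[j] and df_j = 2 Phi_A[j,j]^2 / var
    p = Phi.shape[0]
    dPhi = np.stack([-(Phi @ Ai @ Phi).diagonal() for Ai in A])  # m x p
    var_phi = np.einsum("ab,aj,bj->j", W, dPhi, dPhi)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * np.diag(Phi_A) ** 2 / var_phi
    df = np.clip(np.nan_to_num(df, nan=design.k - p, posinf=design.k - p),
                 3.0, design.k - p)
    return Phi_A, df


def fit_meta(
    effects: Sequence[EffectSize] | pd.DataFrame,
    spec: MetaModelSpec,
    A: PhyloCorrelation | None = None,
    moderator_data: pd.DataFrame | None = None,
    max_starts: int = 5,
    gtol: float = 1e-6,
    theta0: np.ndarray | None = None,
    ci_method: str = "z",
) -> MetaFit:
    """Fit a multilevel meta-analytic model by ML or REML.

    Optimisation is L-BFGS on transformed parameters with semi-analytic
    gradients; up to ``max_starts`` dispersed starting points (preceded by
    ``theta0`` when given, e.g. a warm start from a nested model) are tried
    before a fit is flagged as non-converged (never silently).

    ``ci_method`` selects the confidence intervals: "z" (Wald normal, the
    convention of the published symmetric intervals); "t-contain"
    (t quantiles with containment degrees of freedom, the number of levels
    of the coarsest grouping factor minus the fixed-effect count); or
    "adjusted" (Kenward-Roger-style covariance inflation that propagates
    the sampling uncertainty of the variance components, plus containment
    t quantiles — the appropriate choice when weakly identified components
    such as the phylogenetic variance make plain Wald intervals run
    narrow; available for correlation-free covariance structures).
    """
    design = build_design(effects, spec, A, moderator_data)
    if design.k <= design.p:
        raise ValueError(
            f"k = {design.k} effect sizes cannot identify {design.p} fixed effects"
        )
    reml = spec.method == "REML"
    starts = _initial_thetas(design)
    if theta0 is not None:
        starts = [np.asarray(theta0, dtype=float)] + starts
    best = None
    converged = False
    message = ""
    for theta0 in starts[:max_starts]:
        res = optimize.minimize(
            _neg_ll_and_grad,
            theta0,
            args=(design, reml),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-30.0, 10.0)] * len(theta0),  # keeps exp() finite
            options={"maxiter": 500, "gtol": gtol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            converged = True
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("meta-analytic fit failed at every starting point")
    if not converged:
        message = f"optimizer did not report convergence: {best.message}"
    theta = best.x
    V = design.build_V(theta)
    ll, beta, XtViX_inv, _, _ = _loglik_parts(design, V, reml)
    se = np.sqrt(np.diag(XtViX_inv))
    comps, corrs = design.component_variances(theta)
    n_theta = design.n_theta
    aic = -2.0 * ll + 2.0 * (n_theta + (design.p if not reml else 0))
    sat_df = None
    if ci_method == "adjusted":
        if spec.vcv_structure not in ("single_var_zero_cov", "diagonal"):
            raise ValueError(
                "adjusted covariance requires a correlation-free structure"
            )
        Phi_A, sat_df = _kr_adjusted_cov(design, theta, reml)
        se = np.sqrt(np.diag(Phi_A))
    coef = dict(zip(design.coef_names, beta))
    se_d = dict(zip(design.coef_names, se))
    if ci_method == "adjusted":
        from scipy.stats import t as t_dist

        crit = t_dist.ppf(0.975, sat_df)
        ci = {
            n: (coef[n] - c * se_d[n], coef[n] + c * se_d[n])
            for n, c in zip(design.coef_names, crit)
        }
    elif ci_method == "t-contain":
        from scipy.stats import t as t_dist

        levels = []
        if "study_trait" in spec.random:
            levels.append(design.n_levels["study"])
        if "population" in spec.random:
            levels.append(design.n_levels["population"])
        if "species" in spec.random or "phylogeny" in spec.random:
            levels.append(design.n_levels["species"])
        if not levels:
            levels = [design.k]
        df = max(min(levels) - design.p, 3)
        crit = float(t_dist.ppf(0.975, df))
        ci = {n: (coef[n] - crit * se_d[n], coef[n] + crit * se_d[n]) for n in coef}
    elif ci_method == "z":
        ci = {name: wald_ci(coef[name], se_d[name]) for name in coef}
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    fit = MetaFit(
        spec=spec,
        k=design.k,
        coef={k_: float(v) for k_, v in coef.items()},
        se={k_: float(v) for k_, v in se_d.items()},
        ci_low={k_: float(v[0]) for k_, v in ci.items()},
        ci_high={k_: float(v[1]) for k_, v in ci.items()},
        variance_components=comps,
        correlations=corrs,
        loglik=float(ll),
        aic=float(aic),
        n_theta=n_theta,
        converged=converged,
        message=message,
        fixed_signature=f"{spec.fixed}|{','.join(spec.moderators)}",
        _vi=design.vi,
        _fitted=design.X @ beta,
        _theta=theta,
    )
    return fit


def compare_vcv_structures(
    effects: Sequence[EffectSize] | pd.DataFrame,
    A: PhyloCorrelation | None = None,
    random: tuple[str, ...] = RANDOM_TERMS,
    measure: str = "lnCVR",
) -> pd.DataFrame:
    """Fit all five study-by-trait covariance structures by ML; rank by AIC.

    Returns a table with structure, free study-block parameter count,
    log-likelihood, AIC and delta AIC. Ties in AIC (below 1e-6) are broken
    toward the structure with fewer parameters. Single-trait data only
    admits the single-variance structure.
    """
    df = effects if isinstance(effects, pd.DataFrame) else effects_to_frame(effects)
    n_traits = df["trait"].nunique()
    structures = VCV_STRUCTURES if n_traits > 1 else ("single_var_zero_cov",)
    rows = []
    warm: dict[str, np.ndarray] = {}
    if n_traits > 1:
        # fit the diagonal structure first and warm-start the others from
        # it (they are all reachable from a diagonal study block), which
        # protects the nested-likelihood ordering from local optima
        diag_spec = MetaModelSpec(
            measure=measure, fixed="trait", random=random,
            vcv_structure="diagonal", obs_by_trait=True, method="ML",
        )
        diag_fit = fit_meta(df, diag_spec, A)
        th = diag_fit._theta
        t = n_traits
        logs2, rest = th[:t], th[t:]
        z0 = -math.log(t - 1)  # maps to rho = 0 under the CS transform
        warm = {
            "diagonal": th,
            "single_var_zero_cov": np.concatenate([[np.mean(logs2)], rest]),
            "compound_symmetric": np.concatenate([[np.mean(logs2)], [z0], rest]),
            "heteroscedastic_cs": np.concatenate([logs2, [z0], rest]),
            "unstructured": np.concatenate(
                [0.5 * logs2, np.zeros(t * (t - 1) // 2), rest]),
        }
    for s in structures:
        spec = MetaModelSpec(
            measure=measure, fixed="trait", random=random,
            vcv_structure=s, obs_by_trait=True, method="ML",
        )
        fit = fit_meta(df, spec, A, theta0=warm.get(s))
        rows.append(
            {
                "structure": s,
                "n_params": VCV_N_PARAMS[s] if n_traits == 3 else fit.n_theta,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "converged": fit.converged,
            }
        )
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    # deterministic ordering: AIC, then parameter count for near-ties
    out = out.sort_values(
        by=["aic", "n_params"], kind="mergesort"
    ).reset_index(drop=True)
    near = out["aic"] - out["aic"].iloc[0] < 1e-6
    if near.sum() > 1:
        tied = out[near].sort_values("n_params", kind="mergesort")
        out = pd.concat([tied, out[~near]]).reset_index(drop=True)
    return out


def i2_decomposition(fit: MetaFit, vi: np.ndarray | None = None) -> HeterogeneityDecomposition:
    """Multilevel I2: share of total variance due to each random component.

    The typical sampling variance is
    sigma2_m = (k - 1) sum(w) / (sum(w)^2 - sum(w^2)), w = 1/vi, and
    I2_u = sigma2_u / (sum_u sigma2_u + sigma2_m) in percent.
    """
    vi = fit._vi if vi is None else np.asarray(vi, dtype=float)
    if vi is None or len(vi) < 2:
        raise ValueError("need at least 2 sampling variances")
    w = 1.0 / vi
    k = len(vi)
    s2m = (k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
    total = fit.sigma2_total
    denom = total + s2m
    comps = {
        name: 100.0 * v / denom for name, v in fit.variance_components.items()
    }
    return HeterogeneityDecomposition(
        i2_total=100.0 * total / denom,
        i2_components=comps,
        typical_sampling_variance=float(s2m),
    )


def r2_marginal(fit: MetaFit) -> float:
    """Marginal R2 (%): variance of fixed-effect predictions over fixed + random."""
    if fit._fitted is None or fit.spec.fixed == "intercept" and not fit.spec.moderators:
        raise ValueError("marginal R2 requires at least one non-intercept fixed term")
    vf = float(np.var(fit._fitted, ddof=0))
    return 100.0 * vf / (vf + fit.sigma2_total)


# --------------------------------------------------------------------------
# arm-based lnSD model
# --------------------------------------------------------------------------


def fit_arm_based(
    rows: Sequence[ArmRow],
    A: PhyloCorrelation | None = None,
    method: str = "REML",
) -> MetaFit:
    """Arm-based model of log phenotypic SD for a single trait.

    ln_sd ~ beta0 + beta1 * [urban] + beta2 * (ln_mean - mean(ln_mean)),
    with random population, phylogeny and species intercepts plus a
    study-level effect term whose entries within a study share an estimated
    correlation (compound symmetry within study), and known sampling
    variances 1/(2(n-1)). beta1 is the habitat effect on lnSD; beta2 the
    mean-variance (Taylor's-law) slope.
    """
    df = pd.DataFrame([asdict(r) for r in rows])
    if df["trait"].nunique() != 1:
        raise ValueError("arm-based model is fitted per trait")
    if df["habitat"].nunique() < 2:
        raise ValueError("both habitats must be represented")
    if df["study_id"].nunique() < 2:
        raise ValueError("need at least 2 studies")
    y = df["ln_sd"].to_numpy(dtype=float)
    vi = df["v_ln_sd"].to_numpy(dtype=float)
    urban = (df["habitat"] == "urban").to_numpy(dtype=float)
    ln_mean = df["ln_mean"].to_numpy(dtype=float)
    ln_mean_c = ln_mean - ln_mean.mean()
    X = np.column_stack([np.ones(len(df)), urban, ln_mean_c])
    coef_names = ["intercept", "habitat_urban", "ln_mean"]

    study_idx, _ = _codes(df["study_id"])
    pop_idx, _ = _codes(df["population_pair_id"])
    sp_idx, sp_levels = _codes(df["species"])
    same_study = (study_idx[:, None] == study_idx[None, :]).astype(float)
    masks = {
        "study": same_study,
        "population": (pop_idx[:, None] == pop_idx[None, :]).astype(float),
        "species": (sp_idx[:, None] == sp_idx[None, :]).astype(float),
    }
    A_expanded = None
    random = ["population", "species", "observation"]
    if A is not None:
        missing = [s for s in sp_levels if s not in A.species]
        if missing:
            raise ValueError(f"species missing from correlation matrix: {missing}")
        sub = A.submatrix(list(sp_levels))
        A_expanded = sub.matrix[sp_idx[:, None], sp_idx[None, :]]
        random.append("phylogeny")

    spec = MetaModelSpec(
        measure="lnSD", fixed="trait", random=tuple(random),
        vcv_structure="single_var_zero_cov", method=method,
    )
    design = Design(y, X, vi, np.zeros(len(df), dtype=np.int64), 1, masks,
                    A_expanded, coef_names, spec)
    design.trait_levels = [str(df["trait"].iloc[0])]

    # replace the scalar study term with a within-study CS effect-size term
    eye_k = np.eye(len(df))
    off = same_study - eye_k

    def build_V(theta, _d=design, _off=off, _eye=eye_k):
        V = np.diag(_d.vi.copy())
        s2_tau = math.exp(theta[0])
        rho = math.tanh(theta[1])
        V += s2_tau * (_eye + rho * _off)
        pos = 2
        V += math.exp(theta[pos]) * _d.masks["population"]; pos += 1
        V += math.exp(theta[pos]) * _d.masks["species"]; pos += 1
        if _d.A_expanded is not None:
            V += math.exp(theta[pos]) * _d.A_expanded; pos += 1
        V[np.diag_indices(_d.k)] += math.exp(theta[pos])
        return V

    design.build_V = build_V

    def dV_list(theta, _d=design, _off=off, _eye=eye_k):
        s2_tau = math.exp(theta[0])
        rho = math.tanh(theta[1])
        mats = [s2_tau * (_eye + rho * _off),
                s2_tau * (1.0 - rho**2) * _off,
                math.exp(theta[2]) * _d.masks["population"],
                math.exp(theta[3]) * _d.masks["species"]]
        pos = 4
        if _d.A_expanded is not None:
            mats.append(math.exp(theta[4]) * _d.A_expanded)
            pos = 5
        mats.append(math.exp(theta[pos]) * _eye)
        return mats

    design.dV_list = dV_list
    n_extra = 1 if A_expanded is not None else 0
    design.n_theta = 4 + n_extra

    def component_variances(theta):
        comps = {
            "study_effect": math.exp(theta[0]),
            "population": math.exp(theta[2]),
            "species": math.exp(theta[3]),
        }
        pos = 4
        if A_expanded is not None:
            comps["phylogeny"] = math.exp(theta[4]); pos = 5
        comps["observation"] = math.exp(theta[pos])
        return comps, {"within_study": math.tanh(theta[1])}

    design.component_variances = component_variances

    reml = method == "REML"
    resid = max(float(np.var(y, ddof=1)) - float(np.mean(vi)), 1e-3)
    base = math.log(resid / (4 + n_extra))
    theta0 = np.array([base, 0.5] + [base] * (2 + n_extra) + [base])
    best = None
    for attempt in range(5):
        start = theta0 if attempt == 0 else theta0 + np.random.default_rng(attempt).uniform(-2, 2, len(theta0))
        res = optimize.minimize(
            _neg_ll_and_grad, start, args=(design, reml), jac=True,
            method="L-BFGS-B", bounds=[(-30.0, 10.0)] * len(theta0),
            options={"maxiter": 500, "gtol": 1e-6, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    theta = best.x
    V = design.build_V(theta)
    ll, beta, XtViX_inv, _, _ = _loglik_parts(design, V, reml)
    se = np.sqrt(np.diag(XtViX_inv))
    comps, corrs = design.component_variances(theta)
    coef = dict(zip(coef_names, map(float, beta)))
    se_d = dict(zip(coef_names, map(float, se)))
    ci = {n: wald_ci(coef[n], se_d[n]) for n in coef}
    return MetaFit(
        spec=spec,
        k=len(df),
        coef=coef,
        se=se_d,
        ci_low={n: v[0] for n, v in ci.items()},
        ci_high={n: v[1] for n, v in ci.items()},
        variance_components=comps,
        correlations=corrs,
        loglik=float(ll),
        aic=float(-2 * ll + 2 * (design.n_theta + (0 if reml else X.shape[1]))),
        n_theta=design.n_theta,
        converged=bool(best.success),
        message="" if best.success else str(best.message),
        fixed_signature="arm",
        _vi=vi,
        _fitted=X @ beta,
    )


# --------------------------------------------------------------------------
# publication bias
# --------------------------------------------------------------------------


def publication_bias_tests(
    effects: Sequence[EffectSize] | pd.DataFrame,
    A: PhyloCorrelation | None = None,
    method: str = "REML",
) -> dict:
    """Small-study and decline-effect meta-regressions.

    Fits two uni-moderator multilevel models: one with the square root of
    the inverse effective sample size (small-study / funnel asymmetry), one
    with the mean-centred publication year (decline effect). Returns both
    fits with their marginal R2.
    """
    df = effects if isinstance(effects, pd.DataFrame) else effects_to_frame(effects)
    df = df.reset_index(drop=True).copy()
    df["sqrt_inv_n_eff"] = np.sqrt(1.0 / df["effective_n"].to_numpy(dtype=float))
    year = df["publication_year"].to_numpy(dtype=float)
    df["year_centred"] = year - year.mean()
    random = RANDOM_TERMS if A is not None else tuple(
        t for t in RANDOM_TERMS if t != "phylogeny"
    )
    out = {}
    for name, mod in (("small_study", "sqrt_inv_n_eff"), ("decline", "year_centred")):
        if np.ptp(df[mod].to_numpy()) == 0:
            raise ValueError(f"moderator {mod!r} is constant")
        spec = MetaModelSpec(
            measure=str(df["measure"].iloc[0]), fixed="intercept",
            moderators=(mod,), random=random,
            vcv_structure="single_var_zero_cov", obs_by_trait=False,
            method=method,
        )
        fit = fit_meta(df, spec, A)
        out[name] = {
            "fit": fit,
            "slope": fit.coef[mod],
            "ci": (fit.ci_low[mod], fit.ci_high[mod]),
            "r2_marginal": r2_marginal(fit),
        }
    return out


def results_table(fits: dict[str, MetaFit]) -> pd.DataFrame:
    """Render per-trait estimates, one row per model, columns per trait.

    Mirrors the conventional temporal-scale summary layout: each cell shows
    "estimate [low, high]" for that trait's mean effect.
    """
    rows = []
    for label, fit in fits.items():
        row = {"model": label, "k": fit.k}
        for name, est in fit.coef.items():
            if name.startswith("mu:") or name == "intercept":
                trait = name.split(":", 1)[-1]
                row[trait] = (
                    f"{est:.3f} [{fit.ci_low[name]:.3f}, {fit.ci_high[name]:.3f}]"
                )
        rows.append(row)
    return pd.DataFrame(rows)
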