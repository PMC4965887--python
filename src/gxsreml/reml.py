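"""Sex-stratified bivariate variance-component estimation by REML.

The model treats male and female observations of one trait as two
environmental contexts of the same phenotype:

    y = (y_m; y_f) = X beta + g + e

where the additive genetic values g have covariance

    Cov(g_i, g_j) = c_{x z} K[i, j],   c_mm = sg2_m,  c_ff = sg2_f,
                                       c_mf = rho * sqrt(sg2_m * sg2_f)

for individuals i of sex x and j of sex z, K the genomic relationship
matrix, and residuals are independent with sex-specific variances.  Fixed
effects are estimated jointly inside the restricted likelihood (block
per-sex intercepts and covariate columns; the univariate comparator uses a
sex main effect plus sex-by-covariate interactions, which spans the same
mean structure).

Fitting uses average-information (AI) REML with analytic first derivatives
and step-halving, falling back to a derivative-free Nelder–Mead restart on
a transformed (log variance / atanh correlation) scale when the AI updates
stall.  Standard errors come from the inverse AI matrix at the optimum,
with delta-method propagation to heritabilities and the genetic
correlation.

The restricted log-likelihood is reported as

    logLr = -1/2 * ( log|V| + log|X' V^-1 X| + y' P y )

with no additive constant, so only differences between two evaluations on
the same data are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import lapack
from scipy.optimize import minimize

from .grm import Grm
from .simgen import SexedCohort

_VAR_FLOOR_REL = 1e-8  # relative to phenotypic variance


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class VarianceParams:
    """Natural-scale variance parameters for one model variant.

    ``parametrization`` is one of ``free``, ``rho1``, ``equal_h2``,
    ``univariate``.  For ``equal_h2`` the auxiliary fields hold the
    (sigma2_m, sigma2_f, lambda) reparametrization in which genetic
    variances are sigma2_x and residual variances lambda * sigma2_x, so both
    heritabilities equal 1/(1 + lambda) exactly.
    """

    sigma2_g_m: float
    sigma2_g_f: float
    rho: float
    sigma2_e_m: float
    sigma2_e_f: float
    parametrization: str = "free"
    sigma2_m: float | None = None
    sigma2_f: float | None = None
    lambda_: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma2_g_m", "sigma2_g_f", "sigma2_e_m", "sigma2_e_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # rho is allowed slightly outside [-1, 1]: the fitter parametrizes the
        # cross-sex genetic covariance unconstrained (subject to V remaining
        # positive definite), so estimates near a true correlation of 1 can
        # overshoot; clipping them would bias the null mean downwards.
        if not np.isfinite(self.rho):
            raise ValueError("rho must be finite")

    @property
    def gamma(self) -> float:
        """Cross-sex genetic covariance rho * sqrt(sg2_m * sg2_f)."""
        return self.rho * np.sqrt(self.sigma2_g_m * self.sigma2_g_f)

    @property
    def h2_m(self) -> float:
        tot = self.sigma2_g_m + self.sigma2_e_m
        return self.sigma2_g_m / tot if tot > 0 else 0.0

    @property
    def h2_f(self) -> float:
        tot = self.sigma2_g_f + self.sigma2_e_f
        return self.sigma2_g_f / tot if tot > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "sigma2_g_m": self.sigma2_g_m,
            "sigma2_g_f": self.sigma2_g_f,
            "rho": self.rho,
            "sigma2_e_m": self.sigma2_e_m,
            "sigma2_e_f": self.sigma2_e_f,
            "parametrization": self.parametrization,
            "h2_m": self.h2_m,
            "h2_f": self.h2_f,
        }


@dataclass
class RemlFit:
    params: VarianceParams
    beta: np.ndarray
    beta_names: list[str]
    logLr: float
    converged: bool
    iterations: int
    gradient_norm: float
    se: dict[str, float] = field(default_factory=dict)
    param_cov: np.ndarray | None = None
    boundary: bool = False
    n_m: int = 0
    n_f: int = 0

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "beta": {n: float(b) for n, b in zip(self.beta_names, self.beta)},
            "logLr": float(self.logLr),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "gradient_norm": float(self.gradient_norm),
            "se": {k: float(v) for k, v in self.se.items()},
            "boundary": bool(self.boundary),
            "n_m": int(self.n_m),
            "n_f": int(self.n_f),
        }


@dataclass
class GxsResult:
    """One row of the gene-by-sex summary: heritabilities, r_g and LRT P values."""

    h2_m: float
    h2_f: float
    rg: float
    se_h2_m: float
    se_h2_f: float
    se_rg: float
    p_rg: float
    p_h2: float
    fit_free: RemlFit | None = None
    fit_rho1: RemlFit | None = None
    fit_equal_h2: RemlFit | None = None

    def to_dict(self) -> dict:
        return {
            "h2_m": float(self.h2_m),
            "h2_f": float(self.h2_f),
            "rg": float(self.rg),
            "se_h2_m": float(self.se_h2_m),
            "se_h2_f": float(self.se_h2_f),
            "se_rg": float(self.se_rg),
            "p_rg": float(self.p_rg),
            "p_h2": float(self.p_h2),
        }


@dataclass
class RemlOptions:
    max_iter: int = 200
    tol_obj: float = 1e-8
    tol_param: float = 1e-6
    restarts: int = 3
    restart_seed: int = 1234
    verbose: bool = False


class RemlError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# data alignment and design matrices


def design_matrix(
    sex: np.ndarray, covariates, univariate: bool = False, single_sex_ok: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design for a cohort, in the given row order.

    Bivariate structure: per-sex intercepts and per-sex covariate columns
    (block diagonal up to row order).  Univariate structure: intercept, sex
    main effect and sex-by-covariate interactions — the same column space
    and column count.  A single-sex cohort gets a plain intercept plus
    covariates.
    """
    sex = np.asarray(sex)
    n = len(sex)
    male = (sex == 1).astype(float)
    nm, nf = int(male.sum()), int(n - male.sum())
    cols: list[np.ndarray] = []
    names: list[str] = []
    cov_arr = (
        covariates.to_numpy(dtype=float)
        if covariates.shape[1]
        else np.empty((n, 0))
    )
    if nm == 0 or nf == 0:
        if not single_sex_ok:
            raise RemlError("both sexes must be present")
        cols.append(np.ones(n))
        names.append("intercept")
        for j, c in enumerate(covariates.columns):
            cols.append(cov_arr[:, j])
            names.append(str(c))
    elif univariate:
        cols.append(np.ones(n))
        names.append("intercept")
        cols.append(male)
        names.append("sex_m")
        for j, c in enumerate(covariates.columns):
            cols.append(cov_arr[:, j])
            names.append(str(c))
            cols.append(cov_arr[:, j] * male)
            names.append(f"{c}:sex_m")
    else:
        for lab, ind in (("m", male), ("f", 1.0 - male)):
            cols.append(ind)
            names.append(f"intercept_{lab}")
            for j, c in enumerate(covariates.columns):
                cols.append(cov_arr[:, j] * ind)
                names.append(f"{c}_{lab}")
    return np.column_stack(cols), names


class GxsProblem:
    """Aligned data for one REML problem: K, y, X with males ordered first."""

    def __init__(
        self, grm: Grm, cohort: SexedCohort, univariate_design: bool = False
    ) -> None:
        id_to_row = {i: r for r, i in enumerate(grm.ids)}
        try:
            rows = np.array([id_to_row[i] for i in cohort.ids])
        except KeyError as exc:
            raise ValueError(f"cohort ID {exc} absent from GRM") from exc
        order = np.argsort(~cohort.is_male, kind="stable")  # males first
        self.cohort_order = order
        self.ids = cohort.ids[order]
        self.sex = cohort.sex[order]
        self.nm = int(cohort.is_male.sum())
        self.nf = cohort.n - self.nm
        g_rows = rows[order]
        self.K = grm.matrix[np.ix_(g_rows, g_rows)]
        self.y = cohort.y[order]
        cov = cohort.covariates.iloc[order]
        self.X, self.beta_names = design_matrix(self.sex, cov, univariate_design)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise RemlError("fixed-effect design matrix is rank deficient")


# ---------------------------------------------------------------------------
# model variants: theta (natural scale) <-> base coefficients
#
# base coordinates: (c_mm, c_ff, c_mf, e_m, e_f) multiplying
# (K male-male block, K female-female block, K cross blocks, male diag,
#  female diag).


class ModelSpec:
    name: str
    param_names: list[str]

    def coeffs(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        """d(base coeffs)/d(theta), shape (5, p)."""
        raise NotImplementedError

    def project(self, theta: np.ndarray, floor: float) -> np.ndarray:
        raise NotImplementedError

    def init(self, var_m: float, var_f: float) -> np.ndarray:
        raise NotImplementedError

    def to_params(self, theta: np.ndarray) -> VarianceParams:
        raise NotImplementedError

    def to_transformed(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def from_transformed(self, z: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class FreeModel(ModelSpec):
    """Five parameters: sg2_m, sg2_f, gamma (genetic covariance), se2_m, se2_f.

    gamma is unconstrained during optimization (the line search rejects any
    step that makes V indefinite), so the implied genetic correlation may
    land slightly outside [-1, 1] — the behaviour of standard GREML solvers,
    and what keeps the estimator unbiased around a true correlation of 1.
    """

    name = "free"
    param_names = ["sigma2_g_m", "sigma2_g_f", "gamma", "sigma2_e_m", "sigma2_e_f"]

    def coeffs(self, t):
        return np.array([t[0], t[1], t[2], t[3], t[4]])

    def jacobian(self, t):
        return np.eye(5)

    def project(self, t, floor):
        t = t.copy()
        t[[0, 1, 3, 4]] = np.maximum(t[[0, 1, 3, 4]], floor)
        return t

    def init(self, var_m, var_f):
        g = np.array([var_m / 2, var_f / 2])
        return np.array([g[0], g[1], 0.5 * np.sqrt(g[0] * g[1]), var_m / 2, var_f / 2])

    def to_params(self, t):
        rho = t[2] / np.sqrt(t[0] * t[1]) if t[0] > 0 and t[1] > 0 else 0.0
        return VarianceParams(t[0], t[1], float(rho), t[3], t[4], "free")

    def to_transformed(self, t):
        # gamma expressed as a correlation-like ratio, left unbounded
        return np.array(
            [
                np.log(t[0]),
                np.log(t[1]),
                t[2] / np.sqrt(t[0] * t[1]),
                np.log(t[3]),
                np.log(t[4]),
            ]
        )

    def from_transformed(self, z):
        s0, s1 = np.exp(z[0]), np.exp(z[1])
        return np.array([s0, s1, z[2] * np.sqrt(s0 * s1), np.exp(z[3]), np.exp(z[4])])


class Rho1Model(ModelSpec):
    """Four parameters with the genetic correlation pinned at 1."""

    name = "rho1"
    param_names = ["sigma2_g_m", "sigma2_g_f", "sigma2_e_m", "sigma2_e_f"]

    def coeffs(self, t):
        return np.array([t[0], t[1], np.sqrt(t[0] * t[1]), t[2], t[3]])

    def jacobian(self, t):
        j = np.zeros((5, 4))
        j[0, 0] = 1.0
        j[1, 1] = 1.0
        r = np.sqrt(t[0] * t[1])
        if r > 0:
            j[2, 0] = 0.5 * np.sqrt(t[1] / t[0])
            j[2, 1] = 0.5 * np.sqrt(t[0] / t[1])
        j[3, 2] = 1.0
        j[4, 3] = 1.0
        return j

    def project(self, t, floor):
        return np.maximum(t, floor)

    def init(self, var_m, var_f):
        return np.array([var_m / 2, var_f / 2, var_m / 2, var_f / 2])

    def to_params(self, t):
        return VarianceParams(t[0], t[1], 1.0, t[2], t[3], "rho1")

    def to_transformed(self, t):
        return np.log(t)

    def from_transformed(self, z):
        return np.exp(z)


class EqualH2Model(ModelSpec):
    """(sigma2_m, sigma2_f, gamma, lambda): residuals are lambda * genetic.

    Enforces h2_m = h2_f = 1/(1 + lambda) exactly by construction.
    """

    name = "equal_h2"
    param_names = ["sigma2_m", "sigma2_f", "gamma", "lambda"]

    def coeffs(self, t):
        return np.array([t[0], t[1], t[2], t[3] * t[0], t[3] * t[1]])

    def jacobian(self, t):
        j = np.zeros((5, 4))
        j[0, 0] = 1.0
        j[1, 1] = 1.0
        j[2, 2] = 1.0
        j[3, 0] = t[3]
        j[3, 3] = t[0]
        j[4, 1] = t[3]
        j[4, 3] = t[1]
        return j

    def project(self, t, floor):
        t = t.copy()
        t[[0, 1]] = np.maximum(t[[0, 1]], floor)
        t[3] = max(t[3], _VAR_FLOOR_REL)
        return t

    def init(self, var_m, var_f):
        return np.array(
            [var_m / 2, var_f / 2, 0.5 * np.sqrt(var_m * var_f) / 2, 1.0]
        )

    def to_params(self, t):
        rho = t[2] / np.sqrt(t[0] * t[1]) if t[0] > 0 and t[1] > 0 else 0.0
        return VarianceParams(
            t[0],
            t[1],
            float(rho),
            t[3] * t[0],
            t[3] * t[1],
            "equal_h2",
            sigma2_m=t[0],
            sigma2_f=t[1],
            lambda_=t[3],
        )

    def to_transformed(self, t):
        return np.array(
            [np.log(t[0]), np.log(t[1]), t[2] / np.sqrt(t[0] * t[1]), np.log(t[3])]
        )

    def from_transformed(self, z):
        s0, s1 = np.exp(z[0]), np.exp(z[1])
        return np.array([s0, s1, z[2] * np.sqrt(s0 * s1), np.exp(z[3])])


class UnivariateModel(ModelSpec):
    """Sex-agnostic comparator: one genetic and one residual variance."""

    name = "univariate"
    param_names = ["sigma2_g", "sigma2_e"]

    def coeffs(self, t):
        return np.array([t[0], t[0], t[0], t[1], t[1]])

    def jacobian(self, t):
        j = np.zeros((5, 2))
        j[[0, 1, 2], 0] = 1.0
        j[[3, 4], 1] = 1.0
        return j

    def project(self, t, floor):
        return np.maximum(t, floor)

    def init(self, var_m, var_f):
        v = 0.5 * (var_m + var_f)
        return np.array([v / 2, v / 2])

    def to_params(self, t):
        return VarianceParams(t[0], t[0], 1.0, t[1], t[1], "univariate")

    def to_transformed(self, t):
        return np.log(t)

    def from_transformed(self, z):
        return np.exp(z)


MODELS: dict[str, ModelSpec] = {
    m.name: m for m in (FreeModel(), Rho1Model(), EqualH2Model(), UnivariateModel())
}


# ---------------------------------------------------------------------------
# likelihood machinery


def _chol_inverse(v: np.ndarray):
    """Cholesky factor, log-determinant and explicit inverse of a PD matrix."""
    c, info = lapack.dpotrf(v, lower=1)
    if info != 0:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    vi, info = lapack.dpotri(c, lower=1)
    if info != 0:
        return None
    vi = np.tril(vi) + np.tril(vi, -1).T
    return c, logdet, vi


class _Evaluator:
    """Caches the problem pieces and evaluates logLr / gradient / AI matrix."""

    def __init__(self, prob: GxsProblem):
        self.prob = prob
        self.n = len(prob.y)
        self.nm = prob.nm
        self.p = prob.X.shape[1]

    def build_v(self, c: np.ndarray) -> np.ndarray:
        nm = self.nm
        K = self.prob.K
        v = np.empty_like(K)
        v[:nm, :nm] = c[0] * K[:nm, :nm]
        v[nm:, nm:] = c[1] * K[nm:, nm:]
        v[:nm, nm:] = c[2] * K[:nm, nm:]
        v[nm:, :nm] = c[2] * K[nm:, :nm]
        d = v.ravel()[:: self.n + 1]
        d[:nm] += c[3]
        d[nm:] += c[4]
        return v

    def loglik_only(self, c: np.ndarray) -> float | None:
        v = self.build_v(c)
        ch = _chol_inverse(v)
        if ch is None:
            return None
        _, logdet_v, vi = ch
        X, y = self.prob.X, self.prob.y
        vix = vi @ X
        xtvix = X.T @ vix
        sign, logdet_x = np.linalg.slogdet(xtvix)
        if sign <= 0:
            return None
        beta = np.linalg.solve(xtvix, vix.T @ y)
        u = vi @ y - vix @ beta  # P y
        return float(-0.5 * (logdet_v + logdet_x + y @ u))

    def full_state(self, c: np.ndarray):
        """logLr, base-scale gradient (5,), base-scale AI (5x5), beta, Py."""
        v = self.build_v(c)
        ch = _chol_inverse(v)
        if ch is None:
            return None
        _, logdet_v, vi = ch
        X, y, K = self.prob.X, self.prob.y, self.prob.K
        nm = self.nm
        vix = vi @ X
        xtvix = X.T @ vix
        sign, logdet_x = np.linalg.slogdet(xtvix)
        if sign <= 0:
            return None
        xtvix_inv = np.linalg.inv(xtvix)
        beta = xtvix_inv @ (vix.T @ y)
        u = vi @ y - vix @ beta  # u = P y
        ll = float(-0.5 * (logdet_v + logdet_x + y @ u))

        P = vi - vix @ xtvix_inv @ vix.T
        PK = P * K
        tr_base = np.array(
            [
                PK[:nm, :nm].sum(),
                PK[nm:, nm:].sum(),
                2.0 * PK[:nm, nm:].sum(),
                np.trace(P[:nm, :nm]),
                np.trace(P[nm:, nm:]),
            ]
        )
        um, uf = u[:nm], u[nm:]
        k_mm_u = K[:nm, :nm] @ um
        k_ff_u = K[nm:, nm:] @ uf
        k_x_m = K[:nm, nm:] @ uf
        k_x_f = K[nm:, :nm] @ um
        quad_base = np.array(
            [
                um @ k_mm_u,
                uf @ k_ff_u,
                2.0 * (um @ k_x_m),
                um @ um,
                uf @ uf,
            ]
        )
        grad_base = -0.5 * (tr_base - quad_base)

        bu = np.zeros((self.n, 5))
        bu[:nm, 0] = k_mm_u
        bu[nm:, 1] = k_ff_u
        bu[:nm, 2] = k_x_m
        bu[nm:, 2] = k_x_f
        bu[:nm, 3] = um
        bu[nm:, 4] = uf
        ai_base = 0.5 * (bu.T @ (P @ bu))
        return ll, grad_base, ai_base, beta, u


def restricted_loglik(
    params: VarianceParams, grm: Grm, cohort: SexedCohort
) -> float:
    """Restricted log-likelihood of the bivariate model at given parameters.

    Convention: -1/2 (log|V| + log|X'V^-1 X| + y'Py), no additive constant.
    """
    prob = GxsProblem(grm, cohort, univariate_design=False)
    ev = _Evaluator(prob)
    c = np.array(
        [
            params.sigma2_g_m,
            params.sigma2_g_f,
            params.gamma,
            params.sigma2_e_m,
            params.sigma2_e_f,
        ]
    )
    ll = ev.loglik_only(c)
    if ll is None:
        raise RemlError("covariance matrix V (or X'V^-1X) is singular")
    return ll


# ---------------------------------------------------------------------------
# the fitter


def _ai_reml(
    ev: _Evaluator,
    model: ModelSpec,
    theta0: np.ndarray,
    options: RemlOptions,
):
    """AI-REML loop; returns (theta, ll, state, converged, iters, grad_norm)."""
    vary = float(np.var(ev.prob.y))
    floor = max(_VAR_FLOOR_REL * max(vary, 1e-12), 1e-300)
    theta = model.project(theta0.copy(), floor)
    state = ev.full_state(model.coeffs(theta))
    if state is None:
        raise RemlError("initial covariance matrix is singular")
    ll = state[0]
    converged = False
    it = 0
    grad_nat = model.jacobian(theta).T @ state[1]
    for it in range(1, options.max_iter + 1):
        J = model.jacobian(theta)
        grad_nat = J.T @ state[1]
        ai_nat = J.T @ state[2] @ J
        # solve with a small ridge for safety
        p = len(theta)
        ridge = 1e-10 * max(1.0, float(np.trace(ai_nat)) / p)
        try:
            delta = np.linalg.solve(ai_nat + ridge * np.eye(p), grad_nat)
        except np.linalg.LinAlgError:
            delta = grad_nat
        if grad_nat @ delta <= 0:  # not an ascent direction
            delta = grad_nat / max(1.0, np.linalg.norm(grad_nat))
        step = 1.0
        new_theta, new_ll = None, None
        for _ in range(30):
            cand = model.project(theta + step * delta, floor)
            if np.allclose(cand, theta, rtol=1e-14, atol=0.0):
                break  # projection pinned us to the current (boundary) point
            cll = ev.loglik_only(model.coeffs(cand))
            if cll is not None and cll >= ll - 1e-12:
                new_theta, new_ll = cand, cll
                break
            step *= 0.5
        if new_theta is None:
            # no improving step along the AI/gradient direction: numerical
            # optimum (possibly on the constraint boundary) after at least
            # one productive iteration
            converged = it >= 2
            break
        param_change = np.max(
            np.abs(new_theta - theta) / np.maximum(np.abs(theta), 1e-10)
        )
        obj_change = abs(new_ll - ll) / max(1.0, abs(ll))
        theta, ll = new_theta, new_ll
        state = ev.full_state(model.coeffs(theta))
        if state is None:
            raise RemlError("covariance matrix became singular during fitting")
        ll = state[0]
        grad_nat = model.jacobian(theta).T @ state[1]
        if obj_change < options.tol_obj and param_change < options.tol_param:
            converged = True
            break
    return theta, ll, state, converged, it, float(np.linalg.norm(grad_nat))


def _nelder_mead(ev: _Evaluator, model: ModelSpec, theta0: np.ndarray):
    z0 = model.to_transformed(np.maximum(theta0, 1e-10))

    def neg(z):
        ll = ev.loglik_only(model.coeffs(model.from_transformed(z)))
        return np.inf if ll is None else -ll

    res = minimize(
        neg,
        z0,
        method="Nelder-Mead",
        options={"maxiter": 120 * len(z0), "xatol": 1e-8, "fatol": 1e-10},
    )
    return model.from_transformed(res.x)


def _fit(
    grm: Grm,
    cohort: SexedCohort,
    model_name: str,
    init: np.ndarray | None = None,
    options: RemlOptions | None = None,
) -> RemlFit:
    options = options or RemlOptions()
    model = MODELS[model_name]
    prob = GxsProblem(grm, cohort, univariate_design=(model_name == "univariate"))
    ev = _Evaluator(prob)
    if prob.nm > 0 and prob.nf > 0:
        var_m = float(np.var(prob.y[: prob.nm], ddof=1))
        var_f = float(np.var(prob.y[prob.nm :], ddof=1))
    else:
        var_m = var_f = float(np.var(prob.y, ddof=1))
    theta0 = np.asarray(init, float) if init is not None else model.init(var_m, var_f)

    rng = np.random.default_rng(options.restart_seed)
    best = None
    for attempt in range(1 + options.restarts):
        start = theta0 if attempt == 0 else model.project(
            theta0 * np.exp(rng.normal(0, 0.3, size=theta0.shape)),
            _VAR_FLOOR_REL * max(var_m, var_f),
        )
        theta, ll, state, conv, iters, gnorm = _ai_reml(ev, model, start, options)
        if not conv:
            # derivative-free restart from the stalled point
            theta_nm = _nelder_mead(ev, model, theta)
            vary = max(float(np.var(ev.prob.y)), 1e-12)
            theta_nm = model.project(theta_nm, _VAR_FLOOR_REL * vary)
            state_nm = ev.full_state(model.coeffs(theta_nm))
            if state_nm is not None and state_nm[0] >= ll - 1e-9:
                g = model.jacobian(theta_nm).T @ state_nm[1]
                theta, ll, state, gnorm = theta_nm, state_nm[0], state_nm, float(
                    np.linalg.norm(g)
                )
                conv = gnorm < 1e-3 * max(1.0, abs(ll))
        if best is None or ll > best[1] + 1e-9:
            best = (theta, ll, state, conv, iters, gnorm)
        if best[3]:
            break
    theta, ll, state, conv, iters, gnorm = best
    params = model.to_params(theta)

    vary = max(float(np.var(ev.prob.y)), 1e-12)
    floor = _VAR_FLOOR_REL * vary
    # a variance pinned at its floor means that component is effectively zero
    # and ratios involving it (h2, rho) are unreliable
    boundary = bool(
        any(
            v <= 10 * floor
            for v in (
                params.sigma2_g_m,
                params.sigma2_g_f,
                params.sigma2_e_m,
                params.sigma2_e_f,
            )
        )
    )

    se: dict[str, float] = {}
    cov_nat = None
    if conv:
        J = model.jacobian(theta)
        ai_nat = J.T @ state[2] @ J
        try:
            cov_nat = np.linalg.inv(ai_nat)
        except np.linalg.LinAlgError:
            cov_nat = np.linalg.pinv(ai_nat)  # boundary fits can be singular
        se = _delta_se(model, theta, cov_nat)

    fit = RemlFit(
        params=params,
        beta=state[3],
        beta_names=prob.beta_names,
        logLr=ll,
        converged=conv,
        iterations=iters,
        gradient_norm=gnorm,
        se=se,
        param_cov=cov_nat,
        boundary=boundary,
        n_m=prob.nm,
        n_f=prob.nf,
    )
    return fit


def _delta_se(model: ModelSpec, theta: np.ndarray, cov: np.ndarray) -> dict[str, float]:
    """Delta-method SEs for natural parameters, heritabilities and rho."""

    def se_of(grad: np.ndarray) -> float:
        v = float(grad @ cov @ grad)
        return float(np.sqrt(max(v, 0.0)))

    p = len(theta)
    se: dict[str, float] = {}

    def h2_grad(ig: int, ie: int) -> np.ndarray:
        g, e = theta[ig], theta[ie]
        tot2 = (g + e) ** 2
        grad = np.zeros(p)
        grad[ig] = e / tot2
        grad[ie] = -g / tot2
        return grad

    if model.name == "free":
        for i, nm in enumerate(model.param_names):
            g = np.zeros(p)
            g[i] = 1.0
            se[nm] = se_of(g)
        se["h2_m"] = se_of(h2_grad(0, 3))
        se["h2_f"] = se_of(h2_grad(1, 4))
        s0, s1, gam = theta[0], theta[1], theta[2]
        if s0 > 0 and s1 > 0:
            rho = gam / np.sqrt(s0 * s1)
            g = np.zeros(p)
            g[0] = -rho / (2 * s0)
            g[1] = -rho / (2 * s1)
            g[2] = 1.0 / np.sqrt(s0 * s1)
            se["rho"] = se_of(g)
    elif model.name == "rho1":
        for i, nm in enumerate(model.param_names):
            g = np.zeros(p)
            g[i] = 1.0
            se[nm] = se_of(g)
        se["h2_m"] = se_of(h2_grad(0, 2))
        se["h2_f"] = se_of(h2_grad(1, 3))
        se["rho"] = 0.0
    elif model.name == "equal_h2":
        for i, nm in enumerate(model.param_names):
            g = np.zeros(p)
            g[i] = 1.0
            se[nm] = se_of(g)
        lam = theta[3]
        g = np.zeros(p)
        g[3] = -1.0 / (1.0 + lam) ** 2  # h2 = 1/(1+lambda)
        se["h2_m"] = se["h2_f"] = se_of(g)
        s0, s1, gam = theta[0], theta[1], theta[2]
        if s0 > 0 and s1 > 0:
            rho = gam / np.sqrt(s0 * s1)
            g = np.zeros(p)
            g[0] = -rho / (2 * s0)
            g[1] = -rho / (2 * s1)
            g[2] = 1.0 / np.sqrt(s0 * s1)
            se["rho"] = se_of(g)
    elif model.name == "univariate":
        for i, nm in enumerate(model.param_names):
            g = np.zeros(p)
            g[i] = 1.0
            se[nm] = se_of(g)
        se["h2_m"] = se["h2_f"] = se_of(h2_grad(0, 1))
        se["rho"] = 0.0
    return se


def fit_bivariate(
    grm: Grm,
    cohort: SexedCohort,
    init: np.ndarray | None = None,
    options: RemlOptions | None = None,
) -> RemlFit:
    """Unconstrained five-parameter bivariate fit (sg2_m, sg2_f, rho, se2_m, se2_f)."""
    return _fit(grm, cohort, "free", init, options)


def fit_rho1(
    grm: Grm,
    cohort: SexedCohort,
    init: np.ndarray | None = None,
    options: RemlOptions | None = None,
) -> RemlFit:
    """Constrained fit with the cross-sex genetic correlation pinned at 1."""
    return _fit(grm, cohort, "rho1", init, options)


def fit_equal_h2(
    grm: Grm,
    cohort: SexedCohort,
    init: np.ndarray | None = None,
    options: RemlOptions | None = None,
) -> RemlFit:
    """Constrained fit forcing equal heritabilities via the lambda reparametrization."""
    return _fit(grm, cohort, "equal_h2", init, options)


def fit_univariate(
    grm: Grm,
    cohort: SexedCohort,
    init: np.ndarray | None = None,
    options: RemlOptions | None = None,
) -> RemlFit:
    """Sex-agnostic single-trait fit with sex interactions in the fixed effects."""
    return _fit(grm, cohort, "univariate", init, options)


def heritability(fit: RemlFit) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-sex heritability with delta-method SE: ((h2_m, se), (h2_f, se))."""
    return (
        (fit.params.h2_m, fit.se.get("h2_m", np.nan)),
        (fit.params.h2_f, fit.se.get("h2_f", np.nan)),
    )


def lrt(fit_full: RemlFit, fit_constrained: RemlFit) -> float:
    """1-df likelihood-ratio P value for a constrained vs the free fit.

    The statistic 2*(logLr_full - logLr_constrained) is clipped at 0.  The
    rho = 1 null sits on the parameter boundary, so referring the statistic
    to a plain chi-square(1) is conservative; this mirrors common practice.
    """
    if not (fit_full.converged and fit_constrained.converged):
        raise RemlError(
            "LRT requires converged fits "
            f"(full: {fit_full.converged}, constrained: {fit_constrained.converged})"
        )
    stat = max(0.0, 2.0 * (fit_full.logLr - fit_constrained.logLr))
    return float(stats.chi2.sf(stat, df=1))


def gxs_report(
    grm: Grm, cohort: SexedCohort, options: RemlOptions | None = None
) -> GxsResult:
    """Full gene-by-sex analysis for one trait: three fits and both LRTs."""
    free = fit_bivariate(grm, cohort, options=options)
    rho1 = fit_rho1(grm, cohort, options=options)
    eqh2 = fit_equal_h2(grm, cohort, options=options)
    (h2m, se_h2m), (h2f, se_h2f) = heritability(free)
    return GxsResult(
        h2_m=h2m,
        h2_f=h2f,
        rg=free.params.rho,
        se_h2_m=se_h2m,
        se_h2_f=se_h2f,
        se_rg=free.se.get("rho", np.nan),
        p_rg=lrt(free, rho1),
        p_h2=lrt(free, eqh2),
        fit_free=free,
        fit_rho1=rho1,
        fit_equal_h2=eqh2,
    )
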