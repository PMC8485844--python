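"""Monotone logistic generalized additive mixed model for the GRC anchor.

The probability that a patient reports *feeling better* over a follow-up
interval is modelled on the logit scale as a smooth surface in
(change, baseline severity) plus a per-patient random intercept:

    logit P(better) = alpha + g(baseline) + s(change, baseline) + u_patient,
    u_patient ~ Normal(0, sigma_u^2).

The interaction smooth ``s`` is a tensor product of an *integrated* B-spline
margin in the change direction and an ordinary B-spline margin in the
baseline direction.  Integrated B-splines are non-negative and
non-decreasing, and B-splines are non-negative, so constraining all tensor
coefficients to be >= 0 makes the linear predictor non-decreasing in change
at every baseline — the shape constraint the anchor model needs (more
improvement can never lower the modelled probability of feeling better).
``g`` is an unconstrained penalized spline capturing the baseline main
effect.

Random intercepts are integrated out by a Laplace approximation; smoothing
parameters and the random-intercept variance are chosen by maximizing the
Laplace-approximate restricted marginal likelihood (``REML``), or can be
fixed for fast, fully deterministic fits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.special import expit

from ed50mcid.data_model import BETTER, ObservationRecord, ScaleSpec

__all__ = [
    "SmoothSpec",
    "MonotoneBasis",
    "MonotoneSurface",
    "DomainError",
    "ConfigurationError",
    "build_monotone_basis",
    "fit_gamm",
    "predict_probability",
]

_SPLINE_DEGREE = 3


class ConfigurationError(ValueError):
    """Raised for invalid smoother configuration."""


class DomainError(ValueError):
    """Raised when a prediction is requested outside the admissible region."""


@dataclass(frozen=True)
class SmoothSpec:
    """Configuration of the bivariate smooth and its selection.

    Parameters
    ----------
    n_basis_change, n_basis_baseline
        Marginal basis dimensions (>= 4 each; default 8 x 8 — flexible
        enough for a non-linear baseline dependency without overfitting).
    penalty_order
        Order of the difference penalty on spline coefficients (default 2,
        shrinking towards linear behaviour).
    smoothing_selection
        ``"REML"`` (default) selects the two smoothing parameters and the
        random-intercept variance by Laplace-approximate restricted maximum
        likelihood; ``"fixed"`` uses ``lambda_surface``/``lambda_baseline``
        and ``fixed_sigma_u`` as given (deterministic, no outer
        optimization).
    lambda_surface, lambda_baseline
        Penalty weights for the tensor interaction smooth and the baseline
        main-effect smooth.  Used directly in ``fixed`` mode and as the
        starting point for REML.
    fixed_sigma_u
        Random-intercept SD in ``fixed`` mode (0 drops the random effect);
        ignored under REML.
    """

    n_basis_change: int = 8
    n_basis_baseline: int = 8
    penalty_order: int = 2
    smoothing_selection: str = "REML"
    lambda_surface: float = 1.0
    lambda_baseline: float = 1.0
    fixed_sigma_u: float = 0.5

    def __post_init__(self) -> None:
        for name, k in (
            ("n_basis_change", self.n_basis_change),
            ("n_basis_baseline", self.n_basis_baseline),
        ):
            if k < 4:
                raise ConfigurationError(f"{name} must be >= 4, got {k}")
            if k < self.penalty_order + 2:
                raise ConfigurationError(
                    f"{name}={k} too small for penalty order "
                    f"{self.penalty_order} (need >= penalty_order + 2)"
                )
        if self.lambda_surface <= 0 or self.lambda_baseline <= 0:
            raise ConfigurationError("smoothing parameters must be > 0")
        if self.fixed_sigma_u < 0:
            raise ConfigurationError("fixed_sigma_u must be >= 0")
        if self.smoothing_selection not in ("REML", "fixed"):
            raise ConfigurationError(
                "smoothing_selection must be 'REML' or 'fixed' "
                f"(got {self.smoothing_selection!r}; GCV is not implemented)"
            )


def _open_uniform_knots(a: float, b: float, n_basis: int, degree: int) -> np.ndarray:
    """Open-uniform knot vector giving ``n_basis`` B-splines on [a, b]."""
    n_interior = n_basis - degree - 1
    interior = np.linspace(a, b, n_interior + 2)[1:-1]
    return np.concatenate([[a] * (degree + 1), interior, [b] * (degree + 1)])


def _bspline_matrix(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(x, knots, degree).toarray()


def _difference_penalty(k: int, order: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


class MonotoneBasis:
    """Tensor-product basis with a monotone (integrated-spline) change margin.

    The change margin consists of integrated B-splines ``I_j`` (non-negative,
    non-decreasing, zero at the lower end of the change range); the baseline
    margin of ordinary B-splines ``B_k`` (non-negative, partition of unity).
    A linear predictor ``sum_jk beta_jk I_j(c) B_k(b)`` with all
    ``beta_jk >= 0`` is therefore non-decreasing in ``c`` for every ``b``.
    """

    def __init__(self, spec: SmoothSpec, scale: ScaleSpec, degree: int = _SPLINE_DEGREE):
        self.spec = spec
        self.scale = scale
        self.degree = degree
        span = scale.max_score - scale.min_score
        self.change_range = (-float(span), float(span))
        self.baseline_range = (float(scale.min_score), float(scale.max_score))
        self.knots_change = _open_uniform_knots(
            *self.change_range, spec.n_basis_change, degree
        )
        self.knots_baseline = _open_uniform_knots(
            *self.baseline_range, spec.n_basis_baseline, degree
        )
        self._antiderivatives = []
        for j in range(spec.n_basis_change):
            e = np.zeros(spec.n_basis_change)
            e[j] = 1.0
            self._antiderivatives.append(
                BSpline(self.knots_change, e, degree, extrapolate=False).antiderivative()
            )

    @property
    def n_change(self) -> int:
        return self.spec.n_basis_change

    @property
    def n_baseline(self) -> int:
        return self.spec.n_basis_baseline

    @property
    def n_coef(self) -> int:
        """Total fixed-effect coefficients: intercept + baseline margin + tensor."""
        return 1 + self.n_baseline + self.n_change * self.n_baseline

    def change_design(self, change: np.ndarray) -> np.ndarray:
        """Integrated-B-spline design ``I_j(c)``; each column non-decreasing."""
        c = np.clip(np.asarray(change, dtype=float).ravel(), *self.change_range)
        cols = np.empty((c.size, self.n_change))
        for j, anti in enumerate(self._antiderivatives):
            cols[:, j] = anti(c)
        return cols

    def baseline_design(self, baseline: np.ndarray) -> np.ndarray:
        return _bspline_matrix(np.asarray(baseline, dtype=float), self.knots_baseline, self.degree)

    def design(
        self,
        change: np.ndarray,
        baseline: np.ndarray,
        g_center: np.ndarray | None = None,
    ) -> np.ndarray:
        """Full fixed-effect design [1 | centred baseline margin | tensor]."""
        change = np.atleast_1d(np.asarray(change, dtype=float))
        baseline = np.atleast_1d(np.asarray(baseline, dtype=float))
        ic = self.change_design(change)
        bb = self.baseline_design(baseline)
        g = bb if g_center is None else bb - g_center
        tensor = (ic[:, :, None] * bb[:, None, :]).reshape(len(change), -1)
        return np.hstack([np.ones((len(change), 1)), g, tensor])

    def penalty_blocks(self) -> tuple[np.ndarray, np.ndarray]:
        """(baseline-margin penalty, tensor penalty) difference matrices."""
        order = self.spec.penalty_order
        p_g = _difference_penalty(self.n_baseline, order)
        p_c = _difference_penalty(self.n_change, order)
        p_b = _difference_penalty(self.n_baseline, order)
        p_t = np.kron(p_c, np.eye(self.n_baseline)) + np.kron(np.eye(self.n_change), p_b)
        return p_g, p_t

    def full_penalty(self, lambda_surface: float, lambda_baseline: float) -> np.ndarray:
        p_g, p_t = self.penalty_blocks()
        p = self.n_coef
        s = np.zeros((p, p))
        s[1 : 1 + self.n_baseline, 1 : 1 + self.n_baseline] = lambda_baseline * p_g
        s[1 + self.n_baseline :, 1 + self.n_baseline :] = lambda_surface * p_t
        return s

    def monotone_mask(self) -> np.ndarray:
        """Boolean mask of coefficients constrained to be non-negative."""
        mask = np.zeros(self.n_coef, dtype=bool)
        mask[1 + self.n_baseline :] = True
        return mask


def build_monotone_basis(spec: SmoothSpec, scale: ScaleSpec) -> MonotoneBasis:
    """Construct the monotone tensor-product basis for a scale."""
    return MonotoneBasis(spec, scale)


# ---------------------------------------------------------------------------
# fitting


def _solve_joint(
    x_mat: np.ndarray,
    y: np.ndarray,
    patient_idx: np.ndarray | None,
    n_u: int,
    penalty: np.ndarray,
    sigma2: float,
    nonneg_mask: np.ndarray | None,
    z0: np.ndarray | None = None,
    maxiter: int = 200,
    tol: float = 1e-8,
):
    """Minimize the joint penalized Bernoulli negative log-likelihood.

    Coefficient vector is [theta | u]; entries of theta flagged in
    ``nonneg_mask`` are box-constrained to [0, inf).  Uses projected Newton
    with an Armijo backtracking line search: the objective is convex, the
    random-intercept block of the Hessian is diagonal (Schur complement
    keeps each step at the cost of one dense p x p solve), and coefficients
    that the data never touch stay exactly at zero.  Returns a scipy-style
    OptimizeResult.
    """
    p = x_mat.shape[1]
    use_u = n_u > 0 and sigma2 > 0
    n_var = p + (n_u if use_u else 0)
    if nonneg_mask is None:
        nonneg_mask = np.zeros(p, dtype=bool)

    z = np.zeros(n_var) if z0 is None or len(z0) != n_var else z0.copy()
    z[:p][nonneg_mask] = np.maximum(z[:p][nonneg_mask], 0.0)

    def objective(zv):
        theta = zv[:p]
        eta = x_mat @ theta
        if use_u:
            eta = eta + zv[p:][patient_idx]
        val = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
        val += 0.5 * float(theta @ penalty @ theta)
        if use_u:
            val += 0.5 * float(zv[p:] @ zv[p:]) / sigma2
        return val, eta

    f_val, eta = objective(z)
    converged = False
    message = "maximum Newton iterations reached"
    it = 0
    for it in range(1, maxiter + 1):
        theta = z[:p]
        mu = expit(eta)
        r = mu - y
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        g_theta = x_mat.T @ r + penalty @ theta
        if use_u:
            u = z[p:]
            g_u = np.bincount(patient_idx, weights=r, minlength=n_u) + u / sigma2

        # active set: bounded coefficients pinned at 0 with inward gradient
        active = nonneg_mask & (theta <= 1e-12) & (g_theta > 0)
        free = ~active
        # projected-gradient stationarity
        pg = np.abs(np.where(free, g_theta, 0.0)).max()
        if use_u:
            pg = max(pg, np.abs(g_u).max())
        if pg < tol:
            converged = True
            message = "projected gradient below tolerance"
            break

        xf = x_mat[:, free]
        xw = xf * w[:, None]
        a_ff = xf.T @ xw + penalty[np.ix_(free, free)]
        a_ff[np.diag_indices_from(a_ff)] += 1e-10
        rhs_theta = -g_theta[free]
        if use_u:
            b_f = np.zeros((n_u, int(free.sum())))
            np.add.at(b_f, patient_idx, xw)
            d_u = np.bincount(patient_idx, weights=w, minlength=n_u) + 1.0 / sigma2
            schur = a_ff - (b_f / d_u[:, None]).T @ b_f
            rhs = rhs_theta + b_f.T @ (g_u / d_u)
            try:
                d_theta = np.linalg.solve(schur, rhs)
            except np.linalg.LinAlgError:
                schur[np.diag_indices_from(schur)] += 1e-6
                d_theta = np.linalg.solve(schur, rhs)
            d_u_step = -(g_u + b_f @ d_theta) / d_u
        else:
            try:
                d_theta = np.linalg.solve(a_ff, rhs_theta)
            except np.linalg.LinAlgError:
                a_ff[np.diag_indices_from(a_ff)] += 1e-6
                d_theta = np.linalg.solve(a_ff, rhs_theta)

        direction = np.zeros(n_var)
        direction[:p][free] = d_theta
        if use_u:
            direction[p:] = d_u_step

        def line_search(direc, slope):
            step = 1.0
            for _ in range(50):
                z_new = z + step * direc
                z_new[:p][nonneg_mask] = np.maximum(z_new[:p][nonneg_mask], 0.0)
                f_new, eta_new = objective(z_new)
                if f_new <= f_val + 1e-4 * step * slope or f_new < f_val - 1e-12:
                    return z_new, f_new, eta_new
                step *= 0.5
            return None

        slope = float(g_theta[free] @ d_theta)
        if use_u:
            slope += float(g_u @ d_u_step)
        hit = line_search(direction, slope)
        if hit is None:
            # Newton direction can lose its descent property once the
            # projection clips it at the bounds; fall back to the projected
            # gradient, which always descends away from a constrained optimum
            grad_dir = np.zeros(n_var)
            grad_dir[:p] = -np.where(free, g_theta, 0.0)
            if use_u:
                grad_dir[p:] = -g_u
            gnorm2 = float(grad_dir @ grad_dir)
            hit = line_search(grad_dir / max(np.sqrt(gnorm2), 1.0), -np.sqrt(gnorm2))
        if hit is None:
            converged = pg < 1e-4
            message = "line search stalled"
            break
        z_new, f_new, eta_new = hit
        rel_drop = (f_val - f_new) / max(abs(f_val), 1.0)
        z, f_val, eta = z_new, f_new, eta_new
        if rel_drop < 1e-13:
            converged = True
            message = "penalized likelihood stabilized"
            break

    return optimize.OptimizeResult(
        x=z, fun=f_val, success=converged, message=message, nit=it
    )


def _laplace_reml(
    res,
    x_mat: np.ndarray,
    y: np.ndarray,
    patient_idx: np.ndarray | None,
    n_u: int,
    penalty: np.ndarray,
    sigma2: float,
    rank_terms: float,
) -> float:
    """Laplace-approximate restricted log marginal likelihood at the mode.

    ``rank_terms`` carries ``sum(rank_i * log(lambda_i)) / 2`` from the
    penalty pseudo-determinant (its lambda-free part is constant in the
    outer optimization and omitted).  Curvature from active non-negativity
    bounds is ignored, i.e. the Hessian is taken as if all coefficients were
    free — a standard working approximation.
    """
    p = x_mat.shape[1]
    theta = res.x[:p]
    eta = x_mat @ theta
    use_u = n_u > 0 and sigma2 > 0
    if use_u:
        eta = eta + res.x[p:][patient_idx]
    w = expit(eta)
    w = w * (1.0 - w)
    xw = x_mat * w[:, None]
    a = x_mat.T @ xw + penalty
    if use_u:
        w_pat = np.bincount(patient_idx, weights=w, minlength=n_u)
        b = np.zeros((n_u, p))
        np.add.at(b, patient_idx, xw)
        d = w_pat + 1.0 / sigma2
        logdet_h = float(np.sum(np.log(d)))
        schur = a - (b / d[:, None]).T @ b
        logdet_h += float(np.linalg.slogdet(schur)[1])
        sigma_term = -0.5 * n_u * np.log(sigma2)
    else:
        logdet_h = float(np.linalg.slogdet(a)[1])
        sigma_term = 0.0
    return -res.fun + rank_terms - 0.5 * logdet_h + sigma_term


@dataclass
class MonotoneSurface:
    """Fitted population-level probability surface P(better | change, baseline).

    Holds the basis definition (reconstructible from the smoother spec and
    scale), the fitted coefficients under the non-negativity
    parameterization of the monotone margin, smoothing parameters, the
    random-intercept SD, and fit diagnostics.
    """

    scale: ScaleSpec
    spec: SmoothSpec
    intercept: float
    gamma: np.ndarray  # baseline-margin coefficients
    beta: np.ndarray  # (n_change, n_baseline) tensor coefficients, all >= 0
    g_center: np.ndarray  # training-sample column means of the baseline margin
    lambda_surface: float
    lambda_baseline: float
    random_intercept_sd: float
    converged: bool = True
    penalized_loglik: float = float("nan")
    n_obs: int = 0
    n_patients: int = 0
    separation_flag: bool = False
    _basis: MonotoneBasis | None = field(default=None, repr=False, compare=False)

    @property
    def basis(self) -> MonotoneBasis:
        if self._basis is None:
            self._basis = MonotoneBasis(self.spec, self.scale)
        return self._basis

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.gamma, self.beta.ravel()])

    def _check_domain(self, change: np.ndarray, baseline: np.ndarray) -> None:
        lo, hi = self.scale.min_score, self.scale.max_score
        tol = 1e-9
        if np.any(baseline < lo - tol) or np.any(baseline > hi + tol):
            raise DomainError(f"baseline outside scale range [{lo}, {hi}]")
        if np.any(change > baseline + tol) or np.any(change < baseline - hi - tol):
            raise DomainError(
                "change outside the scale-feasible region "
                "[baseline - max_score, baseline]"
            )

    def linear_predictor(self, change, baseline) -> np.ndarray:
        change = np.atleast_1d(np.asarray(change, dtype=float))
        baseline = np.atleast_1d(np.asarray(baseline, dtype=float))
        change, baseline = np.broadcast_arrays(change, baseline)
        x = self.basis.design(change.ravel(), baseline.ravel(), self.g_center)
        return (x @ self.theta).reshape(change.shape)

    def predict(self, change, baseline, mode: str = "population") -> np.ndarray:
        """Predicted probability of feeling better.

        ``mode="population"`` sets the random intercept to zero (median
        patient); ``mode="marginal"`` averages over the random-intercept
        distribution by Gauss-Hermite quadrature.
        """
        scalar = np.ndim(change) == 0 and np.ndim(baseline) == 0
        self._check_domain(
            np.atleast_1d(np.asarray(change, dtype=float)),
            np.atleast_1d(np.asarray(baseline, dtype=float)),
        )
        eta = self.linear_predictor(change, baseline)
        if mode == "population" or self.random_intercept_sd == 0:
            prob = expit(eta)
        elif mode == "marginal":
            nodes, weights = np.polynomial.hermite_e.hermegauss(21)
            u = nodes * self.random_intercept_sd
            w = weights / weights.sum()
            prob = np.tensordot(expit(eta[..., None] + u), w, axes=([-1], [0]))
        else:
            raise ValueError(f"unknown prediction mode {mode!r}")
        return float(prob.ravel()[0]) if scalar else prob

    def check_monotonicity(self, resolution: float = 0.1, tol: float = 1e-8) -> bool:
        """Grid check: non-decreasing probability in change at every integer baseline."""
        lo, hi = self.scale.min_score, self.scale.max_score
        for b in range(lo, hi + 1):
            c = np.arange(b - hi, b + resolution / 2, resolution)
            probs = self.predict(np.minimum(c, b), float(b))
            if np.any(np.diff(probs) < -tol):
                return False
        return True

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "format": "ed50mcid-surface",
            "version": 1,
            "scale": {
                "name": self.scale.name,
                "min_score": self.scale.min_score,
                "max_score": self.scale.max_score,
                "severity_bands": list(map(list, self.scale.severity_bands)),
            },
            "spec": {
                "n_basis_change": self.spec.n_basis_change,
                "n_basis_baseline": self.spec.n_basis_baseline,
                "penalty_order": self.spec.penalty_order,
                "smoothing_selection": self.spec.smoothing_selection,
                "lambda_surface": self.spec.lambda_surface,
                "lambda_baseline": self.spec.lambda_baseline,
                "fixed_sigma_u": self.spec.fixed_sigma_u,
            },
            "intercept": self.intercept,
            "gamma": self.gamma.tolist(),
            "beta": self.beta.tolist(),
            "g_center": self.g_center.tolist(),
            "lambda_surface": self.lambda_surface,
            "lambda_baseline": self.lambda_baseline,
            "random_intercept_sd": self.random_intercept_sd,
            "converged": self.converged,
            "penalized_loglik": self.penalized_loglik,
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "separation_flag": self.separation_flag,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MonotoneSurface":
        d = json.loads(text)
        if d.get("format") != "ed50mcid-surface":
            raise ValueError("not a serialized probability surface")
        scale = ScaleSpec(
            name=d["scale"]["name"],
            min_score=d["scale"]["min_score"],
            max_score=d["scale"]["max_score"],
            severity_bands=tuple((str(l), int(b)) for l, b in d["scale"]["severity_bands"]),
        )
        spec = SmoothSpec(**d["spec"])
        return cls(
            scale=scale,
            spec=spec,
            intercept=float(d["intercept"]),
            gamma=np.asarray(d["gamma"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            g_center=np.asarray(d["g_center"], dtype=float),
            lambda_surface=float(d["lambda_surface"]),
            lambda_baseline=float(d["lambda_baseline"]),
            random_intercept_sd=float(d["random_intercept_sd"]),
            converged=bool(d["converged"]),
            penalized_loglik=float(d["penalized_loglik"]),
            n_obs=int(d["n_obs"]),
            n_patients=int(d["n_patients"]),
            separation_flag=bool(d["separation_flag"]),
        )


def fit_gamm(
    records: Sequence[ObservationRecord],
    spec: SmoothSpec | None = None,
    reml_maxfev: int = 80,
) -> MonotoneSurface:
    """Fit the monotone logistic GAMM to observation intervals.

    The penalized marginal log-likelihood (random intercepts integrated by
    Laplace approximation) is maximized over coefficients; under
    ``smoothing_selection="REML"`` the two smoothing parameters and the
    random-intercept variance are selected by Nelder-Mead on the
    Laplace-approximate restricted marginal likelihood.  Non-convergence is
    flagged on the returned surface, never silent; apparent complete
    separation raises a warning but the penalized fit is still returned.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 observation records to fit")
    scale = records[0].scale
    if any(r.scale != scale for r in records):
        raise ValueError("all records must share one scale")
    y = np.array([1.0 if r.grc_binary == BETTER else 0.0 for r in records])
    if y.min() == y.max():
        raise ValueError("both outcome classes (better / not_better) must be present")
    spec = spec or SmoothSpec()

    basis = build_monotone_basis(spec, scale)
    change = np.array([r.change for r in records], dtype=float)
    baseline = np.array([r.baseline_score for r in records], dtype=float)
    g_center = basis.baseline_design(baseline).mean(axis=0)
    x_mat = basis.design(change, baseline, g_center)

    patients = sorted({r.patient_id for r in records})
    pat_index = {pid: i for i, pid in enumerate(patients)}
    patient_idx = np.array([pat_index[r.patient_id] for r in records])
    n_u = len(patients)

    nonneg = basis.monotone_mask()
    p_g, p_t = basis.penalty_blocks()
    rank_g = np.linalg.matrix_rank(p_g)
    rank_t = np.linalg.matrix_rank(p_t)

    warm: dict[str, np.ndarray | None] = {"z": None}

    def fit_at(lam_s: float, lam_b: float, sigma2: float):
        penalty = basis.full_penalty(lam_s, lam_b)
        res = _solve_joint(
            x_mat, y, patient_idx, n_u, penalty, sigma2, nonneg, z0=warm["z"]
        )
        warm["z"] = res.x
        return res, penalty

    if spec.smoothing_selection == "fixed":
        sigma2 = spec.fixed_sigma_u**2
        res, _ = fit_at(spec.lambda_surface, spec.lambda_baseline, sigma2)
        lam_s, lam_b, sigma_u = spec.lambda_surface, spec.lambda_baseline, spec.fixed_sigma_u
        converged = bool(res.success)
    else:  # REML
        def neg_reml(logs):
            lam_s, lam_b, sigma2 = np.exp(np.clip(logs, -20, 20))
            res, penalty = fit_at(lam_s, lam_b, sigma2)
            rank_terms = 0.5 * (rank_g * np.log(lam_b) + rank_t * np.log(lam_s))
            return -_laplace_reml(
                res, x_mat, y, patient_idx, n_u, penalty, sigma2, rank_terms
            )

        x0 = np.log([spec.lambda_surface, spec.lambda_baseline, spec.fixed_sigma_u**2 or 0.25])
        simplex = np.vstack([x0, x0 + np.diag([1.5, 1.5, 1.0])])
        outer = optimize.minimize(
            neg_reml,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": reml_maxfev,
                "xatol": 0.1,
                "fatol": 0.05,
                "initial_simplex": simplex,
            },
        )
        lam_s, lam_b, sigma2 = np.exp(np.clip(outer.x, -20, 20))
        res, _ = fit_at(lam_s, lam_b, sigma2)
        sigma_u = float(np.sqrt(sigma2))
        converged = bool(res.success)

    theta = res.x[: basis.n_coef]
    eta_hat = x_mat @ theta
    if n_u and sigma2 > 0:
        eta_hat = eta_hat + res.x[basis.n_coef :][patient_idx]
    separation = bool(np.max(np.abs(eta_hat)) > 25)
    if separation:
        warnings.warn(
            "fitted linear predictor is extreme; data may be (quasi-)separated — "
            "returning the penalized fit",
            RuntimeWarning,
            stacklevel=2,
        )
    if not converged:
        warnings.warn(
            f"inner optimizer did not report convergence: {res.message}",
            RuntimeWarning,
            stacklevel=2,
        )

    surface = MonotoneSurface(
        scale=scale,
        spec=spec,
        intercept=float(theta[0]),
        gamma=theta[1 : 1 + basis.n_baseline].copy(),
        beta=theta[1 + basis.n_baseline :].reshape(basis.n_change, basis.n_baseline).copy(),
        g_center=g_center,
        lambda_surface=float(lam_s),
        lambda_baseline=float(lam_b),
        random_intercept_sd=float(sigma_u),
        converged=converged,
        penalized_loglik=float(-res.fun),
        n_obs=len(records),
        n_patients=n_u,
        separation_flag=separation,
        _basis=basis,
    )
    assert surface.check_monotonicity(), "monotonicity contract violated post-fit"
    return surface


def predict_probability(
    surface: MonotoneSurface, change, baseline, mode: str = "population"
) -> np.ndarray:
    """Population-level P(feeling better | change, baseline); see MonotoneSurface.predict."""
    return surface.predict(change, baseline, mode=mode)
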