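"""Maximum-likelihood spatial capture-recapture for count detectors.

Model
-----
Activity centres follow an inhomogeneous Poisson point process with
log-linear intensity over the habitat mask,

    log D(s) = theta0 + sum_d theta_d x_d(s),          [animals / km²]

counts of individual i at detector k are Poisson with mean
``mu_k(s) = effort_k * lambda0_k * exp(-d(s,k)² / (2 sigma_k²))`` — the
half-normal encounter function with log-linear detector-covariate models

    log lambda0 = phi0 + sum_l phi_l x_l,              [encounters / day]
    log sigma   = beta0 + sum_i beta_i x_i,            [m]

and ``d(s,k)`` either the Euclidean distance or, when a conductance
("noneuc") covariate is modelled, the least-cost ecological distance whose
coefficient alpha is estimated jointly with everything else.

Marginalising the activity centres gives the Poisson-process likelihood

    -logL = Lambda - sum_i log( sum_s D(s) a prod_k Pois(y_ik; mu_k(s)) )
            + sum_ik log(y_ik!) + log(n!),

with ``Lambda = sum_s D(s) a p.(s)``, ``p.(s) = 1 - exp(-sum_k mu_k(s))``
and ``a`` the pixel area in km².  The ``log(n!)`` term — a constant for
fixed data — is included, so reported log-likelihoods follow the
exchangeable-history convention.

Covariates are z-scored (mask covariates over mask pixels, numeric detector
covariates over detectors) before fitting, so slope estimates are on the
standardized scale; squared terms square the standardized covariate.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .captures import CaptureHistory, DetectorArray, TOPOGRAPHY_LEVELS
from .geomask import LeastCostEngine, MaskGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ScrModelSpec",
    "ScrParams",
    "ScrFit",
    "DensitySurface",
    "encounter_rate",
    "expected_counts",
    "neg_log_likelihood",
    "fit",
    "derived_density",
    "evaluate_density",
]


# ---------------------------------------------------------------------------
# Model specification and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScrModelSpec:
    """Which covariates enter each sub-model.

    Empty term lists mean intercept-only ("~1").  Density terms name mask
    covariates (append "^2" for a quadratic term on the standardized scale);
    lambda0/sigma terms name detector covariates, where "Cameras" is the
    two-camera indicator and "Topo" expands to topography dummies with
    "cliff" as the baseline.  ``noneuc`` names the mask covariate driving
    conductance; None means Euclidean distance.
    """

    density: tuple[str, ...] = ()
    lambda0: tuple[str, ...] = ()
    sigma: tuple[str, ...] = ()
    noneuc: str | None = None
    standardize: bool = True

    def __init__(self, density=(), lambda0=(), sigma=(), noneuc=None, standardize=True):
        object.__setattr__(self, "density", tuple(density))
        object.__setattr__(self, "lambda0", tuple(lambda0))
        object.__setattr__(self, "sigma", tuple(sigma))
        object.__setattr__(self, "noneuc", noneuc)
        object.__setattr__(self, "standardize", standardize)

    @property
    def label(self) -> str:
        def clause(terms):
            return "+".join(terms) if terms else "1"
        out = f"D~{clause(self.density)}; lambda0~{clause(self.lambda0)}; sigma~{clause(self.sigma)}"
        if self.noneuc:
            out += f"; noneuc~{self.noneuc}"
        return out


@dataclass
class ScrParams:
    """Link-scale parameters: density (theta), encounter intercept (phi),
    range (beta) and the conductance coefficient alpha (None if Euclidean).

    theta[0] is log density in animals/km²; phi[0] is log encounters/day at
    distance zero; beta[0] is log sigma in meters.
    """

    theta: np.ndarray
    phi: np.ndarray
    beta: np.ndarray
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError("parameters must be finite on the link scale")

    def to_vector(self) -> np.ndarray:
        parts = [self.theta, self.phi, self.beta]
        if self.alpha is not None:
            parts.append([self.alpha])
        return np.concatenate([np.atleast_1d(p) for p in parts]).astype(float)

    @classmethod
    def from_vector(cls, vec, n_theta: int, n_phi: int, n_beta: int, has_alpha: bool) -> "ScrParams":
        vec = np.asarray(vec, dtype=float)
        i = 0
        theta = vec[i : i + n_theta]; i += n_theta
        phi = vec[i : i + n_phi]; i += n_phi
        beta = vec[i : i + n_beta]; i += n_beta
        alpha = float(vec[i]) if has_alpha else None
        return cls(theta=theta, phi=phi, beta=beta, alpha=alpha)

    @property
    def npar(self) -> int:
        return self.to_vector().size


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / (sd if sd > 0 else 1.0)


def mask_design(mask: MaskGrid, terms: Sequence[str], standardize: bool = True):
    """Density design matrix over mask pixels (intercept first)."""
    cols = [np.ones(mask.n_pixels)]
    names = ["(Intercept)"]
    for term in terms:
        squared = term.endswith("^2")
        base = term[:-2] if squared else term
        if base not in mask.covariates.columns:
            raise KeyError(f"mask has no covariate named {base!r}")
        v = mask.covariates[base].to_numpy(float)
        if standardize:
            v = _standardize(v)
        cols.append(v * v if squared else v)
        names.append(term)
    return np.column_stack(cols), names


def detector_design(detectors: DetectorArray, terms: Sequence[str], standardize: bool = True):
    """Detector-covariate design matrix (intercept first).

    "Cameras" is the two-camera indicator; "Topo" expands to dummies for
    'gully bed' and 'ridgeline' ('cliff' baseline); any other name must be a
    numeric detector-table column (z-scored when standardizing).
    """
    t = detectors.table
    cols = [np.ones(len(t))]
    names = ["(Intercept)"]
    for term in terms:
        if term == "Cameras":
            cols.append((t["n_cameras"].to_numpy() == 2).astype(float))
            names.append("Cameras")
        elif term == "Topo":
            for level in TOPOGRAPHY_LEVELS[1:]:  # cliff is the baseline
                cols.append((t["topography"].to_numpy() == level).astype(float))
                names.append(f"Topo[{level}]")
        else:
            if term not in t.columns:
                raise KeyError(f"detector table has no covariate named {term!r}")
            v = t[term].to_numpy(float)
            cols.append(_standardize(v) if standardize else v)
            names.append(term)
    return np.column_stack(cols), names


def evaluate_density(mask: MaskGrid, spec: ScrModelSpec, theta: np.ndarray) -> np.ndarray:
    """Per-pixel density (animals/km²) implied by theta under ``spec``."""
    X, _ = mask_design(mask, spec.density, spec.standardize)
    return np.exp(X @ np.atleast_1d(np.asarray(theta, float)))


# ---------------------------------------------------------------------------
# Encounter model
# ---------------------------------------------------------------------------

def encounter_rate(params: ScrParams, distance, x_lambda0=None, x_sigma=None) -> np.ndarray:
    """Half-normal expected encounter rate per day at the given distance (m).

    ``x_lambda0``/``x_sigma`` are the detector's covariate vectors matching
    the slope parameters (excluding the intercept).
    """
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distance must be >= 0")
    lam0 = math.exp(params.phi[0] + (0.0 if x_lambda0 is None else float(np.dot(params.phi[1:], x_lambda0))))
    sig = math.exp(params.beta[0] + (0.0 if x_sigma is None else float(np.dot(params.beta[1:], x_sigma))))
    return lam0 * np.exp(-(distance**2) / (2.0 * sig**2))


def expected_counts(params: ScrParams, effort, distances, X_lambda0=None, X_sigma=None) -> np.ndarray:
    """Expected Poisson counts mu_k = effort_k * lambda(d_k) per detector."""
    effort = np.atleast_1d(np.asarray(effort, dtype=float))
    distances = np.atleast_1d(np.asarray(distances, dtype=float))
    if np.any(effort <= 0):
        raise ValueError("effort must be > 0")
    mu = np.empty_like(distances)
    for k in range(len(distances)):
        xl = None if X_lambda0 is None else np.atleast_2d(X_lambda0)[k]
        xs = None if X_sigma is None else np.atleast_2d(X_sigma)[k]
        mu[k] = effort[k] * encounter_rate(params, distances[k], xl, xs)
    return mu


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

class _ScrData:
    """Precomputed arrays for fast repeated likelihood evaluation."""

    def __init__(self, spec: ScrModelSpec, history: CaptureHistory,
                 mask: MaskGrid, detectors: DetectorArray):
        self.spec = spec
        self.mask = mask
        self.detectors = detectors
        y = history.y.reindex(columns=detectors.ids, fill_value=0)
        self.y = y.to_numpy(dtype=float)
        self.individuals = list(y.index)
        self.n = self.y.shape[0]
        self.effort = detectors.effort
        self.X_mask, self.density_names = mask_design(mask, spec.density, spec.standardize)
        self.X_l, self.lambda0_names = detector_design(detectors, spec.lambda0, spec.standardize)
        self.X_s, self.sigma_names = detector_design(detectors, spec.sigma, spec.standardize)
        self.a = mask.area_per_pixel
        self.checksum = history.checksum
        det_xy = detectors.xy
        if spec.noneuc is not None:
            self.engine = LeastCostEngine(mask, spec.noneuc)
            self.det_idx = mask.snap(det_xy)
            self.euclid = None
        else:
            self.engine = None
            diff = det_xy[:, None, :] - mask.centers[None, :, :]
            self.euclid = np.sqrt((diff**2).sum(axis=2))  # (K, S)
        self.logfact_y = float(gammaln(self.y + 1).sum())
        self.log_n_fact = float(gammaln(self.n + 1))

    @property
    def sizes(self) -> tuple[int, int, int, bool]:
        return (self.X_mask.shape[1], self.X_l.shape[1], self.X_s.shape[1],
                self.spec.noneuc is not None)

    @property
    def param_names(self) -> list[str]:
        names = [f"D.{n}" for n in self.density_names]
        names += [f"lambda0.{n}" for n in self.lambda0_names]
        names += [f"sigma.{n}" for n in self.sigma_names]
        if self.spec.noneuc is not None:
            names.append(f"noneuc.{self.spec.noneuc}")
        return names

    def distances(self, alpha: float | None) -> np.ndarray:
        if self.engine is None:
            return self.euclid
        return self.engine.distances(0.0 if alpha is None else alpha, self.det_idx)

    def nll_vector(self, vec: np.ndarray) -> float:
        nt, nl, ns, has_alpha = self.sizes
        p = ScrParams.from_vector(vec, nt, nl, ns, has_alpha)
        return self.nll(p)

    def nll(self, params: ScrParams) -> float:
        try:
            d = self.distances(params.alpha)
            lam0 = np.exp(self.X_l @ params.phi)          # (K,)
            sig = np.exp(self.X_s @ params.beta)          # (K,)
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                mu = self.effort[:, None] * lam0[:, None] * np.exp(
                    -(d**2) / (2.0 * sig[:, None] ** 2))  # (K, S)
                mu = np.where(np.isfinite(mu), mu, 0.0)   # unreachable pixels (inf d) -> 0
                log_d_s = self.X_mask @ params.theta       # (S,) log density
                mu_sum = mu.sum(axis=0)
                pdot = -np.expm1(-mu_sum)
                lam_total = float(np.exp(log_d_s) @ pdot) * self.a
                if self.n == 0:
                    return lam_total
                # mu == 0 with a positive count must force the likelihood to
                # zero (-inf log); a large finite stand-in keeps 0 * log(0)
                # products at 0 while logsumexp still underflows to -inf.
                log_mu = np.where(mu > 0, np.log(np.clip(mu, 1e-300, None)), -1e30)
                per_pixel = (self.y @ log_mu) - mu_sum[None, :] + log_d_s[None, :] + math.log(self.a)
                li = logsumexp(per_pixel, axis=1)          # (n,)
                nll = lam_total - float(li.sum()) + self.logfact_y + self.log_n_fact
            if not np.isfinite(nll) or nll > 1e25:
                # an individual with zero likelihood at every pixel (p.(s)=0)
                return np.inf
            return nll
        except (FloatingPointError, OverflowError):
            return np.inf


def neg_log_likelihood(params: ScrParams, history: CaptureHistory, mask: MaskGrid,
                       detectors: DetectorArray, spec: ScrModelSpec) -> float:
    """Negative log-likelihood of the count-detector SCR model (see module
    docstring for the exact expression and constant conventions).  Returns
    +inf (never raises) when detection is impossible for observed data, so
    optimizers can recover."""
    return _ScrData(spec, history, mask, detectors).nll(params)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _start_values(data: _ScrData) -> np.ndarray:
    """Data-driven fixed starting point: slopes 0; intercepts from crude
    moment heuristics (density from n/area, lambda0 from mean counts, sigma
    from RMS between-detector displacement of recaptured individuals)."""
    nt, nl, ns, has_alpha = data.sizes
    n = max(data.n, 1)
    theta0 = math.log(max(n / data.mask.total_area, 1e-8))
    total = data.y.sum()
    lam0 = max(total / (n * data.effort.mean()), 1e-6)
    phi0 = math.log(lam0)
    det_xy = data.detectors.xy
    d2 = []
    for i in range(data.n):
        where = np.nonzero(data.y[i] > 0)[0]
        for a_i in range(len(where)):
            for b_i in range(a_i + 1, len(where)):
                d2.append(((det_xy[where[a_i]] - det_xy[where[b_i]]) ** 2).sum())
    if d2:
        sigma0 = max(math.sqrt(float(np.mean(d2))) / 2.0, data.mask.spacing / 2)
    else:
        span = det_xy.max(axis=0) - det_xy.min(axis=0)
        sigma0 = max(float(np.hypot(*span)) / 4.0, data.mask.spacing)
    vec = np.zeros(nt + nl + ns + (1 if has_alpha else 0))
    vec[0] = theta0
    vec[nt] = phi0
    vec[nt + nl] = math.log(sigma0)
    return vec


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


@dataclass
class ScrFit:
    """A fitted SCR model: MLE, uncertainty and information criteria."""

    spec: ScrModelSpec
    params: ScrParams
    vcov: np.ndarray
    log_lik: float
    npar: int
    aic: float
    converged: bool
    message: str
    param_names: list[str]
    data_checksum: str
    _data: "_ScrData" = dataclass_field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        d = np.diag(self.vcov)
        return np.sqrt(np.where(d > 0, d, np.nan))

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        est = self.params.to_vector()
        return np.column_stack([est - z * self.se, est + z * self.se])

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.spec.label,
            "param_names": self.param_names,
            "estimates": self.params.to_vector().tolist(),
            "vcov": self.vcov.tolist(),
            "logLik": float(self.log_lik),
            "npar": int(self.npar),
            "AIC": float(self.aic),
            "converged": bool(self.converged),
            "message": self.message,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit(spec: ScrModelSpec, history: CaptureHistory, mask: MaskGrid,
        detectors: DetectorArray, start: ScrParams | None = None) -> ScrFit:
    """Maximum-likelihood fit by quasi-Newton (L-BFGS-B, numerically
    differenced gradients, objective tolerance 1e-8); variance-covariance
    from the inverse numerical Hessian at the optimum.  Deterministic given
    the data and starting point.  Non-convergence is flagged on the
    returned fit, not raised."""
    data = _ScrData(spec, history, mask, detectors)
    nt, nl, ns, has_alpha = data.sizes
    npar = nt + nl + ns + (1 if has_alpha else 0)
    dof = data.y.size
    if npar >= dof:
        logger.warning("model has %d parameters but only %d data cells", npar, dof)
    x0 = start.to_vector() if start is not None else _start_values(data)
    if x0.size != npar:
        raise ValueError(f"start has {x0.size} parameters; model needs {npar}")
    lbfgs_opts = {"ftol": 1e-8, "gtol": 1e-6, "eps": 1e-5, "maxiter": 500}
    res = minimize(data.nll_vector, x0, method="L-BFGS-B", options=lbfgs_opts)
    if start is None:
        # small SCR datasets are prone to multimodality in the range
        # parameter; restarting at halved/doubled sigma guards against
        # settling in a shallower mode
        for shift in (math.log(2.0), -math.log(2.0)):
            alt = x0.copy()
            alt[nt + nl] += shift
            res_alt = minimize(data.nll_vector, alt, method="L-BFGS-B", options=lbfgs_opts)
            if res_alt.fun < res.fun - 1e-9:
                res = res_alt
    # a derivative-free polish rescues quasi-Newton stalls on badly scaled
    # (e.g. unstandardized-covariate) surfaces; when the simplex cannot
    # improve on the quasi-Newton point, that point was an optimum even if
    # the line search ended "abnormally"
    confirmed = False
    if not res.success:
        polish = minimize(data.nll_vector, res.x, method="Nelder-Mead",
                          options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400 * npar})
        confirmed = bool(polish.success) and polish.fun >= res.fun - 1e-6
        if polish.fun < res.fun - 1e-9:
            res2 = minimize(data.nll_vector, polish.x, method="L-BFGS-B",
                            options={"ftol": 1e-8, "gtol": 1e-6, "eps": 1e-5, "maxiter": 500})
            res = res2 if res2.fun <= polish.fun else polish
            confirmed = bool(polish.success)
    mle = ScrParams.from_vector(res.x, nt, nl, ns, has_alpha)
    H = _numeric_hessian(data.nll_vector, res.x)
    converged = bool((res.success or confirmed) and np.isfinite(res.fun))
    try:
        vcov = np.linalg.inv(H)
        if not np.all(np.diag(vcov) > 0):
            vcov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
        converged = False
    vcov = 0.5 * (vcov + vcov.T)
    log_lik = -float(res.fun)
    return ScrFit(
        spec=spec, params=mle, vcov=vcov, log_lik=log_lik, npar=npar,
        aic=2.0 * npar - 2.0 * log_lik, converged=converged,
        message=str(res.message), param_names=data.param_names,
        data_checksum=data.checksum, _data=data,
    )


# ---------------------------------------------------------------------------
# Derived density and abundance
# ---------------------------------------------------------------------------

@dataclass
class DensitySurface:
    """Per-pixel estimated density with derived abundance over the mask.

    ``density`` is in animals/km²; ``per_100km2`` is the reporting scale.
    ``n_hat = sum_s density(s) * pixel area``.
    """

    mask: MaskGrid
    density: np.ndarray
    n_hat: float
    se: float | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("densities must be >= 0")

    @property
    def per_100km2(self) -> np.ndarray:
        return self.density * 100.0

    @property
    def mean_density_per_100km2(self) -> float:
        return float(self.per_100km2.mean())

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "x": self.mask.centers[:, 0],
            "y": self.mask.centers[:, 1],
            "density_per_km2": self.density,
            "density_per_100km2": self.per_100km2,
        }).to_csv(path, index=False)

    def to_asc(self, path, nodata: float = -9999.0) -> None:
        from .geomask import RasterGrid, write_asc
        m = self.mask
        ncols = int(m.col_index.max()) + 1
        nrows = int(m.row_index.max()) + 1
        vals = np.full((nrows, ncols), nodata)
        vals[m.row_index, m.col_index] = self.per_100km2
        grid = RasterGrid(
            origin_x=float(m.centers[:, 0].min()) - m.spacing / 2,
            origin_y=float(m.centers[:, 1].min()) - m.spacing / 2,
            spacing=m.spacing, values=vals, nodata=nodata,
        )
        write_asc(grid, path)


def derived_density(fit_result: ScrFit, mask: MaskGrid | None = None) -> DensitySurface:
    """Density surface and abundance at the MLE, with delta-method SE and a
    lognormal 95% CI, (N/C, N*C) with C = exp(1.96 sqrt(ln(1 + CV²))), which
    keeps the bounds positive and the interval right-skewed."""
    if not fit_result.converged:
        raise ValueError("cannot derive density from a non-converged fit")
    data = fit_result._data
    if mask is None:
        mask = data.mask
        X = data.X_mask
    else:
        X, _ = mask_design(mask, fit_result.spec.density, fit_result.spec.standardize)
    a = mask.area_per_pixel
    dens = np.exp(X @ fit_result.params.theta)
    n_hat = float(dens.sum() * a)
    nt = X.shape[1]
    grad = np.zeros(fit_result.npar)
    grad[:nt] = a * (dens[:, None] * X).sum(axis=0)
    var = float(grad @ fit_result.vcov @ grad)
    se = math.sqrt(max(var, 0.0))
    if n_hat > 0 and se > 0:
        cv = se / n_hat
        c = math.exp(1.96 * math.sqrt(math.log1p(cv**2)))
        ci = (n_hat / c, n_hat * c)
    else:
        ci = (n_hat, n_hat)
    return DensitySurface(mask=mask, density=dens, n_hat=n_hat, se=se, ci=ci)
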