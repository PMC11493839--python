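"""Population-model estimation: two-stage fits, bootstrap, covariates, diagnostics.

The default estimator is a documented two-stage procedure:

1. each subject's structural parameters are estimated by weighted least
   squares in log-parameter space, with weights from the combined residual
   model evaluated at the observed concentrations (which makes the
   per-subject objective an exact WLS problem);
2. typical values are the log-domain means of the per-subject estimates, and
   the between-subject variances are the log-domain sample variances minus
   the average per-subject estimation variance (floored at zero).

Route-specific residual standard deviations are profiled out by maximum
likelihood on the pooled residuals, alternating with the individual fits.
Empirical-Bayes eta estimates (MAP given the population fit) feed the
shrinkage diagnostic, conditional weighted residuals, and the visual
predictive check.  An optional Laplace marginal-likelihood refinement of the
typical values is provided.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .population import (
    EBESet,
    OmegaSpec,
    ResidualSpec,
    _unchecked_parameters,
    apply_residual_error,
    sample_individuals,
    shrinkage as eta_shrinkage,
)
from .structural_pk import PKParameters, Regimen, secondary_parameters, simulate_profile
from .synthetic_study import StudyDataset

__all__ = [
    "IndividualFit",
    "FitResult",
    "CovariateTerm",
    "CovariateModel",
    "BIC_ADD_THRESHOLD",
    "BIC_DELETE_THRESHOLD",
    "fit_individual",
    "fit_population",
    "bootstrap",
    "covariate_search",
    "diagnostics",
    "laplace_marginal_loglik",
]

#: Stepwise covariate thresholds: a covariate is added only if it improves
#: BIC by more than 6.635 and deleted unless removing it worsens BIC by more
#: than 10.823 (the chi-square 1-df critical values at p = 0.01 and 0.001).
BIC_ADD_THRESHOLD = 6.635
BIC_DELETE_THRESHOLD = 10.823

_PARAM_NAMES = PKParameters.parameter_names()
_PO_ONLY_PARAMS = ("Kabs", "F")

#: Half-width (log units) of the per-subject search box around the population
#: starting values; e^3.5 ~ 33-fold, beyond 4 SD of the widest reported BSV.
_LOG_SEARCH_HALF_WIDTH = 3.5


def _predict(theta: PKParameters, regimen: Regimen, times: np.ndarray) -> np.ndarray:
    """Model predictions at possibly unsorted / duplicated times."""
    uniq, inverse = np.unique(np.asarray(times, dtype=float), return_inverse=True)
    prof = simulate_profile(theta, regimen, uniq)
    return prof.concentrations[inverse]


def _subject_design(ds: StudyDataset, subject_id):
    """(regimen, times, y, routes) of one subject's quantifiable observations."""
    regimen = ds.regimen_for(subject_id)
    obs = ds.observations(subject_id)
    usable = obs[(obs["MDV"] == 0) & (obs["BLQ"] == 0)]
    return (
        regimen,
        usable["TIME"].to_numpy(dtype=float),
        usable["DV"].to_numpy(dtype=float),
        usable["ROUTE"].to_numpy(dtype=object),
    )


def _observation_weights(y: np.ndarray, routes: np.ndarray, res: ResidualSpec) -> np.ndarray:
    """Residual SD per observation, evaluated at the observed concentration."""
    w = np.empty_like(y)
    for route in ("IV", "PO"):
        mask = routes == route
        if np.any(mask):
            sp, sa = res.for_route(route)
            w[mask] = np.sqrt(sp**2 * y[mask] ** 2 + sa**2)
    if np.all(w == 0):  # noise-free data: relative weighting
        w = np.maximum(np.abs(y), 1e-8)
    else:
        w = np.maximum(w, 1e-10)
    return w


@dataclass
class IndividualFit:
    """Per-subject estimate from stage one."""

    subject_id: object
    theta: PKParameters
    free_names: tuple[str, ...]
    fixed_names: tuple[str, ...]
    log_theta_cov: np.ndarray  # over free_names
    cost: float
    n_obs: int
    converged: bool
    message: str = ""
    leverage: np.ndarray | None = None  # per-observation prediction variance
    identifiable: bool = True  # False: too few observations, prior-regularized only

    @property
    def log_theta_var(self) -> dict[str, float]:
        d = np.diag(self.log_theta_cov)
        return dict(zip(self.free_names, d))


def fit_individual(
    ds: StudyDataset,
    subject_id,
    p0: PKParameters,
    res: ResidualSpec,
    n_starts: int = 3,
    seed: int = 0,
    x0: dict[str, float] | None = None,
) -> IndividualFit:
    """Maximum-likelihood fit of one subject's structural parameters.

    The optimization runs in log-parameter space (all parameters positive by
    construction) on the weighted residuals of the combined error model.
    ``Kabs`` and ``F`` are only identifiable from oral data; for IV-only
    subjects they are fixed at the supplied population values and flagged.
    Multi-start (jittered initial values) guards against local minima.
    """
    regimen, times, y, routes = _subject_design(ds, subject_id)
    has_po = any(e.route == "PO" for e in regimen.events)
    free = [n for n in _PARAM_NAMES if has_po or n not in _PO_ONLY_PARAMS]
    fixed = tuple(n for n in _PARAM_NAMES if n not in free)
    if len(y) < len(free):
        raise ValueError(
            f"subject {subject_id}: {len(y)} observations cannot identify "
            f"{len(free)} parameters"
        )
    w = _observation_weights(y, routes, res)
    base = {n: getattr(p0, n) for n in _PARAM_NAMES}

    def build(x: np.ndarray) -> PKParameters:
        values = dict(base)
        values.update({n: np.exp(v) for n, v in zip(free, x)})
        return _unchecked_parameters(values)

    def residuals(x: np.ndarray) -> np.ndarray:
        return (y - _predict(build(x), regimen, times)) / w

    center = np.array([np.log(base[n]) for n in free])
    lo, hi = center - _LOG_SEARCH_HALF_WIDTH, center + _LOG_SEARCH_HALF_WIDTH
    start0 = np.array([
        np.log(x0[n]) if x0 and n in x0 else np.log(base[n]) for n in free
    ])
    start0 = np.clip(start0, lo + 1e-6, hi - 1e-6)
    rng = np.random.default_rng(seed)
    starts = [start0] + [
        np.clip(start0 + rng.normal(0.0, 0.4, size=start0.shape),
                lo + 1e-6, hi - 1e-6)
        for _ in range(n_starts - 1)
    ]
    best = None
    for s in starts:
        sol = optimize.least_squares(
            residuals, s, bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    J = best.jac
    jtj = J.T @ J
    dof = max(len(y) - len(free), 1)
    s2 = 2.0 * best.cost / dof  # standardized residual variance scale
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    hat = np.einsum("ij,jk,ik->i", J, np.linalg.pinv(jtj), J)
    leverage = hat * w**2  # prediction variance in concentration units
    return IndividualFit(
        subject_id=subject_id,
        theta=build(best.x),
        free_names=tuple(free),
        fixed_names=fixed,
        log_theta_cov=cov,
        cost=float(best.cost),
        n_obs=len(y),
        converged=bool(best.status > 0),
        message=best.message,
        leverage=leverage,
    )


def _fit_residual_sigmas(pairs: dict[str, tuple]) -> ResidualSpec:
    """ML estimate of (sigma_prop, sigma_add) per route.

    ``pairs`` maps route to ``(y, f)`` or ``(y, f, extra2)``; ``extra2`` is an
    additive correction to the squared residuals (the propagated variance of
    the individual predictions), which prevents the overfitting-driven
    collapse of the sigmas when predictions come from per-subject fits.
    """
    out = {}
    for route, tup in pairs.items():
        y, f = tup[0], tup[1]
        extra2 = tup[2] if len(tup) > 2 else 0.0
        e2 = (y - f) ** 2 + extra2
        if len(y) == 0 or np.mean(e2 / np.maximum(f, 1e-12) ** 2) < 1e-16:
            out[route] = (0.0, 0.0)
            continue

        def nll(s):
            v = s[0] ** 2 * f**2 + s[1] ** 2
            v = np.maximum(v, 1e-300)
            return float(np.sum(e2 / v + np.log(v)))

        s0 = [max(np.sqrt(np.mean(e2 / np.maximum(f, 1e-12) ** 2)), 1e-4), 1e-3]
        sol = optimize.minimize(
            nll, s0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        out[route] = (abs(sol.x[0]), abs(sol.x[1]))
    sp_iv, sa_iv = out.get("IV", (0.0, 0.0))
    sp_po, sa_po = out.get("PO", (0.0, 0.0))
    return ResidualSpec(
        sigma_prop_iv=sp_iv, sigma_add_iv=sa_iv,
        sigma_prop_po=sp_po, sigma_add_po=sa_po,
    )


@dataclass
class FitResult:
    """Population estimate in the layout of the published parameter table."""

    theta: PKParameters
    omega: OmegaSpec
    residual: ResidualSpec
    individual_fits: list[IndividualFit]
    ebes: EBESet | None
    shrinkage: dict | None
    loglik: float
    bic: float
    n_obs: int
    n_parameters: int
    converged_fraction: float
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        cv = self.omega.cv_percent()
        for name in _PARAM_NAMES:
            rows.append({
                "parameter": name,
                "typical": getattr(self.theta, name),
                "bsv_cv_percent": cv.get(name, np.nan),
            })
        for name, value in secondary_parameters(self.theta).items():
            rows.append({"parameter": name, "typical": value,
                         "bsv_cv_percent": np.nan})
        return pd.DataFrame(rows)


def _unidentifiable_fit(ds, subject_id, start, exc) -> IndividualFit:
    """Placeholder for a subject with too few observations for stage one.

    Such subjects are excluded from the unregularized pooling (their
    estimation variance is set very large, so downstream precision weighting
    ignores them) and contribute through the MAP-regularized refinement only.
    """
    regimen, times, y, routes = _subject_design(ds, subject_id)
    has_po = any(e.route == "PO" for e in regimen.events)
    free = tuple(n for n in _PARAM_NAMES if has_po or n not in _PO_ONLY_PARAMS)
    fixed = tuple(n for n in _PARAM_NAMES if n not in free)
    values = {n: float(getattr(start, n)) for n in _PARAM_NAMES}
    return IndividualFit(
        subject_id=subject_id,
        theta=_unchecked_parameters(values),
        free_names=free,
        fixed_names=fixed,
        log_theta_cov=np.eye(len(free)) * 1e6,
        cost=float("nan"),
        n_obs=len(y),
        converged=False,
        message=str(exc),
        leverage=np.zeros(len(y)),
        identifiable=False,
    )


#: Starting (and lower-bound for starting) log-variance of the ITS omega
#: iteration, ~20% CV; the EM-style updates move it freely from there.
_ITS_OMEGA_INIT = 0.04

#: Bound on MAP log-deviations (log units) and cap on the updated omega^2;
#: both far beyond any plausible biological variability, present only to stop
#: runaway prior-widening feedback on pathological data.
_ETA_SEARCH_BOUND = 6.0
_OMEGA2_CAP = 9.0


def _iterative_two_stage(
    ds: StudyDataset,
    theta: PKParameters,
    omega: OmegaSpec,
    res: ResidualSpec,
    subject_free: dict,
    its_iter: int,
    estimate_residual: bool,
):
    """EM-style refinement with MAP individual fits under the population prior."""
    subject_ids = ds.subject_ids
    designs = {sid: _subject_design(ds, sid) for sid in subject_ids}
    names = tuple(
        n for n in _PARAM_NAMES
        if any(n in subject_free[sid] for sid in subject_ids)
    )
    omega2 = {n: max(omega.omega2.get(n, 0.0), _ITS_OMEGA_INIT) for n in names}
    values = {n: float(getattr(theta, n)) for n in _PARAM_NAMES}
    etas = {sid: np.zeros(len(names)) for sid in subject_ids}
    covs = {sid: np.zeros((len(names), len(names))) for sid in subject_ids}
    leverages: dict = {}
    for _ in range(its_iter):
        prior_sd = np.sqrt([max(omega2[n], 1e-8) for n in names])
        L_prior = np.diag(1.0 / prior_sd)
        for sid in subject_ids:
            etas[sid], covs[sid], leverages[sid] = _map_fit(
                designs[sid], values, names, L_prior, res, eta0=etas[sid]
            )
        for j, name in enumerate(names):
            members = [s for s in subject_ids if name in subject_free[s]]
            e = np.array([etas[s][j] for s in members])
            c = np.array([covs[s][j, j] for s in members])
            m = float(np.mean(e))
            values[name] *= np.exp(m)
            for s in members:
                etas[s][j] -= m
            omega2[name] = min(float(np.mean((e - m) ** 2 + c)), _OMEGA2_CAP)
        if estimate_residual:
            pairs = {}
            for route in ("IV", "PO"):
                ys, fs, hs = [], [], []
                for sid in subject_ids:
                    regimen, times, y, routes = designs[sid]
                    mask = routes == route
                    if np.any(mask):
                        ind = dict(values)
                        ind.update({
                            n: values[n] * np.exp(e)
                            for n, e in zip(names, etas[sid])
                        })
                        pred = _predict(
                            _unchecked_parameters(ind), regimen, times[mask]
                        )
                        ys.append(y[mask])
                        fs.append(pred)
                        hs.append(leverages[sid][mask])
                if ys:
                    pairs[route] = (
                        np.concatenate(ys), np.concatenate(fs), np.concatenate(hs)
                    )
            if pairs:
                res = _fit_residual_sigmas(pairs)
    individual_thetas = {}
    for sid in subject_ids:
        ind = dict(values)
        ind.update({n: values[n] * np.exp(e) for n, e in zip(names, etas[sid])})
        individual_thetas[sid] = _unchecked_parameters(ind)
    return (
        _unchecked_parameters(values),
        OmegaSpec(omega2=omega2),
        res,
        individual_thetas,
    )


def _map_fit(design, base_values, names, L_prior, res, eta0=None):
    """MAP eta estimate and Gauss-Newton posterior covariance for one subject."""
    regimen, times, y, routes = design
    w = _observation_weights(y, routes, res)

    def residuals(eta):
        values = dict(base_values)
        values.update({n: base_values[n] * np.exp(e) for n, e in zip(names, eta)})
        pred = _predict(_unchecked_parameters(values), regimen, times)
        return np.concatenate([(y - pred) / w, L_prior.T @ eta])

    x0 = np.zeros(len(names)) if eta0 is None else np.asarray(eta0, dtype=float)
    bound = _ETA_SEARCH_BOUND
    x0 = np.clip(x0, -bound + 1e-9, bound - 1e-9)
    sol = optimize.least_squares(
        residuals, x0, bounds=(-bound, bound), method="trf",
        xtol=1e-12, ftol=1e-12, max_nfev=2000,
    )
    J = sol.jac
    C = np.linalg.pinv(J.T @ J)
    Jd = J[: len(y)]  # data rows, standardized by w
    leverage = np.einsum("ij,jk,ik->i", Jd, C, Jd) * w**2
    return sol.x, C, leverage


def fit_population(
    ds: StudyDataset,
    start: PKParameters,
    res0: ResidualSpec | None = None,
    method: str = "its",
    n_iter: int = 2,
    its_iter: int = 8,
    n_starts: int = 3,
    seed: int = 0,
    estimate_residual: bool = True,
    compute_ebes: bool = True,
) -> FitResult:
    """Population fit of a study dataset.

    Stage one alternates bounded per-subject weighted least squares with
    pooled ML updates of the residual model; the plain two-stage pooling
    (``method="sts"``) then takes log-domain means as typical values and
    sample variances minus estimation variances as between-subject
    variances (negative results floored at zero with a warning).

    The default ``method="its"`` continues with an iterative two-stage
    refinement: each subject is refit as a MAP estimate under the current
    population prior, the typical values absorb the mean of the MAP etas,
    and the (diagonal) omega is updated EM-style as the mean of
    ``eta_hat^2`` plus the posterior variance.  The regularized individual
    fits remove the divergence-prone behaviour of unpenalized per-subject
    estimates for weakly identified distribution parameters.
    """
    subject_ids = ds.subject_ids
    if len(subject_ids) < 2:
        raise ValueError("population fit requires at least two subjects")
    res = res0 or ResidualSpec(
        sigma_prop_iv=0.1, sigma_add_iv=0.01, sigma_prop_po=0.1, sigma_add_po=0.01
    )
    notes: list[str] = []
    fits: dict = {}
    warm: dict = {}
    for it in range(n_iter):
        for sid in subject_ids:
            try:
                fits[sid] = fit_individual(
                    ds, sid, start, res,
                    n_starts=n_starts if it == 0 else 1,
                    seed=seed + zlib.crc32(str(sid).encode()) % 100000,
                    x0=warm.get(sid),
                )
            except ValueError as exc:
                if "cannot identify" not in str(exc):
                    raise
                fits[sid] = _unidentifiable_fit(ds, sid, start, exc)
                if it == 0:
                    notes.append(str(exc))
                continue
            warm[sid] = {
                n: getattr(fits[sid].theta, n) for n in fits[sid].free_names
            }
        if estimate_residual:
            pairs = {}
            for route in ("IV", "PO"):
                ys, fs, hs = [], [], []
                for sid in subject_ids:
                    if not fits[sid].identifiable:
                        continue
                    regimen, times, y, routes = _subject_design(ds, sid)
                    mask = routes == route
                    if np.any(mask):
                        pred = _predict(fits[sid].theta, regimen, times[mask])
                        ys.append(y[mask])
                        fs.append(pred)
                        hs.append(fits[sid].leverage[mask])
                if ys:
                    pairs[route] = (
                        np.concatenate(ys), np.concatenate(fs), np.concatenate(hs)
                    )
            if pairs:
                res = _fit_residual_sigmas(pairs)

    # stage two: log-domain pooling
    typ_values, omega2 = {}, {}
    fit_list = [fits[sid] for sid in subject_ids]
    for name in _PARAM_NAMES:
        usable = [f for f in fit_list if name in f.free_names and f.identifiable]
        logs = np.array([np.log(getattr(f.theta, name)) for f in usable])
        est_vars = np.array([f.log_theta_var[name] for f in usable])
        if len(logs) == 0:
            typ_values[name] = getattr(start, name)
            continue
        typ_values[name] = float(np.exp(np.mean(logs)))
        if len(logs) >= 2:
            raw = float(np.var(logs, ddof=1) - np.mean(est_vars))
            if raw < 0:
                notes.append(
                    f"between-subject variance for {name} floored at 0 "
                    f"(correction exceeded observed spread)"
                )
                raw = 0.0
            omega2[name] = raw
    theta = _unchecked_parameters(typ_values)
    omega = OmegaSpec(omega2=omega2)
    individual_thetas = {sid: fits[sid].theta for sid in subject_ids}

    if method == "its":
        theta, omega, res, individual_thetas = _iterative_two_stage(
            ds, theta, omega, res,
            subject_free={sid: fits[sid].free_names for sid in subject_ids},
            its_iter=its_iter,
            estimate_residual=estimate_residual,
        )
        notes = [n for n in notes if "floored" not in n]
        for sid in subject_ids:  # report the MAP-regularized individual estimates
            fits[sid].theta = individual_thetas[sid]
    elif method != "sts":
        raise ValueError("method must be 'its' or 'sts'")

    # conditional log-likelihood at the individual estimates (bookkeeping)
    loglik = 0.0
    n_obs = 0
    for sid in subject_ids:
        regimen, times, y, routes = _subject_design(ds, sid)
        pred = _predict(individual_thetas[sid], regimen, times)
        w = _observation_weights(y, routes, res)
        loglik += float(
            -0.5 * np.sum((y - pred) ** 2 / w**2 + np.log(2 * np.pi * w**2))
        )
        n_obs += len(y)
    k = len(_PARAM_NAMES) + len(omega2) + 4
    bic = -2.0 * loglik + k * np.log(max(n_obs, 1))

    ebes = shrink = None
    if compute_ebes:
        ebes = compute_empirical_bayes(ds, theta, omega, res)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shrink = eta_shrinkage(ebes, omega) if len(subject_ids) >= 2 else None
    if notes:
        for note in notes:
            warnings.warn(note)
    return FitResult(
        theta=theta, omega=omega, residual=res, individual_fits=fit_list,
        ebes=ebes, shrinkage=shrink, loglik=loglik, bic=float(bic), n_obs=n_obs,
        n_parameters=k,
        converged_fraction=float(np.mean([f.converged for f in fit_list])),
        warnings=notes,
    )


def compute_empirical_bayes(
    ds: StudyDataset, theta: PKParameters, omega: OmegaSpec, res: ResidualSpec
) -> EBESet:
    """MAP eta estimates for every subject given the population parameters.

    Minimizes the penalized weighted residual sum of squares
    ``||(y - f(tv*exp(eta)))/w||^2 + eta' Omega^-1 eta`` per subject;
    parameters with zero between-subject variance keep eta = 0.
    """
    names = tuple(n for n in _PARAM_NAMES if omega.omega2.get(n, 0.0) > 0)
    if not names:
        return EBESet(names=tuple(omega.omega2), etas=np.zeros((len(ds.subject_ids), len(omega.omega2))))
    idx = [list(omega.names).index(n) for n in names]
    cov = omega.covariance()[np.ix_(idx, idx)]
    L_prior = np.linalg.cholesky(np.linalg.inv(cov))
    etas = np.zeros((len(ds.subject_ids), len(names)))
    base = {n: getattr(theta, n) for n in _PARAM_NAMES}
    for i, sid in enumerate(ds.subject_ids):
        regimen, times, y, routes = _subject_design(ds, sid)
        w = _observation_weights(y, routes, res)

        def residuals(eta):
            values = dict(base)
            values.update({n: base[n] * np.exp(e) for n, e in zip(names, eta)})
            pred = _predict(_unchecked_parameters(values), regimen, times)
            return np.concatenate([(y - pred) / w, L_prior.T @ eta])

        sol = optimize.least_squares(
            residuals, np.zeros(len(names)), method="trf",
            xtol=1e-12, ftol=1e-12, max_nfev=2000,
        )
        etas[i] = sol.x
    return EBESet(names=names, etas=etas)


def laplace_marginal_loglik(
    ds: StudyDataset, theta: PKParameters, omega: OmegaSpec, res: ResidualSpec
) -> float:
    """Laplace approximation to the marginal log-likelihood.

    For each subject the joint log-density of data and eta is maximized (the
    MAP), and the Gaussian-integral correction uses the Gauss–Newton
    approximation to the Hessian at the mode.  Exposed for optional
    refinement and model comparison; the two-stage path does not require it.
    """
    names = tuple(n for n in _PARAM_NAMES if omega.omega2.get(n, 0.0) > 0)
    idx = [list(omega.names).index(n) for n in names]
    cov = omega.covariance()[np.ix_(idx, idx)]
    prec = np.linalg.inv(cov)
    L_prior = np.linalg.cholesky(prec)
    base = {n: getattr(theta, n) for n in _PARAM_NAMES}
    total = 0.0
    for sid in ds.subject_ids:
        regimen, times, y, routes = _subject_design(ds, sid)
        w = _observation_weights(y, routes, res)

        def residuals(eta):
            values = dict(base)
            values.update({n: base[n] * np.exp(e) for n, e in zip(names, eta)})
            pred = _predict(_unchecked_parameters(values), regimen, times)
            return np.concatenate([(y - pred) / w, L_prior.T @ eta])

        sol = optimize.least_squares(
            residuals, np.zeros(len(names)), method="trf",
            xtol=1e-10, ftol=1e-10, max_nfev=1000,
        )
        J = sol.jac
        H = J.T @ J  # Gauss-Newton Hessian of the joint -log density
        sign, logdet = np.linalg.slogdet(H)
        joint = (
            -float(sol.cost)
            - 0.5 * np.sum(np.log(2 * np.pi * w**2))
            - 0.5 * np.linalg.slogdet(2 * np.pi * cov)[1]
        )
        total += joint + 0.5 * len(names) * np.log(2 * np.pi) - 0.5 * logdet
    return total


def refine_laplace(
    ds: StudyDataset,
    fit: FitResult,
    maxiter: int = 50,
) -> FitResult:
    """Optional refinement of the typical values by Laplace marginal ML.

    Keeps omega and the residual model at the two-stage estimates and moves
    the typical values to maximize the Laplace-approximate marginal
    likelihood (Nelder-Mead, bounded iterations).
    """
    names = _PARAM_NAMES
    x0 = np.log([getattr(fit.theta, n) for n in names])

    def objective(x):
        theta = _unchecked_parameters(dict(zip(names, np.exp(x))))
        return -laplace_marginal_loglik(ds, theta, fit.omega, fit.residual)

    sol = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-4},
    )
    theta = _unchecked_parameters(dict(zip(names, np.exp(sol.x))))
    refined = FitResult(**{**fit.__dict__, "theta": theta})
    refined.loglik = -float(sol.fun)
    return refined


def bootstrap(
    ds: StudyDataset,
    start: PKParameters,
    B: int = 200,
    seed: int = 0,
    res0: ResidualSpec | None = None,
    n_iter: int = 1,
    n_starts: int = 1,
) -> dict:
    """Nonparametric bootstrap over subjects: medians and 2.5/97.5 percentiles.

    Subjects are resampled with replacement and the population fit repeated;
    the summary table mirrors the published layout (typical value as the
    bootstrap median, precision CV%, percentile CI, BSV%).  Failed replicates
    are excluded and their fraction reported.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    subject_ids = ds.subject_ids
    rows = []
    n_failed = 0
    for b in range(B):
        chosen = rng.choice(subject_ids, size=len(subject_ids), replace=True)
        frames = []
        for new_id, sid in enumerate(chosen, start=1):
            sub = ds.records[ds.records["ID"] == sid].copy()
            sub["ID"] = new_id
            frames.append(sub)
        resampled = StudyDataset(
            records=pd.concat(frames, ignore_index=True), seed=None
        )
        try:
            fit = fit_population(
                resampled, start, res0=res0, n_iter=n_iter, n_starts=n_starts,
                seed=int(rng.integers(0, 2**31 - 1)), compute_ebes=False,
            )
        except Exception:
            n_failed += 1
            continue
        row = {n: getattr(fit.theta, n) for n in _PARAM_NAMES}
        row.update({f"BSV%_{k}": v for k, v in fit.omega.cv_percent().items()})
        row.update(secondary_parameters(fit.theta))
        rows.append(row)
    if not rows:
        raise RuntimeError("all bootstrap replicates failed")
    frame = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "parameter": frame.columns,
        "typical": frame.median().to_numpy(),
        "cv_percent": (100 * frame.std(ddof=1) / frame.mean()).to_numpy(),
        "p2.5": frame.quantile(0.025).to_numpy(),
        "p97.5": frame.quantile(0.975).to_numpy(),
    })
    return {
        "summary": summary,
        "replicates": frame,
        "n_failed": n_failed,
        "failed_fraction": n_failed / B,
    }


@dataclass(frozen=True)
class CovariateTerm:
    """One candidate effect: a covariate attached to a structural parameter.

    Continuous covariates enter as a power model on the covariate centred at
    its median, ``theta = tv * (cov/ref)^beta``; categorical covariates as a
    fractional shift, ``theta = tv * exp(beta * I)``.  Both are linear on
    the log-parameter scale.
    """

    covariate: str
    parameter: str
    kind: str = "categorical"  # or "continuous"


@dataclass
class CovariateModel:
    """Inclusion state and coefficients after the stepwise search."""

    terms: list[CovariateTerm] = field(default_factory=list)
    coefficients: dict = field(default_factory=dict)
    bic: float = float("nan")
    history: list = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.terms


def _subject_covariates(ds: StudyDataset) -> pd.DataFrame:
    first = ds.records.groupby("ID").first()
    return first[[c for c in ("COND", "AGE", "BW", "SEX") if c in first.columns]]


def _stage2_fit(y: np.ndarray, X: np.ndarray, v: np.ndarray):
    """Random-effects ML on subject-level estimates: y_i ~ N(X b, tau^2 + v_i).

    ``v`` holds the per-subject estimation variances of the log-parameter, so
    poorly identified individual fits are downweighted rather than allowed to
    dominate the regression.  Returns (-2 log L, beta).
    """
    n = len(y)

    def prof(tau2: float):
        w = 1.0 / (tau2 + v)
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ y)
        r = y - X @ beta
        m2ll = float(np.sum(r**2 * w) + np.sum(np.log(tau2 + v))
                     + n * np.log(2 * np.pi))
        return m2ll, beta

    upper = max(float(np.var(y)), 1e-6) * 4
    sol = optimize.minimize_scalar(
        lambda t: prof(t)[0], bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    return prof(sol.x)


def _stage2_bic(y: np.ndarray, X: np.ndarray, v: np.ndarray) -> float:
    """BIC of the stage-two model (n = number of subjects)."""
    m2ll, _ = _stage2_fit(y, X, v)
    k = X.shape[1] + 1
    return float(m2ll + k * np.log(len(y)))


def covariate_search(
    ds: StudyDataset,
    base: FitResult,
    candidates: list[CovariateTerm],
) -> CovariateModel:
    """Stepwise covariate selection on the subject-level parameter estimates.

    Forward additions require a BIC improvement greater than 6.635; the
    backward pass then deletes any retained term unless its removal worsens
    BIC by more than 10.823.  With no candidate surviving, the returned
    model is empty (the base model).
    """
    cov_table = _subject_covariates(ds)
    fits = {f.subject_id: f for f in base.individual_fits}
    responses: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for term in candidates:
        pname = term.parameter
        if pname in responses:
            continue
        sids = [s for s in ds.subject_ids if pname in fits[s].free_names]
        y = np.array([np.log(getattr(fits[s].theta, pname)) for s in sids])
        v = np.array([fits[s].log_theta_var[pname] for s in sids])
        responses[pname] = (np.array(sids, dtype=object), y, np.maximum(v, 0.0))

    def design_column(term: CovariateTerm, sids) -> np.ndarray:
        values = cov_table.loc[list(sids), term.covariate]
        if term.kind == "continuous":
            v = values.to_numpy(dtype=float)
            ref = np.median(v)
            return np.log(v / ref)
        codes = pd.Categorical(values).codes.astype(float)
        if len(np.unique(codes)) > 2:
            raise ValueError(
                f"categorical covariate {term.covariate} must be binary"
            )
        return codes

    def total_bic(included: list[CovariateTerm]) -> float:
        bic = 0.0
        for pname, (sids, y, v) in responses.items():
            cols = [np.ones(len(sids))]
            for term in included:
                if term.parameter == pname:
                    cols.append(design_column(term, sids))
            X = np.column_stack(cols)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                # constant or collinear covariate set: cannot be selected
                warnings.warn(
                    f"collinear or constant covariate set on parameter {pname}"
                )
                return float("inf")
            bic += _stage2_bic(y, X, v)
        return bic

    included: list[CovariateTerm] = []
    history = []
    current = total_bic(included)
    # forward additions
    remaining = list(candidates)
    while remaining:
        trials = [(total_bic(included + [t]), t) for t in remaining]
        best_bic, best_term = min(trials, key=lambda p: p[0])
        if current - best_bic > BIC_ADD_THRESHOLD:
            included.append(best_term)
            remaining.remove(best_term)
            history.append(("add", best_term, best_bic))
            current = best_bic
        else:
            break
    # backward deletions
    changed = True
    while changed and included:
        changed = False
        for term in list(included):
            without = [t for t in included if t is not term]
            bic_without = total_bic(without)
            if bic_without - current <= BIC_DELETE_THRESHOLD:
                included = without
                history.append(("delete", term, bic_without))
                current = bic_without
                changed = True
                break
    coeffs = {}
    for term in included:
        pname = term.parameter
        sids, y, v = responses[pname]
        cols = [np.ones(len(sids))] + [
            design_column(t, sids) for t in included if t.parameter == pname
        ]
        X = np.column_stack(cols)
        _, beta = _stage2_fit(y, X, v)
        local = [t for t in included if t.parameter == pname]
        for j, t in enumerate(local, start=1):
            coeffs[(t.covariate, t.parameter)] = float(beta[j])
    return CovariateModel(
        terms=included, coefficients=coeffs, bic=current, history=history
    )


def diagnostics(
    ds: StudyDataset,
    fit: FitResult,
    seed: int = 0,
    nsim: int = 200,
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0),
) -> dict:
    """Goodness-of-fit diagnostics: CWRES, PRED/IPRED pairs, and a VPC.

    CWRES uses the first-order conditional linearization around the
    empirical-Bayes etas; the VPC simulates ``nsim`` replicates of the study
    design under the fitted model and summarizes observed vs simulated
    percentile curves per route at the design's nominal times.
    """
    theta, omega, res = fit.theta, fit.omega, fit.residual
    if all(s == 0 for s in (res.sigma_prop_iv, res.sigma_add_iv,
                            res.sigma_prop_po, res.sigma_add_po)):
        return {"cwres": None, "pred_ipred": None, "vpc": None,
                "note": "zero residual error: weighted residuals undefined"}
    ebes = fit.ebes or compute_empirical_bayes(ds, theta, omega, res)
    names = ebes.names
    idx = [list(omega.names).index(n) for n in names]
    Omega = omega.covariance()[np.ix_(idx, idx)]
    base = {n: getattr(theta, n) for n in _PARAM_NAMES}

    rows = []
    cwres_all = []
    for i, sid in enumerate(ds.subject_ids):
        regimen, times, y, routes = _subject_design(ds, sid)
        eta_hat = ebes.etas[i]

        def f_of(eta):
            values = dict(base)
            values.update({n: base[n] * np.exp(e) for n, e in zip(names, eta)})
            return _predict(_unchecked_parameters(values), regimen, times)

        f_hat = f_of(eta_hat)
        pred = _predict(theta, regimen, times)
        # finite-difference sensitivity of predictions to eta at the mode
        G = np.empty((len(y), len(names)))
        h = 1e-5
        for j in range(len(names)):
            ej = eta_hat.copy()
            ej[j] += h
            G[:, j] = (f_of(ej) - f_hat) / h
        v = np.empty(len(y))
        for route in ("IV", "PO"):
            mask = routes == route
            if np.any(mask):
                sp, sa = res.for_route(route)
                v[mask] = sp**2 * f_hat[mask] ** 2 + sa**2
        V = G @ Omega @ G.T + np.diag(np.maximum(v, 1e-12))
        mean = f_hat - G @ eta_hat
        L = np.linalg.cholesky(V)
        cwres = np.linalg.solve(L, y - mean)
        cwres_all.append(cwres)
        for t, yy, fp, fi, cw, route in zip(times, y, pred, f_hat, cwres, routes):
            rows.append({"ID": sid, "TIME": t, "DV": yy, "PRED": fp,
                         "IPRED": fi, "CWRES": cw, "ROUTE": route})
    gof = pd.DataFrame(rows)

    # visual predictive check
    rng = np.random.default_rng(seed)
    designs = {sid: _subject_design(ds, sid) for sid in ds.subject_ids}
    sim_percentiles: dict[str, list] = {}
    for rep in range(nsim):
        inds = sample_individuals(theta, omega, len(designs), rng)
        frames: dict[str, dict[float, list]] = {}
        for ind, (sid, (regimen, times, _, routes)) in zip(inds, designs.items()):
            pred = _predict(ind.theta, regimen, times)
            for route in ("IV", "PO"):
                mask = routes == route
                if not np.any(mask):
                    continue
                y_sim = apply_residual_error(pred[mask], res, route, rng)
                bucket = frames.setdefault(route, {})
                for t, yy in zip(times[mask], y_sim):
                    bucket.setdefault(round(float(t), 6), []).append(yy)
        for route, bucket in frames.items():
            recs = {
                t: np.percentile(vals, percentiles)
                for t, vals in bucket.items()
            }
            sim_percentiles.setdefault(route, []).append(recs)

    vpc = {}
    for route, reps in sim_percentiles.items():
        obs_route = gof[gof["ROUTE"] == route]
        times_r = sorted({round(float(t), 6) for t in obs_route["TIME"]})
        obs_curves = {
            t: np.percentile(
                obs_route.loc[np.isclose(obs_route["TIME"], t), "DV"], percentiles
            )
            for t in times_r
        }
        table = []
        for t in times_r:
            sims = np.array([rep[t] for rep in reps if t in rep])
            entry = {"TIME": t}
            for qi, q in enumerate(percentiles):
                entry[f"obs_p{int(q)}"] = obs_curves[t][qi]
                entry[f"sim_p{int(q)}_median"] = np.median(sims[:, qi])
                entry[f"sim_p{int(q)}_lo"] = np.percentile(sims[:, qi], 2.5)
                entry[f"sim_p{int(q)}_hi"] = np.percentile(sims[:, qi], 97.5)
            table.append(entry)
        vpc[route] = pd.DataFrame(table)
    return {"cwres": np.concatenate(cwres_all), "pred_ipred": gof, "vpc": vpc}
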