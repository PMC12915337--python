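"""Maximum-likelihood structural equation modelling for the LA = LG + RD model.

The airborne-aerosol outcome latent (LA, indicated by log bacterial
abundance and local PM10) is regressed on two explanatory latents: local
generation (LG, indicated by relative humidity, atmospheric pressure and
cloud cover) and regional dispersal (RD, indicated by three desert
dust-immigration indices).  LG and RD covary freely.

The model is expressed in the RAM formulation.  With ``A`` holding factor
loadings and structural paths, ``S`` the exogenous (co)variances and
residuals, and ``F`` the selector of observed variables, the implied
covariance is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T

and parameters minimise the Wishart maximum-likelihood discrepancy

    F_ML = ln|Sigma| + tr(S_sample Sigma^-1) - ln|S_sample| - p.

Identification fixes each exogenous latent variance, and the structural
disturbance variance of each endogenous latent, to 1; the standardized
solution (all variables rescaled to unit variance) is therefore a cheap
post-processing step and is how estimates are reported.  Model fit is
summarised by chi-square = (n - 1) F_min and the TLI, RMSEA and SRMR
indices against an independence baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import yaml

__all__ = [
    "SemSpec",
    "SemFit",
    "StandardizedSolution",
    "default_spec",
    "implied_covariance",
    "fml",
    "fit_sem",
    "standardize",
    "fit_indices",
    "simulate",
    "build_true_theta",
]

RESIDUAL_FLOOR = 1e-6


@dataclass
class SemSpec:
    """Latent structure: measurement map, structural paths, free covariances.

    ``loadings`` maps each latent to its indicators in observed order; each
    indicator loads on exactly one latent.  ``paths`` lists directed
    ``(target, source)`` latent regressions; latents that are never a
    target are exogenous with variance fixed at 1, endogenous latents have
    disturbance variance fixed at ``psi_fixed``.  ``start_signs`` seeds the
    optimizer with the expected loading sign per indicator so the sign
    indeterminacy of each factor resolves the same way every run.
    """

    loadings: dict[str, list[str]]
    paths: list[tuple[str, str]] = field(default_factory=list)
    covariances: list[tuple[str, str]] = field(default_factory=list)
    start_signs: dict[str, float] = field(default_factory=dict)
    psi_fixed: float = 1.0

    def __post_init__(self):
        seen = {}
        for latent, inds in self.loadings.items():
            for ind in inds:
                if ind in seen:
                    raise ValueError(f"indicator {ind!r} loads on two latents")
                seen[ind] = latent
        self.paths = [tuple(p) for p in self.paths]
        self.covariances = [tuple(c) for c in self.covariances]
        for a, b in self.paths + self.covariances:
            if a not in self.loadings or b not in self.loadings:
                raise ValueError(f"unknown latent in ({a}, {b})")

    @property
    def latents(self) -> list[str]:
        return list(self.loadings)

    @property
    def observed(self) -> list[str]:
        return [ind for inds in self.loadings.values() for ind in inds]

    @property
    def endogenous(self) -> list[str]:
        return sorted({t for t, _ in self.paths},
                      key=self.latents.index)

    @property
    def n_free(self) -> int:
        p = len(self.observed)
        return p + len(self.paths) + len(self.covariances) + p

    @property
    def df(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free

    def theta_names(self) -> list[str]:
        names = [f"lambda:{ind}" for ind in self.observed]
        names += [f"gamma:{t}<-{s}" for t, s in self.paths]
        names += [f"psi:{a}~~{b}" for a, b in self.covariances]
        names += [f"theta:{ind}" for ind in self.observed]
        return names

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({
                "loadings": {k: list(v) for k, v in self.loadings.items()},
                "paths": [list(p) for p in self.paths],
                "covariances": [list(c) for c in self.covariances],
                "start_signs": dict(self.start_signs),
            }, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SemSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(loadings=d["loadings"],
                   paths=[tuple(p) for p in d.get("paths", [])],
                   covariances=[tuple(c) for c in d.get("covariances", [])],
                   start_signs=d.get("start_signs", {}))


def default_spec() -> SemSpec:
    """The LA = LG + RD measurement and structural layout."""
    return SemSpec(
        loadings={
            "LG": ["humidity", "pressure", "cloud"],
            "RD": ["rd_horqin", "rd_gobi", "rd_taklimakan"],
            "LA": ["abundance", "local_pm10"],
        },
        paths=[("LA", "LG"), ("LA", "RD")],
        covariances=[("LG", "RD")],
        start_signs={"humidity": -1.0, "cloud": -1.0},
    )


def _split_theta(theta: np.ndarray, spec: SemSpec):
    p = len(spec.observed)
    k = len(spec.paths)
    c = len(spec.covariances)
    lam = theta[:p]
    gam = theta[p:p + k]
    cov = theta[p + k:p + k + c]
    res = theta[p + k + c:]
    return lam, gam, cov, res


def implied_covariance(theta: np.ndarray, spec: SemSpec) -> np.ndarray:
    """Model-implied covariance of the observed variables (RAM algebra)."""
    theta = np.asarray(theta, dtype=float)
    if len(theta) != spec.n_free:
        raise ValueError("parameter vector does not match the free layout")
    obs = spec.observed
    latents = spec.latents
    p, q = len(obs), len(latents)
    m = p + q
    lam, gam, cov, res = _split_theta(theta, spec)

    A = np.zeros((m, m))
    for i, ind in enumerate(obs):
        latent = next(l for l, inds in spec.loadings.items() if ind in inds)
        A[i, p + latents.index(latent)] = lam[i]
    for g, (tgt, src) in zip(gam, spec.paths):
        A[p + latents.index(tgt), p + latents.index(src)] = g

    S = np.zeros((m, m))
    S[np.arange(p), np.arange(p)] = res
    endo = set(spec.endogenous)
    for j, latent in enumerate(latents):
        S[p + j, p + j] = spec.psi_fixed if latent in endo else 1.0
    for ph, (a, b) in zip(cov, spec.covariances):
        ia, ib = p + latents.index(a), p + latents.index(b)
        S[ia, ib] = S[ib, ia] = ph

    ima = np.eye(m) - A
    try:
        inv = np.linalg.inv(ima)
    except np.linalg.LinAlgError as exc:
        raise ValueError("(I - A) is singular") from exc
    full = inv @ S @ inv.T
    return full[:p, :p]


def _full_model_covariance(theta: np.ndarray, spec: SemSpec) -> np.ndarray:
    """Covariance of observed *and* latent variables (for standardization)."""
    obs, latents = spec.observed, spec.latents
    p, q = len(obs), len(latents)
    m = p + q
    lam, gam, cov, res = _split_theta(np.asarray(theta, float), spec)
    A = np.zeros((m, m))
    for i, ind in enumerate(obs):
        latent = next(l for l, inds in spec.loadings.items() if ind in inds)
        A[i, p + latents.index(latent)] = lam[i]
    for g, (tgt, src) in zip(gam, spec.paths):
        A[p + latents.index(tgt), p + latents.index(src)] = g
    S = np.zeros((m, m))
    S[np.arange(p), np.arange(p)] = res
    endo = set(spec.endogenous)
    for j, latent in enumerate(latents):
        S[p + j, p + j] = spec.psi_fixed if latent in endo else 1.0
    for ph, (a, b) in zip(cov, spec.covariances):
        ia, ib = p + latents.index(a), p + latents.index(b)
        S[ia, ib] = S[ib, ia] = ph
    inv = np.linalg.inv(np.eye(m) - A)
    return inv @ S @ inv.T


def fml(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Wishart ML discrepancy ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Zero iff Sigma equals S; strictly positive otherwise.  Both matrices
    must be symmetric positive definite of the same order.
    """
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    if S.shape != Sigma.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and Sigma must be square and conformable")
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise ValueError("covariance matrices must be positive definite")
    return float(logdet_m + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


@dataclass
class SemFit:
    """A converged ML solution with its sample context."""

    spec: SemSpec
    theta: np.ndarray
    S: np.ndarray
    n: int
    fmin: float
    chi2: float
    df: int
    converged: bool
    n_iter: int
    objective_trace: list[float] = field(default_factory=list)
    heywood: bool = False

    @property
    def loadings(self) -> dict[str, float]:
        lam, _, _, _ = _split_theta(self.theta, self.spec)
        return dict(zip(self.spec.observed, lam.tolist()))

    @property
    def structural(self) -> dict[str, float]:
        _, gam, _, _ = _split_theta(self.theta, self.spec)
        return {f"{t}<-{s}": float(g) for g, (t, s) in zip(gam, self.spec.paths)}

    @property
    def latent_covariances(self) -> dict[str, float]:
        _, _, cov, _ = _split_theta(self.theta, self.spec)
        return {f"{a}~~{b}": float(c) for c, (a, b) in zip(cov, self.spec.covariances)}

    @property
    def residuals(self) -> dict[str, float]:
        _, _, _, res = _split_theta(self.theta, self.spec)
        return dict(zip(self.spec.observed, res.tolist()))

    def implied(self) -> np.ndarray:
        return implied_covariance(self.theta, self.spec)


@dataclass
class StandardizedSolution:
    """All variables rescaled to unit variance; explained variance per
    indicator equals its squared standardized loading."""

    loadings: dict[str, float]
    paths: dict[str, float]
    latent_covariances: dict[str, float]
    explained_variance: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings,
            "paths": self.paths,
            "latent_covariances": self.latent_covariances,
            "explained_variance": self.explained_variance,
        }


def _start_theta(spec: SemSpec, S: np.ndarray) -> np.ndarray:
    p = len(spec.observed)
    lam = np.array([0.5 * spec.start_signs.get(ind, 1.0) * np.sqrt(S[i, i])
                    for i, ind in enumerate(spec.observed)])
    gam = np.full(len(spec.paths), 0.3)
    cov = np.full(len(spec.covariances), 0.2)
    res = 0.5 * np.diag(S).copy()
    return np.concatenate([lam, gam, cov, res])


def _bounds(spec: SemSpec):
    p = len(spec.observed)
    b = [(-np.inf, np.inf)] * p
    b += [(-np.inf, np.inf)] * len(spec.paths)
    b += [(-0.999, 0.999)] * len(spec.covariances)  # exog latents have unit variance
    b += [(RESIDUAL_FLOOR, np.inf)] * p
    return b


def fit_sem(data: pd.DataFrame | np.ndarray | None = None,
            spec: SemSpec | None = None, *,
            S: np.ndarray | None = None, n: int | None = None,
            n_starts: int = 5, seed: int = 0,
            gtol: float = 1e-8, track_trace: bool = False) -> SemFit:
    """Fit the model by quasi-Newton minimisation of the ML discrepancy.

    Either a data table (rows = observations, columns named as in the
    spec; missing rows dropped listwise) or a sample covariance ``S`` with
    its ``n`` may be supplied.  ``n_starts`` jittered restarts guard
    against local minima; the best objective wins.  Residual variances are
    bounded below at 1e-6 - a solution pinned at that floor (a Heywood
    case) is flagged with a warning rather than rejected.
    """
    spec = spec or default_spec()
    if S is None:
        if data is None:
            raise ValueError("supply either data or (S, n)")
        if isinstance(data, pd.DataFrame):
            data = data[spec.observed].dropna().to_numpy(dtype=float)
        else:
            data = np.asarray(data, dtype=float)
            data = data[~np.isnan(data).any(axis=1)]
        n = data.shape[0]
        S = np.cov(data, rowvar=False, ddof=1)
    else:
        S = np.asarray(S, dtype=float)
        if n is None:
            raise ValueError("n is required when fitting from a covariance")
    p = len(spec.observed)
    if n <= p:
        raise ValueError("need more observations than observed variables")
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite")

    def objective(theta):
        try:
            return fml(S, implied_covariance(theta, spec))
        except (ValueError, np.linalg.LinAlgError):
            return 1e10

    rng = np.random.default_rng(seed)
    base = _start_theta(spec, S)
    bounds = _bounds(spec)
    best = None
    best_trace: list[float] = []
    traces = []
    for start_idx in range(max(1, n_starts)):
        x0 = base if start_idx == 0 else base * rng.uniform(0.6, 1.4, len(base))
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        trace: list[float] = []
        callback = (lambda xk: trace.append(objective(xk))) if track_trace \
            else None
        res = scipy.optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            callback=callback,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": gtol})
        traces.append(trace)
        if res.fun < 1e9 and (best is None or res.fun < best.fun):
            best = res
            best_trace = trace
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        raise RuntimeError(
            f"SEM did not converge after {n_starts} starts; traces: "
            f"{[t[-3:] for t in traces]}")
    theta = best.x
    _, _, _, res_var = _split_theta(theta, spec)
    heywood = bool((res_var <= RESIDUAL_FLOOR * 1.01).any())
    if heywood:
        warnings.warn("Heywood case: residual variance at floor 1e-6",
                      stacklevel=2)
    fmin = float(best.fun)
    return SemFit(spec=spec, theta=theta, S=S, n=int(n), fmin=fmin,
                  chi2=float((n - 1) * fmin), df=spec.df,
                  converged=bool(best.success or best.fun < 1e9),
                  n_iter=int(best.nit), objective_trace=best_trace,
                  heywood=heywood)


def standardize(fit: SemFit) -> StandardizedSolution:
    """Rescale the solution so every observed and latent variable has unit
    variance.

    Standardized loadings are ``lambda * sd(latent) / sd(indicator)``;
    structural paths scale by ``sd(source) / sd(target)``; latent
    covariances become correlations.  The explained variance of an
    indicator is the square of its standardized loading (each indicator
    loads on a single latent).
    """
    spec = fit.spec
    full = _full_model_covariance(fit.theta, spec)
    sd = np.sqrt(np.diag(full))
    p = len(spec.observed)
    latents = spec.latents
    lam, gam, cov, _ = _split_theta(fit.theta, spec)

    loadings, explained = {}, {}
    for i, ind in enumerate(spec.observed):
        latent = next(l for l, inds in spec.loadings.items() if ind in inds)
        lstar = lam[i] * sd[p + latents.index(latent)] / sd[i]
        loadings[ind] = float(lstar)
        explained[ind] = float(lstar ** 2)
    paths = {}
    for g, (tgt, src) in zip(gam, spec.paths):
        paths[f"{tgt}<-{src}"] = float(
            g * sd[p + latents.index(src)] / sd[p + latents.index(tgt)])
    covs = {}
    for c, (a, b) in zip(cov, spec.covariances):
        ia, ib = p + latents.index(a), p + latents.index(b)
        covs[f"{a}~~{b}"] = float(full[ia, ib] / (sd[ia] * sd[ib]))
    return StandardizedSolution(loadings=loadings, paths=paths,
                                latent_covariances=covs,
                                explained_variance=explained)


def fit_indices(fit: SemFit) -> dict[str, float]:
    """TLI, RMSEA and SRMR of a fitted model.

    The independence baseline constrains the implied covariance to the
    diagonal of S.  RMSEA uses the (n - 1) denominator; SRMR averages
    squared residuals of the sample vs implied matrices in the correlation
    metric over the p(p+1)/2 unique elements (diagonal included).
    """
    S, n, p = fit.S, fit.n, len(fit.spec.observed)
    if fit.df == 0:
        return {"tli": float("nan"), "rmsea": float("nan"),
                "srmr": _srmr(S, fit.implied())}
    _, logdet_s = np.linalg.slogdet(S)
    f_base = float(np.sum(np.log(np.diag(S))) - logdet_s)
    chi2_b = (n - 1) * f_base
    df_b = p * (p - 1) / 2
    chi2_m, df_m = fit.chi2, fit.df
    denom = chi2_b / df_b - 1.0
    tli = ((chi2_b / df_b - chi2_m / df_m) / denom) if denom != 0 else float("nan")
    rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n - 1))))
    return {"tli": float(tli), "rmsea": rmsea, "srmr": _srmr(S, fit.implied())}


def _srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    d = 1.0 / np.sqrt(np.diag(S))
    Rs = S * np.outer(d, d)
    Rm = Sigma * np.outer(d, d)
    p = S.shape[0]
    iu = np.triu_indices(p)
    return float(np.sqrt(np.mean((Rs[iu] - Rm[iu]) ** 2)))


def build_true_theta(spec: SemSpec,
                     loadings: dict[str, float],
                     paths: dict[tuple[str, str], float],
                     covariances: dict[tuple[str, str], float],
                     residuals: dict[str, float] | None = None) -> np.ndarray:
    """Assemble a parameter vector in the spec's free layout.

    With standardized truth values (unit-variance latents and indicators),
    omitted residual variances default to ``1 - loading**2``.
    """
    lam = [loadings[ind] for ind in spec.observed]
    gam = [paths[(t, s)] for t, s in spec.paths]
    cov = [covariances[(a, b)] for a, b in spec.covariances]
    if residuals is None:
        residuals = {ind: 1.0 - loadings[ind] ** 2 for ind in spec.observed}
    res = [residuals[ind] for ind in spec.observed]
    return np.concatenate([lam, gam, cov, res])


def simulate(theta: np.ndarray, spec: SemSpec, n: int,
             rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` multivariate-normal rows from the implied covariance."""
    Sigma = implied_covariance(theta, spec)
    data = rng.multivariate_normal(np.zeros(Sigma.shape[0]), Sigma, size=n,
                                   method="cholesky")
    return pd.DataFrame(data, columns=spec.observed)
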