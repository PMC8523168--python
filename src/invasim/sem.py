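"""Maximum-likelihood latent-variable structural equation models for the
composition -> productivity -> invasion mediation test.

Three latent variables are measured by observed indicators:

* Composition (C): the functional-group abundance features plus Simpson
  diversity;
* Productivity (P): cell yields at days 7 and 14;
* Invasion (I): the six invader-survival endpoints (2 invaders x 3 time
  points).

Three structural hypotheses differ only in their paths:

* NoMediation:        C -> I
* PartialMediation:   C -> P, P -> I, C -> I
* CompleteMediation:  C -> P, P -> I        (nested in Partial, df + 1)

The model-implied covariance is Sigma = Lambda V Lambda' + Theta with
V = (I - B)^-1 Psi (I - B)^-T the latent covariance; parameters are
estimated by minimising the normal-theory discrepancy

    F_ML = log|Sigma| + tr(S Sigma^-1) - log|S| - p

with an analytic gradient.  Identification fixes the first loading of
each latent at 1; indicator residual variances and latent disturbances
are free.  Model comparison uses chi^2 = (n - 1) F_ML, AICc, CFI and the
likelihood-ratio test; the mediation decomposition is the product of
standardised coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_PENALTY = 1e12
_VAR_FLOOR = 1e-10


@dataclass
class SemModelSpec:
    """One structural specification over a shared measurement model.

    ``indicators`` maps each latent name to its (ordered) observed
    columns; the first indicator's loading is fixed at 1.  ``paths`` are
    directed (source, destination) latent pairs and must form a DAG.
    ``fixed_residuals`` pins named indicators' residual variances (used
    e.g. for single-indicator latents with error-free measurement).
    """

    name: str
    indicators: dict[str, list[str]]
    paths: list[tuple[str, str]]
    fixed_residuals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.latents = list(self.indicators)
        self.columns = [c for lat in self.latents for c in self.indicators[lat]]
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("each indicator may load on exactly one latent")
        for s, d in self.paths:
            if s not in self.latents or d not in self.latents:
                raise ValueError(f"path {s}->{d} references unknown latent")
        # DAG check by Kahn-style elimination
        order, remaining = [], set(self.latents)
        edges = set(self.paths)
        while remaining:
            free = [v for v in remaining if not any(d == v for _, d in edges)]
            if not free:
                raise ValueError("structural paths must form a DAG")
            for v in free:
                remaining.discard(v)
                edges = {(s, d) for s, d in edges if s != v}
            order.extend(free)

    @property
    def n_free_parameters(self) -> int:
        n_load = sum(len(cols) - 1 for cols in self.indicators.values())
        n_resid = sum(1 for c in self.columns if c not in self.fixed_residuals)
        return n_load + len(self.paths) + len(self.latents) + n_resid

    def degrees_of_freedom(self, strict: bool = True) -> int:
        p = len(self.columns)
        df = p * (p + 1) // 2 - self.n_free_parameters
        if strict and df < 0:
            raise ValueError("model has more free parameters than covariance entries")
        return df


def build_mediation_models(composition: list[str], productivity: list[str],
                           invasion: list[str]) -> dict[str, SemModelSpec]:
    """The three mediation specifications over shared indicator sets.

    Each latent needs at least two indicators for identification.
    CompleteMediation is nested in PartialMediation with exactly one
    fewer structural parameter.
    """
    for name, cols in (("composition", composition),
                       ("productivity", productivity),
                       ("invasion", invasion)):
        if len(cols) < 2:
            raise ValueError(f"latent {name!r} needs >= 2 indicators, got {len(cols)}")
    indicators = {"C": list(composition), "P": list(productivity),
                  "I": list(invasion)}
    return {
        "no_mediation": SemModelSpec("no_mediation", dict(indicators),
                                     [("C", "I")]),
        "partial_mediation": SemModelSpec("partial_mediation", dict(indicators),
                                          [("C", "P"), ("P", "I"), ("C", "I")]),
        "complete_mediation": SemModelSpec("complete_mediation", dict(indicators),
                                           [("C", "P"), ("P", "I")]),
    }


@dataclass
class SemFit:
    """A fitted structural equation model."""

    spec: SemModelSpec
    params: np.ndarray
    implied_cov: np.ndarray
    sample_cov: np.ndarray
    n: int
    fmin: float
    chi2: float
    df: int
    loglik: float
    aic: float
    aicc: float
    cfi: float
    std_loadings: pd.DataFrame
    std_paths: dict[tuple[str, str], float]
    paths: dict[tuple[str, str], float]
    latent_rsq: dict[str, float]
    converged: bool
    heywood: bool
    n_restarts_used: int = 0


class _Parametrisation:
    """Maps the free-parameter vector onto (Lambda, B, Psi, Theta)."""

    def __init__(self, spec: SemModelSpec, S: np.ndarray):
        self.spec = spec
        self.p = len(spec.columns)
        self.m = len(spec.latents)
        self.col_index = {c: i for i, c in enumerate(spec.columns)}
        self.lat_index = {l: k for k, l in enumerate(spec.latents)}
        self.load_slots = []   # (row, latent) for free loadings
        self.fixed_loads = []  # (row, latent) loading fixed at 1
        for lat, cols in spec.indicators.items():
            k = self.lat_index[lat]
            self.fixed_loads.append((self.col_index[cols[0]], k))
            for c in cols[1:]:
                self.load_slots.append((self.col_index[c], k))
        self.path_slots = [(self.lat_index[s], self.lat_index[d])
                           for s, d in spec.paths]
        self.free_resid = [i for i, c in enumerate(spec.columns)
                           if c not in spec.fixed_residuals]
        self.theta_fixed = np.zeros(self.p)
        for c, v in spec.fixed_residuals.items():
            self.theta_fixed[self.col_index[c]] = v
        self.nq = (len(self.load_slots) + len(self.path_slots)
                   + self.m + len(self.free_resid))
        # start values: loadings 1, psi = half the variance of each
        # latent's first indicator, residuals = half observed variances;
        # structural paths start at their factor-proxy regression
        # estimates (from mean inter-block correlations), which keeps the
        # optimiser out of the no-effect local basin on weakly-measured
        # latents
        psi0 = np.array([0.5 * S[self.col_index[spec.indicators[l][0]],
                                 self.col_index[spec.indicators[l][0]]]
                         for l in spec.latents])
        self.start = np.concatenate([
            np.ones(len(self.load_slots)),
            self._proxy_path_starts(S),
            psi0,
            0.5 * np.diag(S)[self.free_resid],
        ])
        lb = np.full(self.nq, -np.inf)
        off = len(self.load_slots) + len(self.path_slots)
        lb[off:off + self.m] = _VAR_FLOOR
        lb[off + self.m:] = _VAR_FLOOR
        self.bounds = [(l, np.inf) for l in lb]

    def _proxy_path_starts(self, S: np.ndarray) -> np.ndarray:
        """Regression starts for the paths from block-mean correlations.

        Each latent is proxied by the average correlation structure of
        its indicator block; per endogenous latent the parents' proxy
        correlations give OLS starting coefficients, rescaled to the
        anchor-indicator metric of the unit-first-loading
        parametrisation.
        """
        if not self.path_slots:
            return np.zeros(0)
        sd = np.sqrt(np.clip(np.diag(S), 1e-300, None))
        R = S / np.outer(sd, sd)
        blocks = [[self.col_index[c] for c in self.spec.indicators[l]]
                  for l in self.spec.latents]
        P = np.eye(self.m)
        for k in range(self.m):
            for l in range(k + 1, self.m):
                P[k, l] = P[l, k] = float(np.mean(R[np.ix_(blocks[k], blocks[l])]))
        anchor_sd = np.array([sd[b[0]] for b in blocks])
        starts = np.zeros(len(self.path_slots))
        by_dst: dict[int, list[int]] = {}
        for idx, (s, d) in enumerate(self.path_slots):
            by_dst.setdefault(d, []).append(idx)
        for d, idxs in by_dst.items():
            parents = [self.path_slots[i][0] for i in idxs]
            A = P[np.ix_(parents, parents)]
            b = P[np.ix_(parents, [d])].ravel()
            try:
                coef = np.linalg.solve(A + 1e-8 * np.eye(len(parents)), b)
            except np.linalg.LinAlgError:  # pragma: no cover
                coef = np.zeros(len(parents))
            coef = np.clip(coef, -0.95, 0.95)
            for j, i in enumerate(idxs):
                starts[i] = coef[j] * anchor_sd[d] / anchor_sd[parents[j]]
        return starts

    def unpack(self, theta: np.ndarray):
        nl, npth, m = len(self.load_slots), len(self.path_slots), self.m
        Lam = np.zeros((self.p, m))
        for (i, k) in self.fixed_loads:
            Lam[i, k] = 1.0
        for (i, k), v in zip(self.load_slots, theta[:nl]):
            Lam[i, k] = v
        B = np.zeros((m, m))
        for (s, d), v in zip(self.path_slots, theta[nl:nl + npth]):
            B[d, s] = v
        Psi = np.diag(theta[nl + npth:nl + npth + m])
        th = self.theta_fixed.copy()
        th[self.free_resid] = theta[nl + npth + m:]
        return Lam, B, Psi, np.diag(th)

    def implied(self, theta: np.ndarray):
        Lam, B, Psi, Th = self.unpack(theta)
        A = np.linalg.inv(np.eye(self.m) - B)
        V = A @ Psi @ A.T
        Sigma = Lam @ V @ Lam.T + Th
        return Sigma, Lam, A, V


def _fml_and_grad(theta: np.ndarray, par: _Parametrisation, S: np.ndarray,
                  logdet_S: float):
    Sigma, Lam, A, V = par.implied(theta)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return _PENALTY, np.zeros_like(theta)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Sinv = np.linalg.inv(Sigma)
    f = logdet + np.trace(Sinv @ S) - logdet_S - par.p
    E = Sinv @ (Sigma - S) @ Sinv
    G = Lam.T @ E @ Lam
    ELV = E @ Lam @ V
    VGA = V @ G @ A
    AGA = A.T @ G @ A
    nl, npth, m = len(par.load_slots), len(par.path_slots), par.m
    grad = np.empty(par.nq)
    for idx, (i, k) in enumerate(par.load_slots):
        grad[idx] = 2.0 * ELV[i, k]
    for idx, (s, d) in enumerate(par.path_slots):
        grad[nl + idx] = 2.0 * VGA[s, d]
    for k in range(m):
        grad[nl + npth + k] = AGA[k, k]
    diagE = np.diag(E)
    grad[nl + npth + m:] = diagE[par.free_resid]
    return f, grad


def fit_sem(spec: SemModelSpec, data: pd.DataFrame | None = None, *,
            sample_cov: np.ndarray | None = None, n: int | None = None,
            n_restarts: int = 5, seed: int = 0,
            ridge_rel: float = 1e-6,
            warm_start: np.ndarray | None = None) -> SemFit:
    """Fit one specification by quasi-Newton ML.

    Either ``data`` (communities x indicators) or ``sample_cov`` + ``n``
    must be given.  A near-singular sample covariance is ridged by
    ``ridge_rel * mean(diag(S))`` with a logged warning.  On
    non-convergence the optimiser is restarted from jittered starts; a
    Heywood case (residual variance at its lower bound) is flagged, not
    raised.
    """
    if data is not None:
        data = data[spec.columns]
        n = len(data)
        if n <= len(spec.columns):
            raise ValueError("need more communities than indicators")
        S = data.cov().to_numpy()
    else:
        if sample_cov is None or n is None:
            raise ValueError("give either data or sample_cov with n")
        S = np.asarray(sample_cov, dtype=float)
    p = len(spec.columns)
    if S.shape != (p, p):
        raise ValueError("sample covariance does not match the indicator set")
    eigmin = float(np.linalg.eigvalsh(S).min())
    if eigmin < 1e-10 * np.mean(np.diag(S)):
        ridge = ridge_rel * np.mean(np.diag(S))
        logger.warning("sample covariance near-singular (min eig %.3g); "
                       "adding ridge %.3g", eigmin, ridge)
        S = S + ridge * np.eye(p)
    df = spec.degrees_of_freedom()
    # optimise on the correlation-scaled covariance: the ML discrepancy is
    # invariant to diagonal rescaling for this model class, and a uniform
    # scale makes convergence independent of the indicators' units
    sd_scale = np.sqrt(np.diag(S))
    if (sd_scale <= 0).any():
        raise ValueError("an indicator has zero variance")
    S_orig = S
    S = S / np.outer(sd_scale, sd_scale)
    scaled_spec = spec
    if spec.fixed_residuals:
        scaled_spec = SemModelSpec(
            spec.name, {k: list(v) for k, v in spec.indicators.items()},
            list(spec.paths),
            {c: v / sd_scale[spec.columns.index(c)] ** 2
             for c, v in spec.fixed_residuals.items()})
    par = _Parametrisation(scaled_spec, S)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite")

    rng = np.random.default_rng(seed)
    best = None
    used = 0
    starts = [par.start if warm_start is None else np.asarray(warm_start)]
    for attempt in range(n_restarts + 1):
        x0 = starts[0] if attempt == 0 else par.start * np.exp(
            rng.normal(0, 0.2, par.nq)) + rng.normal(0, 0.05, par.nq)
        x0 = np.maximum(x0, [b[0] for b in par.bounds])
        res = optimize.minimize(
            _fml_and_grad, x0, args=(par, S, logdet_S), jac=True,
            method="L-BFGS-B", bounds=par.bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        used = attempt
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if res.success and res.fun < _PENALTY / 2:
            best = res if res.fun <= best.fun else best
            break
    if best is None or best.fun >= _PENALTY / 2:
        raise RuntimeError(f"SEM fit failed to converge for {spec.name!r}")
    theta = best.x
    fmin = float(best.fun)
    Sigma, Lam, A, V = par.implied(theta)
    Sigma_orig = Sigma * np.outer(sd_scale, sd_scale)
    chi2 = max(0.0, (n - 1) * fmin)

    # baseline (independence) model for the CFI
    f_base = float(np.log(np.diag(S)).sum() - logdet_S)
    chi2_base = max(0.0, (n - 1) * f_base)
    df_base = p * (p - 1) // 2
    denom = max(chi2_base - df_base, 0.0)
    num = max(chi2 - df, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - min(num / denom, 1.0)

    Sinv_orig = np.linalg.inv(Sigma_orig)
    loglik = -0.5 * n * (
        p * np.log(2.0 * np.pi)
        + 2.0 * np.log(np.diag(np.linalg.cholesky(Sigma_orig))).sum()
        + float(np.trace(Sinv_orig @ S_orig)))
    q = par.nq
    aic = -2.0 * loglik + 2.0 * q
    aicc = aic + 2.0 * q * (q + 1) / (n - q - 1) if n - q - 1 > 0 else np.inf

    # standardised solution
    sd_lat = np.sqrt(np.maximum(np.diag(V), 1e-300))
    sd_obs = np.sqrt(np.diag(Sigma))
    std_load = Lam * sd_lat[None, :] / sd_obs[:, None]
    anchor_sd = {lat: sd_scale[spec.columns.index(cols[0])]
                 for lat, cols in spec.indicators.items()}
    rows = []
    for lat, cols in spec.indicators.items():
        k = par.lat_index[lat]
        for c in cols:
            i = par.col_index[c]
            rows.append({"latent": lat, "indicator": c,
                         "loading": Lam[i, k] * sd_scale[i] / anchor_sd[lat],
                         "std_loading": std_load[i, k]})
    _, B, Psi, Th = par.unpack(theta)
    std_paths, raw_paths = {}, {}
    for (s, d) in spec.paths:
        ks, kd = par.lat_index[s], par.lat_index[d]
        raw_paths[(s, d)] = float(B[kd, ks] * anchor_sd[d] / anchor_sd[s])
        std_paths[(s, d)] = float(B[kd, ks] * sd_lat[ks] / sd_lat[kd])
    latent_rsq = {}
    for lat in spec.latents:
        k = par.lat_index[lat]
        tot = V[k, k]
        latent_rsq[lat] = float(1.0 - Psi[k, k] / tot) if tot > 0 else 0.0

    heywood = bool(np.any(np.diag(Th)[par.free_resid] <= _VAR_FLOOR * 10)
                   or np.any(np.diag(Psi) <= _VAR_FLOOR * 10))
    if heywood:
        logger.warning("Heywood case in %s: a variance estimate hit its bound",
                       spec.name)
    return SemFit(spec=spec, params=theta, implied_cov=Sigma_orig,
                  sample_cov=S_orig,
                  n=n, fmin=fmin, chi2=chi2, df=df, loglik=float(loglik),
                  aic=float(aic), aicc=float(aicc), cfi=float(cfi),
                  std_loadings=pd.DataFrame(rows), std_paths=std_paths,
                  paths=raw_paths, latent_rsq=latent_rsq,
                  converged=bool(best.success), heywood=heywood,
                  n_restarts_used=used)


def compare_models(fits: dict[str, SemFit] | list[SemFit]) -> dict:
    """AICc/CFI comparison table plus the Partial-vs-Complete LRT.

    All fits must be on the same data (same n and indicator set).  The
    likelihood-ratio statistic is chi^2_complete - chi^2_partial on
    df_complete - df_partial degrees of freedom (exactly 1 for the
    standard specifications).
    """
    if isinstance(fits, list):
        fits = {f.spec.name: f for f in fits}
    ns = {f.n for f in fits.values()}
    cols = {tuple(f.spec.columns) for f in fits.values()}
    if len(ns) != 1 or len(cols) != 1:
        raise ValueError("fits must share the same data and indicator set")
    rows = []
    best_aicc = min(f.aicc for f in fits.values())
    for name, f in fits.items():
        rows.append({"model": name, "chi2": f.chi2, "df": f.df,
                     "aicc": f.aicc, "delta_aicc": f.aicc - best_aicc,
                     "cfi": f.cfi, "rsq_inv": f.latent_rsq.get("I", np.nan),
                     "heywood": f.heywood})
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    out = {"table": table, "best_model": table.loc[0, "model"]}
    if "partial_mediation" in fits and "complete_mediation" in fits:
        fp, fc = fits["partial_mediation"], fits["complete_mediation"]
        ddf = fc.df - fp.df
        if ddf <= 0:
            raise ValueError("complete model is not nested in partial "
                             "(no df reduction)")
        stat = max(0.0, fc.chi2 - fp.chi2)
        out["lrt"] = {"stat": stat, "df": ddf,
                      "p_value": float(stats.chi2.sf(stat, ddf))}
    return out


@dataclass
class MediationDecomposition:
    """Product-of-coefficients decomposition of the composition effect.

    ``a`` is C->P, ``b`` the P->I coefficient entering the product (the
    total P->I effect; in a recursive fit this equals the direct path),
    ``direct_ci``/``direct_pi`` the direct paths.  Two proportions are
    reported: the model-based indirect / total-composition ratio, and a
    "printed" variant that rounds the indirect effect to 2 decimals
    before dividing by the total productivity effect — the convention in
    which published mediation tables of this design are typically quoted.
    """

    a: float
    b: float
    direct_ci: float
    direct_pi: float

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def total_composition(self) -> float:
        return self.direct_ci + self.indirect

    @property
    def total_composition_printed(self) -> float:
        return round(self.direct_ci + round(self.indirect, 2), 2)

    @property
    def total_productivity(self) -> float:
        return self.direct_pi + self.indirect

    @property
    def total_productivity_printed(self) -> float:
        return round(self.direct_pi + round(self.indirect, 2), 2)

    @property
    def proportion_mediated(self) -> float:
        """Model-based: indirect / total composition effect (NaN if total 0)."""
        t = self.total_composition
        return float("nan") if t == 0 else self.indirect / t

    @property
    def proportion_mediated_printed(self) -> float:
        """Printed convention: round(indirect, 2) / b, rounded to 2 dp."""
        if self.b == 0:
            return float("nan")
        return round(round(self.indirect, 2) / self.b, 2)

    def summary(self) -> dict:
        return {
            "a_c_to_p": self.a, "b_p_to_i": self.b,
            "direct_c_to_i": self.direct_ci, "direct_p_to_i": self.direct_pi,
            "indirect": self.indirect,
            "indirect_printed": round(self.indirect, 2),
            "total_composition": self.total_composition,
            "total_composition_printed": self.total_composition_printed,
            "total_productivity": self.total_productivity,
            "total_productivity_printed": self.total_productivity_printed,
            "proportion_mediated": self.proportion_mediated,
            "proportion_mediated_printed": self.proportion_mediated_printed,
        }


def mediation_decomposition(fit: SemFit | None = None, *,
                            a: float | None = None, b: float | None = None,
                            direct_ci: float | None = None,
                            direct_pi: float | None = None
                            ) -> MediationDecomposition:
    """Decompose a Partial-structure fit (or explicit coefficients).

    From a fit, the standardised paths are used and ``b`` (the total
    P->I effect of a recursive model) equals the direct path.  Explicit
    coefficients allow reproducing published decompositions from their
    printed standardised solution.
    """
    if fit is not None:
        sp = fit.std_paths
        required = {("C", "P"), ("P", "I"), ("C", "I")}
        if set(sp) != required:
            raise ValueError("mediation decomposition needs a Partial-structure fit")
        a = sp[("C", "P")]
        b = sp[("P", "I")]
        direct_ci = sp[("C", "I")]
        direct_pi = sp[("P", "I")]
    if a is None or b is None or direct_ci is None:
        raise ValueError("need a, b and direct_ci (or a fitted model)")
    if direct_pi is None:
        direct_pi = b
    return MediationDecomposition(a=a, b=b, direct_ci=direct_ci,
                                  direct_pi=direct_pi)
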