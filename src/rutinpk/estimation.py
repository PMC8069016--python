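"""Population-parameter estimation by SAEM, with SEs, AIC, Wald tests,
IWRES diagnostics and visual predictive checks.

The entry point is the statsmodels-style pair :class:`PopPKModel` (data +
model specification) and :class:`PopPKResults` (returned by ``fit``), e.g.::

    model = PopPKModel.from_study(subjects, structural="iv")
    res = model.fit(seed=1)
    print(res.summary())
    res.vpc(design, n_sim=1000, seed=2)

Estimator
---------
Stochastic Approximation EM.  Each iteration alternates

1. a Metropolis-Hastings pass updating every subject's random effects
   ``eta_i`` (component-wise Gaussian random walk, proposal scale adapted
   during burn-in toward ~35% acceptance);
2. stochastic-approximation smoothing of the sufficient statistics of the
   linear-Gaussian part (sampled individual parameters on the transformed
   scale), followed by the exact M-step for the population means / betas of
   the random-effect parameters (generalised least squares) and the
   moment update of Omega and the correlations;
3. a short warm-started quasi-Newton maximisation of the conditional
   observation likelihood for the quantities that enter nonlinearly and
   carry no random effect (e.g. k12/k21, Tlag2 and its betas, the residual
   components a and b), Robbins-Monro-averaged during the smoothing phase.

Burn-in uses step size gamma = 1 with simulated-annealing floors on Omega
and the residual SDs (at most 5% shrinkage per iteration) so that the
chains keep exploring; the smoothing phase uses gamma_t = 1/t^0.65.

After the SAEM run the marginal log-likelihood is computed by
importance sampling (per-subject multivariate-t proposals centred on the
Laplace approximation at the eta mode), and standard errors come from a
finite-difference Fisher information of that importance-sampled
log-likelihood with frozen samples (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, ndtr

from .design import StudyDesign, SubjectDataset
from .io import dataset_fingerprint
from .population import (
    LOG,
    CovariateEffect,
    PopulationModel,
    RandomEffectsSpec,
    ResidualErrorModel,
    inverse_transform,
    transform_jacobian,
    transform_value,
)
from .structural import ROUTE_IV, iv_conc, oral_conc

__all__ = [
    "SAEMSettings",
    "EstimationError",
    "PopPKModel",
    "PopPKResults",
    "FitResult",
    "VPCResult",
    "fit_population",
    "wald_test",
    "compute_iwres",
    "vpc",
    "compare_models",
    "nca_informed_start",
]

_LOG2PI = math.log(2.0 * math.pi)


class EstimationError(ValueError):
    """Raised for non-identifiable specifications or failed estimations."""


@dataclass(frozen=True)
class SAEMSettings:
    """Tuning knobs of the SAEM run (declared defaults; all logged)."""

    n_burn: int = 300
    n_smooth: int = 200
    mh_steps: int = 5
    gamma_power: float = 0.65
    inner_maxiter: int = 8
    mh_target: float = 0.35
    anneal_rate: float = 0.95
    anneal_frac: float = 1.0
    n_is: int = 500         # importance-sampling size for the log-likelihood
    refine_n_is: int = 200  # importance-sampling size for direct refinement
    fim_n_is: int = 200     # importance-sampling size frozen for the FIM
    fim_step: float = 1e-3
    proposal_df: float = 5.0
    proposal_scale: float = 1.2
    numeric_trust: float = 0.2  # max per-iteration move of the numeric block
    profile_n_is: int = 1500    # precise surface for the ka1 profile scan
    profile_range: float = 0.35  # log-scale half-width of the scan
    profile_points: int = 6


# ---------------------------------------------------------------------------
# Parameter layout: maps between a PopulationModel and the internal
# unconstrained theta vector.
# ---------------------------------------------------------------------------


class _Layout:
    """Quantity bookkeeping for one fit.

    Internal scales: population values on their transform scale (log or
    logit), betas raw, Omega SDs log, correlations atanh, residual a/b log.
    """

    def __init__(self, spec: PopulationModel, fix=()):
        self.spec = spec
        self.param_names = spec.param_names
        self.transforms = [spec.transform_of(p) for p in self.param_names]
        self.iiv_names = spec.iiv_names
        self.iiv_slots = [self.param_names.index(p) for p in self.iiv_names]
        self.corr_pairs = list(spec.random_effects.corr.keys())

        names: list[str] = []
        kinds: list[tuple] = []
        values: list[float] = []
        for j, p in enumerate(self.param_names):
            names.append(f"{p}_pop")
            kinds.append(("mu", j))
            values.append(float(transform_value(spec.fixed_effects[p],
                                                self.transforms[j])))
            for eff in spec.effects:
                if eff.parameter == p:
                    names.append(f"beta_{p}_{eff.level}")
                    kinds.append(("beta", j, eff.level))
                    values.append(float(eff.beta))
        for qi, p in enumerate(self.iiv_names):
            names.append(f"omega_{p}")
            kinds.append(("omega", qi))
            values.append(math.log(max(spec.random_effects.sd[p], 1e-3)))
        for ci, (p1, p2) in enumerate(self.corr_pairs):
            names.append(f"corr_{p1}_{p2}")
            kinds.append(("corr", ci))
            values.append(math.atanh(spec.random_effects.corr[(p1, p2)]))
        names += ["a", "b"]
        kinds.append(("a",))
        values.append(math.log(max(spec.error.a, 1e-6)))
        kinds.append(("b",))
        values.append(math.log(max(spec.error.b, 1e-6)))

        self.names = names
        self.kinds = kinds
        self.theta0 = np.array(values)
        unknown_fix = [f for f in fix if f not in names]
        if unknown_fix:
            raise EstimationError(f"cannot fix unknown quantities {unknown_fix}; "
                                  f"available: {names}")
        self.free = np.array([n not in set(fix) for n in names])

        iiv_set = set(self.iiv_slots)
        self.linear_idx = [i for i, k in enumerate(kinds)
                           if self.free[i] and k[0] in ("mu", "beta")
                           and k[1] in iiv_set]
        self.numeric_idx = [i for i, k in enumerate(kinds)
                            if self.free[i]
                            and ((k[0] in ("mu", "beta") and k[1] not in iiv_set)
                                 or k[0] in ("a", "b"))]
        self.omega_idx = {k[1]: i for i, k in enumerate(kinds) if k[0] == "omega"}
        self.corr_idx = {k[1]: i for i, k in enumerate(kinds) if k[0] == "corr"}
        self.a_idx = next(i for i, k in enumerate(kinds) if k[0] == "a")
        self.b_idx = next(i for i, k in enumerate(kinds) if k[0] == "b")

    # -- conversions -------------------------------------------------------

    def mu(self, theta: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.param_names))
        for i, k in enumerate(self.kinds):
            if k[0] == "mu":
                out[k[1]] = theta[i]
        return out

    def error_ab(self, theta: np.ndarray) -> tuple[float, float]:
        return math.exp(theta[self.a_idx]), math.exp(theta[self.b_idx])

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        q = len(self.iiv_names)
        sd = np.array([math.exp(theta[self.omega_idx[qi]]) for qi in range(q)])
        R = np.eye(q)
        for ci, (p1, p2) in enumerate(self.corr_pairs):
            r = math.tanh(theta[self.corr_idx[ci]])
            i1 = self.iiv_names.index(p1)
            i2 = self.iiv_names.index(p2)
            R[i1, i2] = R[i2, i1] = r
        return R * np.outer(sd, sd)

    def to_spec(self, theta: np.ndarray) -> PopulationModel:
        """Materialise theta as a PopulationModel (for simulation/VPC)."""
        fixed = {}
        effects = []
        for i, k in enumerate(self.kinds):
            if k[0] == "mu":
                p = self.param_names[k[1]]
                fixed[p] = float(inverse_transform(theta[i], self.transforms[k[1]]))
            elif k[0] == "beta":
                effects.append(CovariateEffect(self.param_names[k[1]], k[2],
                                               float(theta[i])))
        sd = {p: math.exp(theta[self.omega_idx[qi]])
              for qi, p in enumerate(self.iiv_names)}
        corr = {pair: math.tanh(theta[self.corr_idx[ci]])
                for ci, pair in enumerate(self.corr_pairs)}
        a, b = self.error_ab(theta)
        return replace(self.spec,
                       fixed_effects=fixed,
                       effects=tuple(effects),
                       random_effects=RandomEffectsSpec(sd=sd, corr=corr),
                       error=ResidualErrorModel(a=a, b=b, form=self.spec.error.form))

    def report(self, theta: np.ndarray, se_theta: np.ndarray | None = None):
        """(estimates, SEs) on the reporting scale of the published tables:
        population values on the unit scale, betas raw, Omegas as SDs,
        correlations raw, residual a/b raw."""
        est, se = {}, {}
        for i, (name, k) in enumerate(zip(self.names, self.kinds)):
            s = se_theta[i] if se_theta is not None else math.nan
            if k[0] == "mu":
                unit = float(inverse_transform(theta[i], self.transforms[k[1]]))
                est[name] = unit
                se[name] = abs(transform_jacobian(unit, self.transforms[k[1]])) * s
            elif k[0] == "beta":
                est[name] = float(theta[i])
                se[name] = s
            elif k[0] == "omega":
                w = math.exp(theta[i])
                est[name], se[name] = w, w * s
            elif k[0] == "corr":
                r = math.tanh(theta[i])
                est[name], se[name] = r, (1.0 - r * r) * s
            else:  # a, b
                v = math.exp(theta[i])
                est[name], se[name] = v, v * s
        return est, se


# ---------------------------------------------------------------------------
# The likelihood engine
# ---------------------------------------------------------------------------


class _Engine:
    """Vectorised data + likelihood evaluations for one fit."""

    def __init__(self, subjects: list[SubjectDataset], spec: PopulationModel,
                 fix=(), blq_policy: str = "exclude"):
        if len(subjects) < 2:
            raise EstimationError("population estimation requires >= 2 subjects")
        if blq_policy not in ("exclude", "censored"):
            raise EstimationError(f"unknown BLQ policy {blq_policy!r}")
        route_iv = spec.structural == "iv"
        for s in subjects:
            if (s.dose.route == ROUTE_IV) != route_iv:
                raise EstimationError(
                    f"subject {s.subject_id} route {s.dose.route!r} does not match "
                    f"the {spec.structural!r} structural model")
            if s.level not in spec.levels:
                raise EstimationError(
                    f"subject {s.subject_id} covariate level {s.level!r} not declared "
                    f"in the model (levels: {list(spec.levels)})")
        present = {s.level for s in subjects}
        for eff in spec.effects:
            if eff.level not in present:
                raise EstimationError(
                    f"beta for level {eff.level!r} ({eff.parameter}) is not "
                    f"identifiable: no subject carries that level")

        self.spec = spec
        self.layout = _Layout(spec, fix)
        self.subjects = subjects
        self.blq_policy = blq_policy
        self.n = len(subjects)
        self.q = len(self.layout.iiv_names)

        obs_t, obs_y, obs_subj, obs_cens = [], [], [], []
        starts = []
        self.levels = []
        self.doses = np.empty(self.n)
        for i, s in enumerate(subjects):
            self.levels.append(s.level)
            self.doses[i] = s.dose.amount
            starts.append(len(obs_t))
            for t, dv, blq in zip(s.times, s.dv, s.blq):
                if blq and blq_policy == "exclude":
                    continue
                obs_t.append(t)
                obs_y.append(s.lloq if blq else dv)
                obs_subj.append(i)
                obs_cens.append(blq)
            if len(obs_t) == starts[-1]:
                raise EstimationError(
                    f"subject {s.subject_id} has no usable observations")
        self.obs_t = np.array(obs_t)
        self.obs_y = np.array(obs_y)
        self.obs_subj = np.array(obs_subj, dtype=int)
        self.obs_cens = np.array(obs_cens, dtype=bool)
        self.starts = np.array(starts, dtype=int)
        self.obs_dose = self.doses[self.obs_subj]
        self.lloq = subjects[0].lloq
        self.n_obs = self.obs_t.size

        # per-level one-hot for the beta design
        self.level_mask = {}
        lv = np.array(self.levels)
        for level in spec.levels:
            self.level_mask[level] = lv == level

    # -- parameter mapping -------------------------------------------------

    def phi0(self, theta: np.ndarray) -> np.ndarray:
        """Transformed-scale parameters without random effects, (n, p)."""
        lay = self.layout
        phi = np.tile(lay.mu(theta), (self.n, 1))
        for i, k in enumerate(lay.kinds):
            if k[0] == "beta":
                phi[self.level_mask[k[2]], k[1]] += theta[i]
        return phi

    def _unit(self, phi: np.ndarray) -> np.ndarray:
        out = np.empty_like(phi)
        for j, kind in enumerate(self.layout.transforms):
            # clip the unconstrained scale so that transient optimizer
            # excursions cannot overflow the exponentials downstream
            out[..., j] = inverse_transform(np.clip(phi[..., j], -30.0, 30.0), kind)
        return out

    def _conc(self, U_obs: np.ndarray, t: np.ndarray, dose: np.ndarray) -> np.ndarray:
        cols = [U_obs[..., j] for j in range(U_obs.shape[-1])]
        if self.spec.structural == "iv":
            return iv_conc(*cols, dose, t)
        return oral_conc(*cols, dose, t)

    def predict(self, theta: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Individual predictions f at every usable observation, (N,)."""
        phi = self.phi0(theta)
        if self.q:
            phi[:, self.layout.iiv_slots] += eta
        U = self._unit(phi)
        f = self._conc(U[self.obs_subj], self.obs_t, self.obs_dose)
        return np.maximum(f, 0.0)

    def _obs_terms(self, f: np.ndarray, theta: np.ndarray) -> np.ndarray:
        a, b = self.layout.error_ab(theta)
        if self.spec.error.form == "linear":
            sd = a + b * f
        else:
            sd = np.sqrt(a * a + (b * f) ** 2)
        sd = np.maximum(sd, 1e-10)
        if self.blq_policy == "censored":
            cens = self.obs_cens
            while cens.ndim < f.ndim:
                cens = cens[..., None]
            y = self.obs_y
            while y.ndim < f.ndim:
                y = y[..., None]
            ll_q = -0.5 * _LOG2PI - np.log(sd) - 0.5 * ((y - f) / sd) ** 2
            ll_c = np.log(np.maximum(ndtr((self.lloq - f) / sd), 1e-300))
            return np.where(cens, ll_c, ll_q)
        y = self.obs_y
        while y.ndim < f.ndim:
            y = y[..., None]
        return -0.5 * _LOG2PI - np.log(sd) - 0.5 * ((y - f) / sd) ** 2

    def subject_obs_ll(self, theta: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Conditional observation log-likelihood per subject.

        ``eta`` of shape (n, q) gives a result of shape (n,);
        (n, M, q) gives (n, M).
        """
        if eta.ndim == 2:
            return self._subject_obs_ll_multi(theta, eta[:, None, :])[:, 0]
        return self._subject_obs_ll_multi(theta, eta)

    def _subject_obs_ll_multi(self, theta: np.ndarray, eta3: np.ndarray) -> np.ndarray:
        phi = np.repeat(self.phi0(theta)[:, None, :], eta3.shape[1], axis=1)
        if self.q:
            phi[:, :, self.layout.iiv_slots] += eta3
        U = self._unit(phi)                  # (n, M, p)
        Uo = U[self.obs_subj]                # (N, M, p)
        f = self._conc(Uo, self.obs_t[:, None], self.obs_dose[:, None])
        f = np.maximum(f, 0.0)
        terms = self._obs_terms(f, theta)    # (N, M)
        return np.add.reduceat(terms, self.starts, axis=0)

    def total_obs_ll(self, theta: np.ndarray, eta: np.ndarray) -> float:
        return float(np.sum(self.subject_obs_ll(theta, eta)))

    def obs_ll_one(self, i: int, phi_row: np.ndarray, theta: np.ndarray) -> float:
        """Observation log-likelihood of subject ``i`` at transformed-scale
        parameters ``phi_row`` (cheap per-subject path for mode finding)."""
        lo = self.starts[i]
        hi = self.starts[i + 1] if i + 1 < self.n else self.n_obs
        U = self._unit(phi_row[None, :])[0]
        f = self._conc(np.broadcast_to(U, (hi - lo, U.size)),
                       self.obs_t[lo:hi], self.obs_dose[lo:hi])
        f = np.maximum(f, 0.0)
        a, b = self.layout.error_ab(theta)
        if self.spec.error.form == "linear":
            sd = np.maximum(a + b * f, 1e-10)
        else:
            sd = np.maximum(np.sqrt(a * a + (b * f) ** 2), 1e-10)
        y = self.obs_y[lo:hi]
        ll = -0.5 * _LOG2PI - np.log(sd) - 0.5 * ((y - f) / sd) ** 2
        if self.blq_policy == "censored":
            ll_c = np.log(np.maximum(ndtr((self.lloq - f) / sd), 1e-300))
            ll = np.where(self.obs_cens[lo:hi], ll_c, ll)
        return float(np.sum(ll))

    def total_obs_ll_batch(self, thetas: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Total observation log-likelihood for a batch of theta vectors
        (B, n_theta) at fixed random effects; returns (B,).  Powers the
        finite-difference gradients of the numeric M-step in one sweep."""
        lay = self.layout
        B = thetas.shape[0]
        mu = np.empty((B, len(self.param_names)))
        for i, k in enumerate(lay.kinds):
            if k[0] == "mu":
                mu[:, k[1]] = thetas[:, i]
        phi = np.repeat(mu[:, None, :], self.n, axis=1)        # (B, n, p)
        for i, k in enumerate(lay.kinds):
            if k[0] == "beta":
                phi[:, self.level_mask[k[2]], k[1]] += thetas[:, i, None]
        if self.q:
            phi[:, :, lay.iiv_slots] += eta[None, :, :]
        U = self._unit(phi)
        Uo = U[:, self.obs_subj, :]                            # (B, N, p)
        f = self._conc(Uo, self.obs_t[None, :], self.obs_dose[None, :])
        f = np.maximum(f, 0.0)
        a = np.exp(thetas[:, lay.a_idx])[:, None]
        b = np.exp(thetas[:, lay.b_idx])[:, None]
        if self.spec.error.form == "linear":
            sd = a + b * f
        else:
            sd = np.sqrt(a * a + (b * f) ** 2)
        sd = np.maximum(sd, 1e-10)
        y = self.obs_y[None, :]
        ll_q = -0.5 * _LOG2PI - np.log(sd) - 0.5 * ((y - f) / sd) ** 2
        if self.blq_policy == "censored":
            ll_c = np.log(np.maximum(ndtr((self.lloq - f) / sd), 1e-300))
            terms = np.where(self.obs_cens[None, :], ll_c, ll_q)
        else:
            terms = ll_q
        return terms.sum(axis=1)

    @property
    def param_names(self):
        return self.layout.param_names

    def eta_prior_ll(self, eta3: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """log N(eta; 0, Sigma(theta)); eta3 is (..., q)."""
        sigma = self.layout.sigma(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        prec = np.linalg.inv(sigma)
        maha = np.einsum("...i,ij,...j->...", eta3, prec, eta3)
        return -0.5 * (self.q * _LOG2PI + logdet + maha)


# ---------------------------------------------------------------------------
# SAEM core
# ---------------------------------------------------------------------------


def _mh_sweep(engine: _Engine, theta, eta, ll_cur, prior_cur, scales, rng):
    """One component-wise random-walk Metropolis sweep; returns per-component
    acceptance fractions."""
    n, q = eta.shape
    acc = np.zeros(q)
    for c in range(q):
        prop = eta.copy()
        prop[:, c] = eta[:, c] + scales[c] * rng.standard_normal(n)
        ll_prop = engine.subject_obs_ll(theta, prop)
        prior_prop = engine.eta_prior_ll(prop, theta)
        logr = (ll_prop + prior_prop) - (ll_cur + prior_cur)
        accept = np.log(rng.random(n)) < logr
        eta[accept] = prop[accept]
        ll_cur[accept] = ll_prop[accept]
        prior_cur[accept] = prior_prop[accept]
        acc[c] = accept.mean()
    return acc


def _solve_linear_mstep(engine: _Engine, theta, s_bar):
    """Exact GLS M-step for the population means/betas of the random-effect
    parameters, given the smoothed sampled individual parameters."""
    lay = engine.layout
    idx = lay.linear_idx
    if not idx:
        return theta
    q = engine.q
    iiv_slot_pos = {slot: r for r, slot in enumerate(lay.iiv_slots)}
    W = np.linalg.inv(lay.sigma(theta))

    # design column per unknown: (n, q)
    cols = []
    for i in idx:
        k = lay.kinds[i]
        col = np.zeros((engine.n, q))
        row = iiv_slot_pos[k[1]]
        if k[0] == "mu":
            col[:, row] = 1.0
        else:
            col[engine.level_mask[k[2]], row] = 1.0
        cols.append(col)
    A = np.stack(cols, axis=-1)            # (n, q, nz)

    theta_off = theta.copy()
    theta_off[idx] = 0.0
    offset = engine.phi0(theta_off)[:, lay.iiv_slots]   # (n, q)

    resid = s_bar - offset                  # (n, q)
    lhs = np.einsum("nqz,qr,nrw->zw", A, W, A)
    rhs = np.einsum("nqz,qr,nr->z", A, W, resid)
    z = np.linalg.solve(lhs, rhs)
    theta = theta.copy()
    theta[idx] = z
    return theta


def _update_sigma(engine: _Engine, theta, s_bar, P_bar, anneal: bool,
                  rate: float):
    """Moment update of Omega/correlations from smoothed second moments."""
    lay = engine.layout
    q = engine.q
    if q == 0:
        return theta
    m = engine.phi0(theta)[:, lay.iiv_slots]           # (n, q) current means
    # E[(phi - m)(phi - m)'] averaged over subjects, from smoothed moments
    S = (P_bar - np.einsum("nq,nr->qr", m, s_bar)
         - np.einsum("nq,nr->qr", s_bar, m)
         + np.einsum("nq,nr->qr", m, m)) / engine.n
    S = 0.5 * (S + S.T)
    theta = theta.copy()
    for qi in range(q):
        i = lay.omega_idx[qi]
        if not lay.free[i]:
            continue
        new_sd = math.sqrt(max(S[qi, qi], 1e-8))
        if anneal:
            new_sd = max(new_sd, rate * math.exp(theta[i]))
        theta[i] = math.log(max(new_sd, 0.01))
    for ci, (p1, p2) in enumerate(lay.corr_pairs):
        i = lay.corr_idx[ci]
        if not lay.free[i]:
            continue
        i1, i2 = lay.iiv_names.index(p1), lay.iiv_names.index(p2)
        denom = math.sqrt(max(S[i1, i1] * S[i2, i2], 1e-16))
        r = float(np.clip(S[i1, i2] / denom, -0.95, 0.95))
        theta[i] = math.atanh(r)
    return theta


def _numeric_mstep(engine: _Engine, theta, eta, maxiter: int):
    """Short warm-started maximisation of the conditional observation
    log-likelihood over the nonlinear no-random-effect quantities.

    The gradient is a central finite difference evaluated in a single
    batched likelihood sweep, which keeps the per-iteration cost low."""
    lay = engine.layout
    idx = lay.numeric_idx
    if not idx:
        return theta
    base = theta.copy()
    m = len(idx)
    h = 1e-5

    def nll_and_grad(w):
        thetas = np.repeat(base[None, :], 2 * m + 1, axis=0)
        thetas[:, idx] = w
        for j in range(m):
            thetas[1 + j, idx[j]] += h
            thetas[1 + m + j, idx[j]] -= h
        ll = engine.total_obs_ll_batch(thetas, eta)
        grad = (ll[1:1 + m] - ll[1 + m:]) / (2.0 * h)
        return -ll[0], -grad

    res = minimize(nll_and_grad, theta[idx], jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxfun": 10 * (maxiter + 2)})
    out = theta.copy()
    if np.isfinite(res.fun):
        out[idx] = res.x
    return out


def _run_saem(engine: _Engine, settings: SAEMSettings, rng):
    lay = engine.layout
    theta = lay.theta0.copy()
    n, q = engine.n, engine.q
    history = np.empty((settings.n_burn + settings.n_smooth, theta.size))

    if q == 0:
        # no random effects: the marginal likelihood is the observation
        # likelihood and SAEM reduces to direct (deterministic) maximisation
        eta = np.zeros((n, 0))
        for _ in range(2):
            theta = _numeric_mstep(engine, theta, eta, maxiter=300)
        history[:] = theta
        return theta, eta, history

    eta = np.zeros((n, q))
    s_bar = np.zeros((n, q))
    P_bar = np.zeros((q, q))
    mh_rel = np.full(q, 1.0)   # proposal scale relative to current omega
    anneal_until = int(settings.anneal_frac * settings.n_burn)

    for it in range(settings.n_burn + settings.n_smooth):
        burn = it < settings.n_burn
        gamma = 1.0 if burn else (it - settings.n_burn + 1) ** (-settings.gamma_power)

        omega = np.sqrt(np.diag(lay.sigma(theta)))
        scales = mh_rel * np.maximum(omega, 0.05)
        ll_cur = engine.subject_obs_ll(theta, eta)
        prior_cur = engine.eta_prior_ll(eta, theta)
        acc = np.zeros(q)
        for _ in range(settings.mh_steps):
            acc += _mh_sweep(engine, theta, eta, ll_cur, prior_cur, scales, rng)
        acc /= settings.mh_steps
        if burn:
            mh_rel *= np.exp(0.5 * (acc - settings.mh_target))
            mh_rel = np.clip(mh_rel, 0.05, 20.0)

        s = engine.phi0(theta)[:, lay.iiv_slots] + eta
        if it == 0:
            s_bar = s.copy()
            P_bar = np.einsum("nq,nr->qr", s, s)
        else:
            s_bar += gamma * (s - s_bar)
            P_bar += gamma * (np.einsum("nq,nr->qr", s, s) - P_bar)

        theta = _solve_linear_mstep(engine, theta, s_bar)
        theta = _update_sigma(engine, theta, s_bar, P_bar,
                              anneal=it < anneal_until,
                              rate=settings.anneal_rate)

        theta_num = _numeric_mstep(engine, theta, eta, settings.inner_maxiter)
        idx = lay.numeric_idx
        if idx:
            if burn:
                # trust region: bounded movement per iteration keeps the
                # joint (eta, theta) adaptation coherent during exploration
                step = np.clip(theta_num[idx] - theta[idx],
                               -settings.numeric_trust, settings.numeric_trust)
                new = theta[idx] + step
                if it < anneal_until:
                    # keep residual SDs from collapsing prematurely
                    for j, i in enumerate(idx):
                        if lay.kinds[i][0] in ("a", "b"):
                            new[j] = max(new[j],
                                         theta[i] + math.log(settings.anneal_rate))
                theta[idx] = new
            else:
                theta[idx] = theta[idx] + gamma * (theta_num[idx] - theta[idx])
        history[it] = theta
    return theta, eta, history


# ---------------------------------------------------------------------------
# Marginal likelihood by importance sampling + Fisher information
# ---------------------------------------------------------------------------


def _eta_modes(engine: _Engine, theta, eta_start=None):
    n, q = engine.n, engine.q
    modes = np.zeros((n, q))
    if q == 0:
        return modes
    start = eta_start if eta_start is not None else np.zeros((n, q))
    phi0 = engine.phi0(theta)
    slots = engine.layout.iiv_slots
    sigma = engine.layout.sigma(theta)
    prec = np.linalg.inv(sigma)
    for i in range(n):
        def neg_logpost(e):
            phi = phi0[i].copy()
            phi[slots] += e
            ll = engine.obs_ll_one(i, phi, theta)
            pr = -0.5 * float(e @ prec @ e)
            return -(ll + pr)

        res = minimize(neg_logpost, start[i], method="Nelder-Mead",
                       options={"maxiter": 250 if eta_start is not None else 600,
                                "xatol": 1e-5, "fatol": 1e-7})
        modes[i] = res.x
    return modes


def _mode_hessians(engine: _Engine, theta, modes, h=1e-4):
    """Per-subject FD Hessians of the negative eta log-posterior."""
    n, q = engine.n, engine.q
    H = np.zeros((n, q, q))

    def logpost_all(eta):
        return engine.subject_obs_ll(theta, eta) + engine.eta_prior_ll(eta, theta)

    f0 = logpost_all(modes)
    steps = np.maximum(np.abs(modes), 0.1) * h
    for a_ in range(q):
        ea = np.zeros((n, q)); ea[:, a_] = steps[:, a_]
        fpa = logpost_all(modes + ea)
        fma = logpost_all(modes - ea)
        H[:, a_, a_] = -(fpa + fma - 2 * f0) / steps[:, a_] ** 2
        for b_ in range(a_ + 1, q):
            eb = np.zeros((n, q)); eb[:, b_] = steps[:, b_]
            fpp = logpost_all(modes + ea + eb)
            fpm = logpost_all(modes + ea - eb)
            fmp = logpost_all(modes - ea + eb)
            fmm = logpost_all(modes - ea - eb)
            val = -(fpp - fpm - fmp + fmm) / (4 * steps[:, a_] * steps[:, b_])
            H[:, a_, b_] = H[:, b_, a_] = val
    return H


class _ImportanceSampler:
    """Frozen per-subject multivariate-t importance samples for the marginal
    log-likelihood (common random numbers across theta evaluations)."""

    def __init__(self, engine: _Engine, theta, modes, rng, M: int,
                 df: float = 5.0, scale: float = 1.2):
        self.engine = engine
        n, q = engine.n, engine.q
        self.M = M
        if q == 0:
            self.samples = np.zeros((n, M, 0))
            self.logq = np.zeros((n, M))
            return
        H = _mode_hessians(engine, theta, modes)
        covs = np.empty((n, q, q))
        for i in range(n):
            Hi = 0.5 * (H[i] + H[i].T)
            try:
                w, V = np.linalg.eigh(Hi)
                w = np.maximum(w, 1e-4)
                covs[i] = (V / w) @ V.T * scale ** 2
            except np.linalg.LinAlgError:
                covs[i] = np.eye(q)
        self.chols = np.linalg.cholesky(covs)
        z = rng.standard_normal((n, M, q))
        g = rng.chisquare(df, size=(n, M))
        t_factor = np.sqrt(df / g)
        disp = np.einsum("nqr,nmr->nmq", self.chols, z) * t_factor[..., None]
        self.samples = modes[:, None, :] + disp
        # multivariate-t log density at the samples:
        # (x-mode)' covinv (x-mode) = |z|^2 * df/g
        logdet = 2.0 * np.sum(np.log(np.einsum("nii->ni", self.chols)), axis=1)
        maha = np.sum(z * z, axis=2) * (df / g)
        const = (gammaln((df + q) / 2.0) - gammaln(df / 2.0)
                 - 0.5 * q * math.log(df * math.pi))
        self.logq = (const - 0.5 * logdet[:, None]
                     - 0.5 * (df + q) * np.log1p(maha / df))

    def loglik(self, theta) -> float:
        eng = self.engine
        if eng.q == 0:
            eta = np.zeros((eng.n, 0))
            return eng.total_obs_ll(theta, eta)
        ll = eng._subject_obs_ll_multi(theta, self.samples)     # (n, M)
        prior = eng.eta_prior_ll(self.samples, theta)           # (n, M)
        logw = ll + prior - self.logq
        m = np.max(logw, axis=1, keepdims=True)
        li = m[:, 0] + np.log(np.mean(np.exp(logw - m), axis=1))
        return float(np.sum(li))

    def loglik_batch(self, thetas: np.ndarray, chunk: int = 6,
                     per_subject: bool = False) -> np.ndarray:
        """IS log-likelihood for a batch of theta vectors, (B,) output
        (or (B, n) per-subject contributions with ``per_subject=True``).

        Evaluated in chunks to bound memory; powers the batched
        finite-difference gradients of the direct-likelihood refinement
        and the empirical-Fisher SE step."""
        eng = self.engine
        B = thetas.shape[0]
        if eng.q == 0:
            eta = np.zeros((eng.n, 0))
            if per_subject:
                return np.stack([eng.subject_obs_ll(t, eta) for t in thetas])
            return eng.total_obs_ll_batch(thetas, eta)
        out = np.empty((B, eng.n) if per_subject else B)
        lay = eng.layout
        n, M, q = self.samples.shape
        for lo in range(0, B, chunk):
            hi = min(lo + chunk, B)
            sub = thetas[lo:hi]
            C = hi - lo
            mu = np.empty((C, len(eng.param_names)))
            for i, k in enumerate(lay.kinds):
                if k[0] == "mu":
                    mu[:, k[1]] = sub[:, i]
            phi = np.repeat(mu[:, None, :], n, axis=1)          # (C, n, p)
            for i, k in enumerate(lay.kinds):
                if k[0] == "beta":
                    phi[:, eng.level_mask[k[2]], k[1]] += sub[:, i, None]
            phi = np.repeat(phi[:, :, None, :], M, axis=2)      # (C, n, M, p)
            phi[..., lay.iiv_slots] += self.samples[None, :, :, :]
            U = eng._unit(phi)
            Uo = U[:, eng.obs_subj, :, :]                       # (C, N, M, p)
            cols = [Uo[..., j] for j in range(Uo.shape[-1])]
            t = eng.obs_t[None, :, None]
            dose = eng.obs_dose[None, :, None]
            if eng.spec.structural == "iv":
                f = iv_conc(*cols, dose, t)
            else:
                f = oral_conc(*cols, dose, t)
            f = np.maximum(f, 0.0)                              # (C, N, M)
            a = np.exp(sub[:, lay.a_idx])[:, None, None]
            b = np.exp(sub[:, lay.b_idx])[:, None, None]
            if eng.spec.error.form == "linear":
                sd = a + b * f
            else:
                sd = np.sqrt(a * a + (b * f) ** 2)
            sd = np.maximum(sd, 1e-10)
            y = eng.obs_y[None, :, None]
            terms = -0.5 * _LOG2PI - np.log(sd) - 0.5 * ((y - f) / sd) ** 2
            if eng.blq_policy == "censored":
                ll_c = np.log(np.maximum(ndtr((eng.lloq - f) / sd), 1e-300))
                terms = np.where(eng.obs_cens[None, :, None], ll_c, terms)
            ll = np.add.reduceat(terms, eng.starts, axis=1)     # (C, n, M)
            for c in range(C):
                sigma = lay.sigma(sub[c])
                sign, logdet = np.linalg.slogdet(sigma)
                prec = np.linalg.inv(sigma)
                maha = np.einsum("nmi,ij,nmj->nm", self.samples, prec, self.samples)
                prior = -0.5 * (q * _LOG2PI + logdet + maha)
                logw = ll[c] + prior - self.logq
                mx = np.max(logw, axis=1, keepdims=True)
                li = mx[:, 0] + np.log(np.mean(np.exp(logw - mx), axis=1))
                if per_subject:
                    out[lo + c] = li
                else:
                    out[lo + c] = np.sum(li)
        return out


def _is_refine(engine: _Engine, theta, rng, settings: SAEMSettings,
               rounds: int = 2, maxiter: int = 30, M: int | None = None):
    """Direct maximisation of the importance-sampled marginal log-likelihood.

    With frozen samples the IS log-likelihood is a smooth deterministic
    function of theta, so a quasi-Newton pass removes the residual
    stochastic-approximation error left by SAEM; samples and proposals are
    refreshed between rounds.  Returns (theta, loglik, modes, sampler).
    """
    free = [i for i in range(theta.size) if engine.layout.free[i]]
    M = M or settings.refine_n_is
    modes = _eta_modes(engine, theta)
    sampler = _ImportanceSampler(engine, theta, modes, rng, M,
                                 df=settings.proposal_df,
                                 scale=settings.proposal_scale)
    m = len(free)
    h = 1e-4
    for _ in range(rounds):
        def nll_and_grad(w):
            thetas = np.repeat(theta[None, :], 2 * m + 1, axis=0)
            thetas[:, free] = w
            for j in range(m):
                thetas[1 + j, free[j]] += h
                thetas[1 + m + j, free[j]] -= h
            ll = sampler.loglik_batch(thetas)
            grad = (ll[1:1 + m] - ll[1 + m:]) / (2.0 * h)
            return -ll[0], -grad

        res = minimize(nll_and_grad, theta[free], jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        if np.isfinite(res.fun):
            theta = theta.copy()
            theta[free] = res.x
        modes = _eta_modes(engine, theta, modes)
        sampler = _ImportanceSampler(engine, theta, modes, rng, M,
                                     df=settings.proposal_df,
                                     scale=settings.proposal_scale)
    return theta, sampler.loglik(theta), modes, sampler


def _laplace_loglik(engine: _Engine, theta, start_modes=None):
    """Laplace approximation of the marginal log-likelihood.

    Deterministic (no Monte Carlo), hence ideal for ranking chains and
    profile points: its approximation error drifts only slowly across the
    parameter ridges, so differences between nearby candidates are
    accurate even where importance-sampling noise would dominate.
    Returns (loglik, eta_modes).
    """
    modes = _eta_modes(engine, theta, start_modes)
    if engine.q == 0:
        return engine.total_obs_ll(theta, modes), modes
    H = _mode_hessians(engine, theta, modes)
    ll = engine.subject_obs_ll(theta, modes) + engine.eta_prior_ll(modes, theta)
    q = engine.q
    total = 0.0
    for i in range(engine.n):
        Hi = 0.5 * (H[i] + H[i].T)
        sign, logdet = np.linalg.slogdet(Hi)
        if sign <= 0:
            sign, logdet = np.linalg.slogdet(Hi + 1e-3 * np.eye(q))
        total += float(ll[i]) + 0.5 * q * _LOG2PI - 0.5 * logdet
    return total, modes


def _profile_polish(engine: _Engine, theta, rng, settings: SAEMSettings):
    """Profile-likelihood polish along the weakly identified oral ka1 axis.

    The marginal likelihood is nearly flat along a (ka1, F1, V, k) ridge, so
    quasi-Newton refinement can stall slightly off the optimum — which can
    be far away in parameter space.  This step scans fixed ka1_pop values
    (a coarse pass, then a fine pass around the coarse winner),
    re-optimising every other free quantity at each grid point — notably
    the covariate betas, which must counter-shift to keep the non-reference
    dose groups fitted — and ranks the profile points by the deterministic
    Laplace marginal likelihood.  Returns (theta, loglik, modes, sampler).
    """
    lay = engine.layout
    pos = {n: i for i, n in enumerate(lay.names)}
    i_ka1 = pos.get("ka1_pop")
    if i_ka1 is None or not lay.free[i_ka1]:
        modes = _eta_modes(engine, theta)
        sampler = _ImportanceSampler(engine, theta, modes, rng, settings.n_is,
                                     df=settings.proposal_df,
                                     scale=settings.proposal_scale)
        return theta, sampler.loglik(theta), modes, sampler

    active = [i for i in range(theta.size) if lay.free[i] and i != i_ka1]
    modes = _eta_modes(engine, theta)
    cheap = _ImportanceSampler(engine, theta, modes, rng, settings.refine_n_is,
                               df=settings.proposal_df,
                               scale=settings.proposal_scale)
    m = len(active)
    h = 1e-4

    def reoptimised(delta):
        t0 = theta.copy()
        t0[i_ka1] += delta

        def nll_and_grad(w):
            thetas = np.repeat(t0[None, :], 2 * m + 1, axis=0)
            thetas[:, active] = w
            for j in range(m):
                thetas[1 + j, active[j]] += h
                thetas[1 + m + j, active[j]] -= h
            ll = cheap.loglik_batch(thetas)
            return -ll[0], -(ll[1:1 + m] - ll[1 + m:]) / (2.0 * h)

        res = minimize(nll_and_grad, t0[active], jac=True, method="L-BFGS-B",
                       options={"maxiter": 10})
        t0[active] = res.x
        return t0

    ll0, _ = _laplace_loglik(engine, theta, modes)
    best = (ll0, theta, 0.0)
    coarse = np.linspace(-settings.profile_range, settings.profile_range,
                         settings.profile_points)
    for d in coarse:
        t0 = reoptimised(d)
        ll_t, _ = _laplace_loglik(engine, t0, modes)
        if ll_t > best[0]:
            best = (ll_t, t0, d)
    # fine pass around the coarse winner
    for d in best[2] + np.linspace(-0.1, 0.1, 5):
        t0 = reoptimised(d)
        ll_t, _ = _laplace_loglik(engine, t0, modes)
        if ll_t > best[0]:
            best = (ll_t, t0, d)
    theta = best[1]
    modes = _eta_modes(engine, theta, modes)
    sampler = _ImportanceSampler(engine, theta, modes, rng, settings.n_is,
                                 df=settings.proposal_df,
                                 scale=settings.proposal_scale)
    return theta, sampler.loglik(theta), modes, sampler


def _empirical_fisher(sampler: "_ImportanceSampler", theta, free_idx, step):
    """Empirical Fisher information: sum of outer products of per-subject
    score vectors (central finite differences of the per-subject
    importance-sampled log-likelihood contributions).

    Positive semidefinite by construction, and far more robust than a
    finite-difference Hessian of the Monte-Carlo surface.
    """
    p = len(free_idx)
    h = np.array([step * max(1.0, abs(theta[i])) for i in free_idx])
    thetas = np.repeat(theta[None, :], 2 * p, axis=0)
    for j in range(p):
        thetas[j, free_idx[j]] += h[j]
        thetas[p + j, free_idx[j]] -= h[j]
    li = sampler.loglik_batch(thetas, per_subject=True)      # (2p, n)
    scores = (li[:p] - li[p:]) / (2.0 * h[:, None])          # (p, n)
    return scores @ scores.T


# ---------------------------------------------------------------------------
# Public model / results objects
# ---------------------------------------------------------------------------


class PopPKModel:
    """A nonlinear mixed-effects population-PK model bound to a dataset.

    Parameters
    ----------
    data : list of SubjectDataset (all on one route).
    spec : PopulationModel carrying the model structure *and* the initial
        values used by :meth:`fit`.
    fix : names of quantities held at their ``spec`` value (e.g.
        ``("omega_V", "corr_V_k")``).
    blq : "exclude" drops BLQ records; "censored" integrates the Gaussian
        tail below the LLOQ (M3-style).
    """

    def __init__(self, data: list[SubjectDataset], spec: PopulationModel,
                 *, fix=(), blq: str = "exclude"):
        self.data = list(data)
        self.spec = spec
        self.fix = tuple(fix)
        self.blq = blq
        self.engine = _Engine(self.data, spec, fix=self.fix, blq_policy=blq)
        self.fingerprint = dataset_fingerprint(self.data)

    @classmethod
    def from_study(cls, data: list[SubjectDataset], structural: str, *,
                   error_form: str = "linear", fix=(), blq: str = "exclude"):
        """Build the final-model structure with NCA-informed initial values."""
        spec = nca_informed_start(data, structural, error_form=error_form)
        return cls(data, spec, fix=fix, blq=blq)

    def fit(self, *, seed: int, settings: SAEMSettings | None = None,
            multistart: int = 1, polish: bool = False, prefit: bool = False,
            compute_se: bool = True) -> "PopPKResults":
        """Run SAEM, importance-sampling likelihood and the Fisher SE step.

        ``multistart > 1`` runs that many independent SAEM chains — the
        first from the model's starting values, the others from
        log-normally jittered copies — and keeps the chain with the best
        importance-sampled marginal log-likelihood before computing SEs.
        ``compute_se=False`` skips the (comparatively costly) Fisher step.
        """
        settings = settings or SAEMSettings()
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        engine = self.engine

        if prefit:
            pool_fix = tuple(set(self.fix) | {"k12_pop", "k21_pop", "a", "b"})
            candidates = prefit_candidates(self.data, self.spec, fix=pool_fix,
                                           blq=self.blq)[:max(1, multistart)]
        else:
            candidates = [self.spec]
        while len(candidates) < multistart:
            candidates.append(_jitter_spec(candidates[0], rng, sd=0.4))

        # run one SAEM chain per candidate and rank them by the deterministic
        # Laplace marginal likelihood (cheap, and free of the Monte-Carlo
        # noise that would make close calls unstable)
        best = None
        for start, spec_c in enumerate(candidates):
            if start == 0 and not prefit:
                eng = engine
            else:
                eng = _Engine(self.data, spec_c, fix=self.fix,
                              blq_policy=self.blq)
            theta_c, eta_c, history_c = _run_saem(eng, settings, rng)
            ll_c, _ = _laplace_loglik(engine, theta_c)
            if best is None or ll_c > best[0]:
                best = (ll_c, theta_c, history_c)
        if polish:
            # restart one SAEM chain from the current winner: a warm-started
            # run can leave a shallow mode the quasi-Newton step cannot
            eng = _Engine(self.data, engine.layout.to_spec(best[1]),
                          fix=self.fix, blq_policy=self.blq)
            theta_c, eta_c, history_c = _run_saem(eng, settings, rng)
            ll_c, _ = _laplace_loglik(engine, theta_c)
            if ll_c > best[0]:
                best = (ll_c, theta_c, history_c)
        _, theta, history = best
        theta, loglik, modes, sampler = _is_refine(engine, theta, rng, settings,
                                                   rounds=2, maxiter=20)
        if self.spec.structural == "oral":
            theta, loglik, modes, sampler = _profile_polish(engine, theta, rng,
                                                            settings)
        else:
            # report the likelihood with the full importance-sampling size
            sampler = _ImportanceSampler(engine, theta, modes, rng,
                                         settings.n_is,
                                         df=settings.proposal_df,
                                         scale=settings.proposal_scale)
            loglik = sampler.loglik(theta)

        free_idx = [i for i in range(theta.size) if engine.layout.free[i]]
        se_theta = np.full(theta.size, np.nan)
        if compute_se:
            if settings.fim_n_is == settings.n_is:
                fim_sampler = sampler
            else:
                fim_sampler = _ImportanceSampler(engine, theta, modes, rng,
                                                 settings.fim_n_is,
                                                 df=settings.proposal_df,
                                                 scale=settings.proposal_scale)
            fim = _empirical_fisher(fim_sampler, theta, free_idx,
                                    settings.fim_step)
            # quantities with (numerically) no information make the matrix
            # singular; invert the informative submatrix and report NaN SEs
            # for the rest rather than polluting every entry through pinv
            d = np.diag(fim)
            keep = np.flatnonzero(d > 1e-6 * max(float(d.max()), 1.0))
            if keep.size:
                try:
                    cov = np.linalg.pinv(fim[np.ix_(keep, keep)])
                    cd = np.diag(cov)
                    for j, kj in enumerate(keep):
                        if cd[j] > 0:
                            se_theta[free_idx[kj]] = math.sqrt(cd[j])
                except np.linalg.LinAlgError:
                    pass

        est, se = engine.layout.report(theta, se_theta)
        n_free = len(free_idx)
        aic = -2.0 * loglik + 2.0 * n_free

        tail = history[-min(10, len(history)):]
        step_norm = float(np.linalg.norm(tail[-1] - tail[0])) if len(tail) > 1 else 0.0

        return PopPKResults(
            model=self,
            theta=theta,
            estimates=est,
            se=se,
            loglik=loglik,
            aic=aic,
            n_free=n_free,
            eta_modes=modes,
            history=history,
            seed=seed,
            settings=settings,
            final_step_norm=step_norm,
        )

    def loglik(self, spec: PopulationModel | None = None, *, seed: int = 0,
               n_is: int = 1000) -> float:
        """Importance-sampled marginal log-likelihood at arbitrary
        population values (defaults to the model's spec)."""
        engine = self.engine if spec is None else _Engine(
            self.data, spec, fix=self.fix, blq_policy=self.blq)
        theta = engine.layout.theta0
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        modes = _eta_modes(engine, theta)
        sampler = _ImportanceSampler(engine, theta, modes, rng, n_is)
        return sampler.loglik(theta)


@dataclass
class PopPKResults:
    """Estimates, uncertainties and diagnostics of one SAEM fit."""

    model: PopPKModel
    theta: np.ndarray
    estimates: dict
    se: dict
    loglik: float
    aic: float
    n_free: int
    eta_modes: np.ndarray
    history: np.ndarray
    seed: int
    settings: SAEMSettings
    final_step_norm: float
    _iwres: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def rse(self) -> dict:
        """Relative standard errors, % (100*SE/|estimate|)."""
        out = {}
        for k, v in self.estimates.items():
            s = self.se.get(k, math.nan)
            out[k] = 100.0 * s / abs(v) if v != 0 and np.isfinite(s) else math.nan
        return out

    @property
    def fitted_spec(self) -> PopulationModel:
        """The estimates materialised as a PopulationModel."""
        return self.model.engine.layout.to_spec(self.theta)

    def summary(self) -> pd.DataFrame:
        """Parameter table in the published layout (Value / S.E. / R.S.E. %)."""
        rse = self.rse
        rows = []
        for name in self.model.engine.layout.names:
            rows.append({
                "quantity": name,
                "value": self.estimates[name],
                "se": self.se[name],
                "rse_pct": rse[name],
                "estimated": bool(self.model.engine.layout.free[
                    self.model.engine.layout.names.index(name)]),
            })
        df = pd.DataFrame(rows).set_index("quantity")
        df.attrs["loglik"] = self.loglik
        df.attrs["aic"] = self.aic
        return df

    def wald_test(self, name: str) -> tuple[float, float]:
        return wald_test(self, name)

    def iwres(self) -> pd.DataFrame:
        if self._iwres is None:
            self._iwres = compute_iwres(self)
        return self._iwres

    def vpc(self, design: StudyDesign, n_sim: int = 1000, seed: int = 0) -> "VPCResult":
        return vpc(self, design, n_sim=n_sim, seed=seed, data=self.model.data)


FitResult = PopPKResults


def _flip_spec(spec: PopulationModel) -> PopulationModel:
    """Spec-level flip-flop counterpart (oral models): exchange the
    first-site absorption and elimination rate constants, rescale the
    apparent volume to preserve the profile amplitude, and swap the
    corresponding covariate shifts."""
    fx = dict(spec.fixed_effects)
    fx["ka1"], fx["k"] = spec.fixed_effects["k"], spec.fixed_effects["ka1"]
    fx["V"] = spec.fixed_effects["V"] * fx["k"] / fx["ka1"]
    b = {(e.parameter, e.level): e.beta for e in spec.effects}
    effects = []
    for e in spec.effects:
        if e.parameter == "ka1":
            effects.append(CovariateEffect("ka1", e.level, b.get(("k", e.level), e.beta)))
        elif e.parameter == "k":
            effects.append(CovariateEffect("k", e.level, b.get(("ka1", e.level), e.beta)))
        elif e.parameter == "V":
            shift = b.get(("k", e.level), 0.0) - b.get(("ka1", e.level), 0.0)
            effects.append(CovariateEffect("V", e.level, e.beta + shift))
        else:
            effects.append(e)
    return replace(spec, fixed_effects=fx, effects=tuple(effects))


def pooled_prefit(data: list[SubjectDataset], spec: PopulationModel, *,
                  fix=(), blq: str = "exclude") -> PopulationModel:
    """Deterministic naive-pooled pre-fit.

    All random effects are removed and the fixed effects, betas and
    residual components are maximised exactly (no Monte Carlo).  For oral
    models the flip-flop counterpart of the start is tried as well and the
    better optimum kept — an exact, reproducible resolution of the
    absorption/elimination ambiguity.  Returns the input spec with its
    population values replaced by the pooled estimates (random-effect SDs
    are kept as supplied).
    """
    pooled_spec = replace(spec, random_effects=RandomEffectsSpec(sd={}, corr={}))
    pool_fix = tuple(f for f in fix if not (f.startswith("omega_")
                                            or f.startswith("corr_")))
    candidates = [pooled_spec]
    if spec.structural == "oral":
        candidates.append(_flip_spec(pooled_spec))
    best = None
    for cand in candidates:
        eng = _Engine(data, cand, fix=pool_fix, blq_policy=blq)
        theta, eta, _ = _run_saem(eng, SAEMSettings(), np.random.default_rng(0))
        nll = -eng.total_obs_ll(theta, eta)
        if best is None or nll < best[0]:
            best = (nll, eng.layout.to_spec(theta))
    fitted = best[1]
    return replace(spec,
                   fixed_effects=dict(fitted.fixed_effects),
                   effects=fitted.effects,
                   error=ResidualErrorModel(a=fitted.error.a, b=fitted.error.b,
                                            form=spec.error.form))


def prefit_candidates(data: list[SubjectDataset], spec: PopulationModel, *,
                      fix=(), blq: str = "exclude") -> list[PopulationModel]:
    """Deterministic starting candidates, ranked by Laplace likelihood.

    Each candidate is a naive-pooled pre-fit (exact, reproducible) from a
    deterministic start; the starts vary the assumed residual-error
    weighting, and for oral models also bracket the first-site absorption
    rate over a grid (absorption half-lives of roughly 2-14 h), because
    the pooled likelihood has distinct local optima on the two sides of
    the absorption/elimination ambiguity.  Distinct solutions are scored
    with the deterministic Laplace marginal likelihood of the *full*
    mixed-effects model and returned best-first.
    """
    ys = np.concatenate([s.quantifiable[1] for s in data])
    med_y = float(np.median(ys)) if ys.size else 1000.0
    weightings = [(spec.error.a, spec.error.b), (0.04 * med_y, 0.05)]
    if spec.structural == "oral":
        ka1_grid = [None, 0.05, 0.1, 0.2, 0.4]
    else:
        ka1_grid = [None]
        weightings.append((0.08 * med_y, 0.10))

    def _vec(model: PopulationModel) -> np.ndarray:
        return np.array([
            math.log(model.fixed_effects[p]) if model.transform_of(p) == LOG
            else model.fixed_effects[p] for p in model.param_names])

    solutions: list[PopulationModel] = []
    vecs: list[np.ndarray] = []
    for ka1_0 in ka1_grid:
        for a0, b0 in weightings:
            fixed = dict(spec.fixed_effects)
            if ka1_0 is not None:
                fixed["ka1"] = ka1_0
            cand = replace(spec, fixed_effects=fixed,
                           error=ResidualErrorModel(
                               a=max(a0, 1e-3), b=max(b0, 1e-4),
                               form=spec.error.form))
            pre = pooled_prefit(data, cand, fix=fix, blq=blq)
            v = _vec(pre)
            if any(np.linalg.norm(v - w) < 0.1 for w in vecs):
                continue
            solutions.append(pre)
            vecs.append(v)

    scored = []
    for pre in solutions:
        eng = _Engine(data, pre, fix=(), blq_policy=blq)
        lap, _ = _laplace_loglik(eng, eng.layout.theta0)
        scored.append((lap, pre))
    scored.sort(key=lambda c: c[0], reverse=True)
    return [pre for _, pre in scored]


def _jitter_spec(spec: PopulationModel, rng, sd: float = 0.4) -> PopulationModel:
    """Log-normally jitter the population fixed effects (on their transform
    scales) for multistart exploration; betas/Omega/error are kept."""
    fixed = {}
    for p, v in spec.fixed_effects.items():
        kind = spec.transform_of(p)
        x = float(transform_value(v, kind)) + sd * rng.standard_normal()
        fixed[p] = float(inverse_transform(x, kind))
    return replace(spec, fixed_effects=fixed)


def fit_population(data: list[SubjectDataset], spec: PopulationModel, *,
                   seed: int, settings: SAEMSettings | None = None,
                   fix=(), blq: str = "exclude") -> PopPKResults:
    """Functional wrapper: build a :class:`PopPKModel` and fit it."""
    return PopPKModel(data, spec, fix=fix, blq=blq).fit(seed=seed, settings=settings)


def wald_test(fit: PopPKResults, name: str) -> tuple[float, float]:
    """Wald z = estimate/SE and the two-sided normal p-value, on the
    reporting scale (betas are tested directly)."""
    if name not in fit.estimates:
        raise EstimationError(f"unknown quantity {name!r}")
    se = fit.se[name]
    if not np.isfinite(se) or se == 0:
        raise EstimationError(f"no usable SE for {name!r}")
    z = fit.estimates[name] / se
    p = 2.0 * (1.0 - ndtr(abs(z)))
    return float(z), float(p)


def compute_iwres(fit: PopPKResults, data: list[SubjectDataset] | None = None
                  ) -> pd.DataFrame:
    """Individual weighted residuals (y - f_ind)/sd(f_ind) at the eta modes.

    Zero residual SD with a perfect prediction yields IWRES = 0.
    """
    engine = fit.model.engine
    if data is not None and dataset_fingerprint(data) != fit.model.fingerprint:
        raise EstimationError("IWRES requested for a dataset that differs from "
                              "the fitted one")
    f = engine.predict(fit.theta, fit.eta_modes)
    a, b = engine.layout.error_ab(fit.theta)
    if engine.spec.error.form == "linear":
        sd = a + b * f
    else:
        sd = np.sqrt(a * a + (b * f) ** 2)
    y = engine.obs_y
    diff = y - f
    with np.errstate(divide="ignore", invalid="ignore"):
        iw = np.where(sd > 0, diff / np.maximum(sd, 1e-300),
                      np.where(np.abs(diff) < 1e-9, 0.0, np.inf))
    ids = [engine.subjects[i].subject_id for i in engine.obs_subj]
    return pd.DataFrame({
        "subject_id": ids,
        "time": engine.obs_t,
        "dv": y,
        "ipred": f,
        "iwres": iw,
        "censored": engine.obs_cens,
    })


@dataclass(frozen=True)
class VPCResult:
    """Visual-predictive-check bands and coverage."""

    bands: pd.DataFrame          # group, time, p5, p50, p95, n_quantifiable
    coverage: float              # fraction of observations inside the 90% band
    n_sim: int

    def plot(self, ax=None):
        """Quick band plot (one panel per group), mainly for interactive use."""
        import matplotlib.pyplot as plt

        groups = sorted(self.bands["group"].unique())
        if ax is None:
            _, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3),
                                   squeeze=False)
            axes = axes[0]
        else:
            axes = [ax] * len(groups)
        for g, a_ in zip(groups, axes):
            sub = self.bands[self.bands["group"] == g]
            a_.fill_between(sub["time"], sub["p5"], sub["p95"], alpha=0.3)
            a_.plot(sub["time"], sub["p50"])
            a_.set_title(f"group {g}")
            a_.set_xlabel("time (h)")
            a_.set_ylabel("concentration (ng/mL)")
        return axes


def vpc(fit_or_model, design: StudyDesign, n_sim: int = 1000, seed: int = 0,
        data: list[SubjectDataset] | None = None) -> VPCResult:
    """Simulate ``n_sim`` replicate studies under the (fitted) model and the
    design; report per-time 5th/50th/95th percentile bands of the
    quantifiable simulated concentrations, and the fraction of observed
    quantifiable concentrations falling inside the 90% interval.

    The LLOQ is applied to the simulations exactly as to the data, so the
    bands describe the conditional (quantifiable) predictive distribution.
    """
    if n_sim < 2:
        raise EstimationError("VPC requires n_sim >= 2")
    if isinstance(fit_or_model, PopPKResults):
        pop = fit_or_model.fitted_spec
    elif isinstance(fit_or_model, PopulationModel):
        pop = fit_or_model
    else:
        raise EstimationError("vpc expects a PopPKResults or PopulationModel")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    route_iv = pop.structural == "iv"
    rows = []
    band_lookup = {}
    for group in design.groups:
        if (group.route == ROUTE_IV) != route_iv:
            continue
        times = design.times_for(group.route)
        total = n_sim * group.n
        etas = pop.sample_etas(total, rng) if len(pop.iiv_names) else np.zeros((total, 0))
        profiles = _vpc_profiles(group, pop, times, etas)
        y = profiles + pop.error.sd(profiles) * rng.standard_normal(profiles.shape)
        for j, t in enumerate(times):
            col = y[:, j]
            quant = col[col >= design.lloq]
            if quant.size < 2:
                p5 = p50 = p95 = math.nan
            else:
                p5, p50, p95 = np.percentile(quant, [5, 50, 95])
            rows.append({"group": group.number, "time": t, "p5": p5,
                         "p50": p50, "p95": p95, "n_quantifiable": quant.size})
            band_lookup[(group.number, float(t))] = (p5, p95)
    bands = pd.DataFrame(rows)
    if not np.all(bands[["p5", "p50", "p95"]].isna().any(axis=1)
                  | ((bands["p5"] <= bands["p50"]) & (bands["p50"] <= bands["p95"]))):
        raise EstimationError("VPC band ordering violated")

    coverage = math.nan
    if data is not None:
        inside = total_n = 0
        for s in data:
            for t, dv, blq in zip(s.times, s.dv, s.blq):
                if blq:
                    continue
                band = band_lookup.get((s.group, float(t)))
                if band is None or not np.isfinite(band[0]):
                    continue
                total_n += 1
                if band[0] <= dv <= band[1]:
                    inside += 1
        coverage = inside / total_n if total_n else math.nan
    return VPCResult(bands=bands, coverage=coverage, n_sim=n_sim)


def _vpc_profiles(group, pop: PopulationModel, times: np.ndarray,
                  etas: np.ndarray) -> np.ndarray:
    """Vectorised noise-free profiles for many replicate rats of one group."""
    total = etas.shape[0]
    phi = pop.phi_population(group.level)
    names = pop.param_names
    iiv_slots = [names.index(p) for p in pop.iiv_names]
    PHI = np.tile(phi, (total, 1))
    if iiv_slots:
        PHI[:, iiv_slots] += etas
    U = np.empty_like(PHI)
    for j, p in enumerate(names):
        U[:, j] = inverse_transform(PHI[:, j], pop.transform_of(p))
    t = times[None, :]
    cols = [U[:, j][:, None] for j in range(len(names))]
    if pop.structural == "iv":
        out = iv_conc(*cols, group.rutin_eq_dose, t)
    else:
        out = oral_conc(*cols, group.rutin_eq_dose, t)
    return np.maximum(out, 0.0)


def compare_models(fits: list[PopPKResults]) -> pd.DataFrame:
    """Rank fits of the same data by AIC (ascending) with delta-AIC."""
    if not fits:
        raise EstimationError("no fits to compare")
    fp = {f.model.fingerprint for f in fits}
    if len(fp) > 1:
        raise EstimationError("model comparison requires fits on identical data")
    rows = [{"model": i, "error_form": f.model.spec.error.form,
             "structural": f.model.spec.structural,
             "n_free": f.n_free, "loglik": f.loglik, "aic": f.aic}
            for i, f in enumerate(fits)]
    df = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# NCA-informed starting values
# ---------------------------------------------------------------------------


def nca_informed_start(data: list[SubjectDataset], structural: str, *,
                       error_form: str = "linear") -> PopulationModel:
    """Build the final-model structure with data-driven initial values.

    IV: V from back-extrapolation of the earliest sample, k from NCA
    clearance over V.  Oral: the terminal slope of the reference group
    initialises ka1 (flip-flop kinetics), group Tmax ratios initialise the
    ka1 betas, group terminal-slope ratios the k betas, and the apparent
    volume is rescaled once so the predicted reference Cmax matches the
    observed one.
    """
    from .nca import nca_subject

    if structural not in ("iv", "oral"):
        raise EstimationError(f"unknown structural model {structural!r}")
    present = []
    for s in data:
        if s.level not in present:
            present.append(s.level)
    canonical = ("RU", "GEXT") if structural == "iv" else (
        "D100", "D75", "D500", "D750", "D1000")
    levels = tuple(l for l in canonical if l in present) + tuple(
        l for l in present if l not in canonical)
    if not levels:
        raise EstimationError("no covariate levels found in the data")
    ref = levels[0]

    per_level: dict[str, dict[str, list[float]]] = {
        l: {"lz": [], "tmax": [], "cl": [], "cmax": [], "cfirst": [], "dose": []}
        for l in levels}
    all_y = []
    for s in data:
        t_q, y_q = s.quantifiable
        all_y.extend(y_q.tolist())
        d = per_level[s.level]
        d["dose"].append(s.dose.amount)
        if y_q.size:
            d["cfirst"].append(1000.0 * s.dose.amount / y_q[0])
        try:
            r = nca_subject(s)
            if np.isfinite(r.lambda_z):
                d["lz"].append(r.lambda_z)
            if np.isfinite(r.cl):
                d["cl"].append(r.cl)
            d["tmax"].append(r.tmax)
            d["cmax"].append(r.cmax)
        except Exception:
            pass

    def med(vals, default):
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.median(vals)) if vals else default

    med_y = med(all_y, 1000.0)

    if structural == "iv":
        refd = per_level[ref]
        V0 = float(np.clip(med(refd["cfirst"], 0.1), 1e-3, 0.9))
        Cl0 = med(refd["cl"], 0.1)
        k0 = float(np.clip(Cl0 / V0, 0.05, 20.0))
        fixed = {"V": V0, "k": k0, "k12": k0, "k21": 4.0 * k0}
        effects = tuple(CovariateEffect(p, l, 0.0)
                        for p in ("V", "k") for l in levels[1:])
        re = RandomEffectsSpec(sd={"V": 0.2, "k": 0.2}, corr={("V", "k"): 0.0})
        err = ResidualErrorModel(a=max(1.0, 0.05 * med_y), b=0.2, form=error_form)
        return PopulationModel(structural="iv", fixed_effects=fixed,
                               covariate_axis="source", levels=levels,
                               effects=effects, random_effects=re, error=err)

    refd = per_level[ref]
    lz_ref = med(refd["lz"], 0.2)
    tmax_ref = med(refd["tmax"], 6.0)
    ka1_0 = float(np.clip(lz_ref, 0.02, 2.0))
    tlag0 = float(np.clip(tmax_ref - 2.0, 0.5, 8.0))
    effects = []
    for l in levels[1:]:
        lz_l = med(per_level[l]["lz"], lz_ref)
        tmax_l = med(per_level[l]["tmax"], tmax_ref)
        effects.append(CovariateEffect(
            "ka1", l, float(np.clip(math.log(max(tmax_ref, 1e-3)
                                             / max(tmax_l, 1e-3)), -2.0, 5.0))))
        effects.append(CovariateEffect("Tlag2", l, 0.0))
        effects.append(CovariateEffect("V", l, 0.0))
        effects.append(CovariateEffect(
            "k", l, float(np.clip(math.log(max(lz_l, 1e-4)
                                           / max(lz_ref, 1e-4)), -5.0, 2.0))))
    cl_ref = med(refd["cl"], 10.0)
    V_guess = float(np.clip(cl_ref / max(lz_ref, 1e-4), 0.5, 500.0))
    fixed = {"ka1": ka1_0, "ka2": 2.0 * ka1_0, "F1": 0.5, "Tlag2": tlag0,
             "V": V_guess, "k": 1.0, "k12": 0.3, "k21": 0.3}
    # one exact rescale of V so the predicted reference Cmax matches the
    # observed group mean (concentration is proportional to 1/V)
    cmax_obs = med(refd["cmax"], math.nan)
    dose_ref = med(refd["dose"], 100.0)
    if np.isfinite(cmax_obs) and cmax_obs > 0:
        times = np.linspace(0.01, 24.0, 400)
        pred = oral_conc(fixed["ka1"], fixed["ka2"], fixed["F1"], fixed["Tlag2"],
                         fixed["V"], fixed["k"], fixed["k12"], fixed["k21"],
                         dose_ref, times)
        cmax_pred = float(np.max(pred))
        if cmax_pred > 0:
            fixed["V"] = float(np.clip(fixed["V"] * cmax_pred / cmax_obs,
                                       0.5, 500.0))
    re = RandomEffectsSpec(sd={"ka1": 0.2, "ka2": 0.2, "F1": 0.2, "V": 0.2})
    err = ResidualErrorModel(a=max(1.0, 0.02 * med_y), b=0.15, form=error_form)
    return PopulationModel(structural="oral", fixed_effects=fixed,
                           covariate_axis="dose_group", levels=levels,
                           effects=tuple(effects), random_effects=re, error=err)
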