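"""Modified Rescorla–Wagner model of instructed fear-reversal learning.

The model tracks an expected shock value V in [0, 1] for each of the two
cues. On every trial the presented cue is updated by the delta rule

    V' = V + alpha * (lambda - V),        lambda in {0, 1},

with learning rate ``alpha``; CS− trials are ordinary updates with
lambda = 0. At each *instructed reversal* the two cue values are mixed
convexly toward each other with weight ``rho`` (instruction sensitivity):

    V_A' = rho * V_B + (1 - rho) * V_A    (and symmetrically for B),

so rho = 0 ignores the instruction and rho = 1 swaps the values fully. The
sum V_A + V_B is invariant under the instruction operator for every rho.
Initial values are free ("initFree"): the cue instructed as CS+ at the
start of the task begins at ``v0`` and the other cue at ``1 - v0``, a
one-parameter encoding of how fully the initial instruction is adopted
(v0 = 0.5 means no initial differentiation).

The trial-level physiological fear response is modelled as a noisy affine
readout of the presented cue's value,

    r_t ~ Normal(beta0 + beta1 * V_t, sigma).

Fitting is Bayesian and per subject, on unconstrained transformed scales
(logit for alpha, rho, v0; log for sigma) with Beta(1.1, 1.1) priors on the
bounded parameters, Normal(0, 5) on beta0 and beta1, and Half-Normal(5) on
sigma. Two estimators are provided: affine-invariant ensemble MCMC (emcee)
with split-R-hat / effective-sample-size diagnostics, and a fast MAP path
(profile grid over the three bounded parameters, then full joint
optimisation) used for simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import ParameterError, StructuralError
from .fear_task import TrialSchedule, validate_schedule

PARAM_NAMES = ("alpha", "rho", "v0", "beta0", "beta1", "sigma")
_BOUNDED = ("alpha", "rho", "v0")

# priors
_BETA_A = 1.1
_BETA_B = 1.1
_NORMAL_SD = 5.0
_SIGMA_SCALE = 5.0


@dataclass(frozen=True)
class RWParameters:
    """Subject-level parameters of the instructed Rescorla–Wagner model."""

    alpha: float  # learning rate, [0, 1]
    rho: float  # instruction sensitivity, [0, 1]
    v0: float  # initial value of the instructed CS+ cue, [0, 1]
    beta0: float = 0.0  # response intercept
    beta1: float = 1.0  # response gain on V
    sigma: float = 0.1  # response noise SD, > 0

    def __post_init__(self):
        for name in _BOUNDED:
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"{name}={val} outside [0, 1]")
        if self.sigma <= 0:
            raise ParameterError(f"sigma={self.sigma} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], float)


def rw_update(v: float, outcome: float, alpha: float) -> float:
    """One delta-rule update of the presented cue's expected value."""
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha={alpha} outside [0, 1]")
    return v + alpha * (outcome - v)


def apply_instruction(v_pair: tuple[float, float], rho: float) -> tuple[float, float]:
    """Revise both cue values at an instructed reversal.

    Convex mixing toward the opposite cue's value with weight ``rho``;
    preserves v_a + v_b exactly for every rho.
    """
    if not 0.0 <= rho <= 1.0:
        raise ParameterError(f"rho={rho} outside [0, 1]")
    v_a, v_b = v_pair
    return (rho * v_b + (1.0 - rho) * v_a, rho * v_a + (1.0 - rho) * v_b)


def _schedule_arrays(schedule: TrialSchedule) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Integer encoding of a schedule: cue index, outcome, instruction flag,
    and the index of the cue that starts as CS+."""
    violations = validate_schedule(schedule)
    if violations:
        raise StructuralError(f"invalid schedule: {[str(v) for v in violations[:3]]}")
    cue_idx = (schedule.cue == "B").astype(int)
    outcome = schedule.reinforced.astype(float)
    instruct = schedule.instructed_reversal_before.astype(bool)
    first_plus = int(schedule.cue[schedule.condition == "CS+"][0] == "B")
    return cue_idx, outcome, instruct, first_plus


def _simulate_values_batch(
    alpha: np.ndarray,
    rho: np.ndarray,
    v0: np.ndarray,
    cue_idx: np.ndarray,
    outcome: np.ndarray,
    instruct: np.ndarray,
    first_plus: int,
) -> np.ndarray:
    """Vectorised forward simulation for K parameter sets.

    Returns the (K, T) matrix of the presented cue's value *before* the
    trial's update (after any instruction event on that trial).
    """
    alpha = np.atleast_1d(np.asarray(alpha, float))
    rho = np.atleast_1d(np.asarray(rho, float))
    v0 = np.atleast_1d(np.asarray(v0, float))
    k = len(alpha)
    t_n = len(cue_idx)
    values = np.empty((k, 2))
    values[:, first_plus] = v0
    values[:, 1 - first_plus] = 1.0 - v0
    v_pres = np.empty((k, t_n))
    for t in range(t_n):
        if instruct[t]:
            va = rho * values[:, 1] + (1.0 - rho) * values[:, 0]
            vb = rho * values[:, 0] + (1.0 - rho) * values[:, 1]
            values[:, 0] = va
            values[:, 1] = vb
        c = cue_idx[t]
        v_c = values[:, c]
        v_pres[:, t] = v_c
        values[:, c] = v_c + alpha * (outcome[t] - v_c)
    return v_pres


@dataclass(frozen=True)
class LatentTrajectory:
    """Per-trial latent state of one simulated subject."""

    v_cue_a: np.ndarray  # value of cue A before the trial's update
    v_cue_b: np.ndarray
    v_presented: np.ndarray
    prediction_error: np.ndarray
    expected_response: np.ndarray  # beta0 + beta1 * V_presented (noiseless)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self.v_presented) + 1),
                "v_cue_a": self.v_cue_a,
                "v_cue_b": self.v_cue_b,
                "v_presented": self.v_presented,
                "prediction_error": self.prediction_error,
                "expected_response": self.expected_response,
            }
        )


def simulate_trajectory(params: RWParameters, schedule: TrialSchedule) -> LatentTrajectory:
    """Run the instructed-RW forward model over a schedule.

    At each trial: any instructed reversal first revises both cue values
    with weight rho, then the presented cue is updated by the delta rule
    with outcome = the trial's reinforcement flag.
    """
    cue_idx, outcome, instruct, first_plus = _schedule_arrays(schedule)
    t_n = len(cue_idx)
    values = np.empty(2)
    values[first_plus] = params.v0
    values[1 - first_plus] = 1.0 - params.v0
    v_a = np.empty(t_n)
    v_b = np.empty(t_n)
    v_pres = np.empty(t_n)
    pe = np.empty(t_n)
    for t in range(t_n):
        if instruct[t]:
            values = np.array(apply_instruction((values[0], values[1]), params.rho))
        v_a[t], v_b[t] = values
        c = cue_idx[t]
        v_pres[t] = values[c]
        pe[t] = outcome[t] - values[c]
        values[c] = rw_update(values[c], outcome[t], params.alpha)
    return LatentTrajectory(
        v_cue_a=v_a,
        v_cue_b=v_b,
        v_presented=v_pres,
        prediction_error=pe,
        expected_response=params.beta0 + params.beta1 * v_pres,
    )


# ---------------------------------------------------------------------------
# parameter transforms and log posterior
# ---------------------------------------------------------------------------


def _to_natural(u: np.ndarray) -> np.ndarray:
    """Unconstrained (K, 6) -> natural scale (alpha, rho, v0, beta0, beta1, sigma)."""
    th = np.array(u, float, copy=True)
    th[..., :3] = special.expit(u[..., :3])
    th[..., 5] = np.exp(u[..., 5])
    return th


def _to_unconstrained(theta: np.ndarray) -> np.ndarray:
    th = np.array(theta, float, copy=True)
    eps = 1e-9
    th[..., :3] = special.logit(np.clip(theta[..., :3], eps, 1 - eps))
    th[..., 5] = np.log(theta[..., 5])
    return th


_LN_BETA_NORM = float(special.betaln(_BETA_A, _BETA_B))
_LN_NORM_NORM = float(np.log(_NORMAL_SD * np.sqrt(2 * np.pi)))
_LN_HALFNORM_NORM = float(np.log(_SIGMA_SCALE * np.sqrt(np.pi / 2)))


def _log_prior_natural(theta: np.ndarray) -> np.ndarray:
    """Log prior density on the natural scale; theta is (K, 6).

    Beta(1.1, 1.1) on alpha/rho/v0, Normal(0, 5) on beta0/beta1,
    Half-Normal(5) on sigma; written out for speed (this sits inside the
    MCMC inner loop).
    """
    b = theta[:, :3]
    with np.errstate(divide="ignore"):
        lp = np.sum(
            (_BETA_A - 1.0) * np.log(b) + (_BETA_B - 1.0) * np.log1p(-b), axis=1
        ) - 3.0 * _LN_BETA_NORM
    lp -= 0.5 * (theta[:, 3] / _NORMAL_SD) ** 2 + _LN_NORM_NORM
    lp -= 0.5 * (theta[:, 4] / _NORMAL_SD) ** 2 + _LN_NORM_NORM
    lp += np.where(
        theta[:, 5] > 0,
        -0.5 * (theta[:, 5] / _SIGMA_SCALE) ** 2 - _LN_HALFNORM_NORM,
        -np.inf,
    )
    return lp


def _log_jacobian(u: np.ndarray) -> np.ndarray:
    """log |d theta / d u| for the sigmoid/exp transforms."""
    lj = np.zeros(u.shape[0])
    s = special.expit(u[:, :3])
    lj += np.sum(np.log(s) + np.log1p(-s), axis=1)
    lj += u[:, 5]
    return lj


class _SubjectData:
    """Responses of one subject aligned to a schedule's trial encoding."""

    def __init__(self, responses: np.ndarray, usable: np.ndarray, schedule: TrialSchedule):
        self.cue_idx, self.outcome, self.instruct, self.first_plus = _schedule_arrays(schedule)
        if len(responses) != len(self.cue_idx):
            raise StructuralError(
                f"{len(responses)} responses for a {len(self.cue_idx)}-trial schedule"
            )
        self.responses = np.asarray(responses, float)
        self.usable = np.asarray(usable, bool) & np.isfinite(self.responses)
        self.n_usable = int(self.usable.sum())

    def values(self, alpha, rho, v0) -> np.ndarray:
        return _simulate_values_batch(
            alpha, rho, v0, self.cue_idx, self.outcome, self.instruct, self.first_plus
        )

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        """Gaussian response log likelihood for (K, 6) natural-scale params."""
        theta = np.atleast_2d(theta)
        v = self.values(theta[:, 0], theta[:, 1], theta[:, 2])
        mu = theta[:, [3]] + theta[:, [4]] * v
        resid = self.responses[None, :] - mu
        sig = theta[:, [5]]
        ll_t = -0.5 * np.log(2 * np.pi) - np.log(sig) - 0.5 * (resid / sig) ** 2
        return ll_t[:, self.usable].sum(axis=1)

    def log_posterior_u(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        theta = _to_natural(u)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = self.log_likelihood(theta) + _log_prior_natural(theta) + _log_jacobian(u)
        return np.where(np.isfinite(lp), lp, -np.inf)


def _profile_linear_batch(v: np.ndarray, r: np.ndarray) -> np.ndarray:
    """ML (beta0, beta1, sigma) for each of K value trajectories (K, T)."""
    n = len(r)
    vbar = v.mean(axis=1)
    rbar = r.mean()
    var_v = np.maximum(((v - vbar[:, None]) ** 2).mean(axis=1), 1e-12)
    cov_vr = ((v - vbar[:, None]) * (r - rbar)[None, :]).mean(axis=1)
    b1 = cov_vr / var_v
    b0 = rbar - b1 * vbar
    resid = r[None, :] - (b0[:, None] + b1[:, None] * v)
    sigma = np.sqrt(np.maximum((resid**2).mean(axis=1), 1e-8))
    del n
    return np.column_stack([b0, b1, sigma])


def _minimize_batched(fun_batch, u0: np.ndarray, maxiter: int = 120):
    """L-BFGS-B with a forward-difference gradient from one vectorised call."""
    h = 1e-6

    def fun_and_grad(u):
        pts = np.vstack([u[None, :], u[None, :] + h * np.eye(6)])
        vals = fun_batch(pts)
        return vals[0], (vals[1:] - vals[0]) / h

    return optimize.minimize(
        fun_and_grad, u0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter}
    )


def _fit_map_subject(data: _SubjectData, seed: int) -> tuple[np.ndarray, float]:
    """Profile-grid initialisation followed by full joint MAP optimisation."""
    grid_a = np.linspace(0.02, 0.98, 9)
    grid_r = np.linspace(0.02, 0.98, 9)
    grid_v = np.linspace(0.05, 0.95, 5)
    aa, rr, vv = np.meshgrid(grid_a, grid_r, grid_v, indexing="ij")
    aa, rr, vv = aa.ravel(), rr.ravel(), vv.ravel()
    values = data.values(aa, rr, vv)[:, data.usable]
    r = data.responses[data.usable]
    lin = _profile_linear_batch(values, r)
    thetas = np.column_stack([aa, rr, vv, lin])
    lp = data.log_posterior_u(_to_unconstrained(thetas))
    order = np.argsort(-lp)
    rng = np.random.default_rng(seed)

    def neg_lp_batch(pts):
        return -data.log_posterior_u(pts)

    results = []
    for k in order[:2]:
        u0 = np.clip(_to_unconstrained(thetas[k][None, :])[0], -8, 8)
        res = _minimize_batched(neg_lp_batch, u0 + rng.normal(0, 1e-4, 6))
        results.append(res)
    res = min(results, key=lambda rs: rs.fun)
    return _to_natural(res.x[None, :])[0], -float(res.fun)


def _fit_mcmc_subject(
    data: _SubjectData,
    seed: int,
    n_walkers: int,
    n_steps: int,
    n_burn: int,
) -> dict:
    import emcee

    map_theta, _ = _fit_map_subject(data, seed)
    u_map = np.clip(_to_unconstrained(map_theta[None, :])[0], -6, 6)
    rng = np.random.default_rng(seed + 1)
    p0 = u_map[None, :] + rng.normal(0, 0.05, size=(n_walkers, 6))
    sampler = emcee.EnsembleSampler(
        n_walkers, 6, lambda u: data.log_posterior_u(u), vectorize=True
    )
    state = sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    del state
    chain_u = sampler.get_chain(discard=n_burn)  # (steps, walkers, 6)
    theta = _to_natural(chain_u)
    return {
        "theta": theta,
        "map": map_theta,
        "acceptance": float(np.mean(sampler.acceptance_fraction)),
    }


def _rhat_ess(chains: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-parameter R-hat and bulk ESS for a (draws, walkers, ndim) array.

    Walkers are treated as chains, the usual (slightly optimistic)
    convention for ensemble samplers.
    """
    import arviz as az

    ds = az.convert_to_dataset(chains.transpose(1, 0, 2))  # (chain, draw, dim)
    rhat = np.atleast_1d(az.rhat(ds).to_array().values.squeeze())
    ess = np.atleast_1d(az.ess(ds).to_array().values.squeeze())
    return rhat, ess


@dataclass
class InstructedRWResults:
    """Per-subject posterior summaries from :class:`InstructedRWModel.fit`.

    Attributes
    ----------
    estimates : DataFrame indexed by subject with one column block per
        parameter: ``<p>`` (posterior mean or MAP), ``<p>_median``,
        ``<p>_lo`` / ``<p>_hi`` (central 95% interval) and, for MCMC fits,
        ``<p>_rhat`` and ``<p>_ess``.
    method : "mcmc" or "map".
    converged : per-subject flag (all R-hat < 1.05 for MCMC fits).
    """

    model: "InstructedRWModel"
    estimates: pd.DataFrame
    method: str
    converged: pd.Series

    @property
    def params(self) -> pd.DataFrame:
        """Point estimates (posterior means or MAP) per subject."""
        return self.estimates[list(PARAM_NAMES)]

    def rho(self) -> pd.Series:
        return self.estimates["rho"]

    def r_squared(self) -> tuple[float, float]:
        """Marginal and conditional R² of responses on fitted expected values.

        A linear mixed model ``response ~ V_hat`` with a random intercept per
        subject; the Nakagawa–Schielzeth variance decomposition gives
        R²_marginal = var_fixed / total and R²_conditional =
        (var_fixed + var_random) / total.
        """
        import statsmodels.formula.api as smf

        frames = []
        for sid, sdata in self.model._subjects.items():
            theta = self.estimates.loc[sid, list(PARAM_NAMES)].to_numpy(float)
            v = sdata.values(theta[0], theta[1], theta[2])[0]
            frames.append(
                pd.DataFrame(
                    {
                        "subject": sid,
                        "response": sdata.responses[sdata.usable],
                        "v_hat": v[sdata.usable],
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        md = smf.mixedlm("response ~ v_hat", df, groups=df["subject"]).fit(reml=True)
        var_f = float(np.var(np.asarray(md.model.exog @ md.fe_params)))
        var_u = float(md.cov_re.iloc[0, 0])
        var_e = float(md.scale)
        total = var_f + var_u + var_e
        return var_f / total, (var_f + var_u) / total

    def summary(self) -> str:
        lines = [
            "Instructed Rescorla-Wagner fit",
            f"  method: {self.method}   subjects: {len(self.estimates)}",
            f"  converged: {int(self.converged.sum())}/{len(self.converged)}",
            "",
            "Group-level parameter means (SD):",
        ]
        for p in PARAM_NAMES:
            col = self.estimates[p]
            lines.append(f"  {p:>6}: {col.mean():7.3f} ({col.std():.3f})")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.estimates.reset_index(names="subject")


class InstructedRWModel:
    """Multi-subject instructed Rescorla–Wagner model, statsmodels style.

    Parameters
    ----------
    responses : tidy DataFrame with columns ``subject``, ``trial``,
        ``response`` and optionally ``usable`` (default: all finite
        responses usable).
    schedules : a single :class:`TrialSchedule` shared by all subjects, or a
        mapping subject -> schedule.

    Each subject is fitted independently (no pooling); group-level summaries
    are computed from the per-subject posteriors.
    """

    def __init__(self, responses: pd.DataFrame, schedules):
        required = {"subject", "trial", "response"}
        if not required <= set(responses.columns):
            raise StructuralError(f"responses table needs columns {sorted(required)}")
        self.data = responses
        self._subjects: dict = {}
        for sid, grp in responses.groupby("subject", sort=True):
            grp = grp.sort_values("trial")
            sched = schedules[sid] if isinstance(schedules, dict) else schedules
            usable = grp["usable"].to_numpy(bool) if "usable" in grp else np.ones(len(grp), bool)
            sdata = _SubjectData(grp["response"].to_numpy(float), usable, sched)
            if sdata.n_usable < 20:
                raise StructuralError(f"subject {sid!r} has {sdata.n_usable} usable trials (< 20)")
            self._subjects[sid] = sdata

    @classmethod
    def from_frame(cls, responses: pd.DataFrame, schedule_frame: pd.DataFrame):
        return cls(responses, TrialSchedule.from_frame(schedule_frame))

    def log_likelihood(self, subject, params: RWParameters) -> float:
        """Response log likelihood for one subject at given parameters."""
        return float(self._subjects[subject].log_likelihood(params.as_array()[None, :])[0])

    def fit(
        self,
        method: str = "mcmc",
        seed: int = 0,
        n_walkers: int = 24,
        n_steps: int = 2000,
        n_burn: int = 800,
        rhat_threshold: float = 1.05,
    ) -> InstructedRWResults:
        """Fit all subjects independently; returns :class:`InstructedRWResults`.

        ``method="mcmc"`` runs ensemble MCMC (default); ``method="map"``
        returns the joint posterior mode with interval columns from a local
        Gaussian (Laplace) approximation.
        """
        if method not in ("mcmc", "map"):
            raise ValueError(f"unknown method {method!r}")
        rows = []
        converged = {}
        for i, (sid, sdata) in enumerate(self._subjects.items()):
            sub_seed = (seed + 7919 * (i + 1)) % (2**31 - 1)
            if method == "map":
                theta, _ = _fit_map_subject(sdata, sub_seed)
                row = {}
                for j, p in enumerate(PARAM_NAMES):
                    row[p] = theta[j]
                    row[f"{p}_median"] = theta[j]
                    lo, hi = _laplace_interval(sdata, theta, j)
                    row[f"{p}_lo"], row[f"{p}_hi"] = lo, hi
                converged[sid] = True
            else:
                out = _fit_mcmc_subject(sdata, sub_seed, n_walkers, n_steps, n_burn)
                theta = out["theta"]  # (draws, walkers, 6)
                flat = theta.reshape(-1, 6)
                row = {}
                rhats, esses = _rhat_ess(theta)
                for j, p in enumerate(PARAM_NAMES):
                    row[p] = float(flat[:, j].mean())
                    row[f"{p}_median"] = float(np.median(flat[:, j]))
                    row[f"{p}_lo"] = float(np.quantile(flat[:, j], 0.025))
                    row[f"{p}_hi"] = float(np.quantile(flat[:, j], 0.975))
                    row[f"{p}_rhat"] = float(rhats[j])
                    row[f"{p}_ess"] = float(esses[j])
                row["acceptance"] = out["acceptance"]
                converged[sid] = bool(np.all(rhats < rhat_threshold))
            row["subject"] = sid
            rows.append(row)
        est = pd.DataFrame(rows).set_index("subject")
        conv = pd.Series(converged, name="converged")
        if not conv.all():
            bad = list(conv.index[~conv])
            # flagged, never silent: carried on the results object
            est.attrs["convergence_warning"] = f"subjects with R-hat >= {rhat_threshold}: {bad}"
        return InstructedRWResults(model=self, estimates=est, method=method, converged=conv)


def _laplace_interval(data: _SubjectData, theta: np.ndarray, j: int) -> tuple[float, float]:
    """Crude 95% interval from a numerical second derivative at the mode
    (on the unconstrained scale, mapped back)."""
    u = _to_unconstrained(theta[None, :])[0]
    h = 1e-3
    up, um = u.copy(), u.copy()
    up[j] += h
    um[j] -= h
    f0 = float(data.log_posterior_u(u[None, :])[0])
    fp = float(data.log_posterior_u(up[None, :])[0])
    fm = float(data.log_posterior_u(um[None, :])[0])
    d2 = (fp - 2 * f0 + fm) / h**2
    sd_u = 1.0 / np.sqrt(max(-d2, 1e-6))
    lo_u, hi_u = u[j] - 1.96 * sd_u, u[j] + 1.96 * sd_u
    if j < 3:
        return float(special.expit(lo_u)), float(special.expit(hi_u))
    if j == 5:
        return float(np.exp(lo_u)), float(np.exp(hi_u))
    return float(lo_u), float(hi_u)


def fit_subjects(
    responses: pd.DataFrame,
    schedules,
    method: str = "mcmc",
    seed: int = 0,
    **kwargs,
) -> InstructedRWResults:
    """Convenience wrapper: build an :class:`InstructedRWModel` and fit it."""
    return InstructedRWModel(responses, schedules).fit(method=method, seed=seed, **kwargs)


def rho_group_analysis(
    fit: InstructedRWResults,
    groups: pd.Series,
    exposures: pd.DataFrame | None = None,
    tail: str = "greater",
):
    """Group contrast and exposure regression on per-subject rho estimates.

    Parameters
    ----------
    groups : subject-indexed Series with two levels; the ``tail="greater"``
        hypothesis is that the first level (sorted) scores higher — pass the
        levels so that users sort first, or relabel.
    exposures : optional subject-indexed DataFrame of exposure composites
        and covariates; when given, rho is also regressed on all its columns.

    Returns
    -------
    (ContrastReport, RegressionReport | None)
    """
    from .survey_models import fit_adjusted_model, group_contrast

    rho = fit.estimates["rho"]
    groups = groups.reindex(rho.index)
    contrast = group_contrast(rho.to_numpy(), groups.to_numpy(), tail=tail)
    regression = None
    if exposures is not None:
        tab = exposures.reindex(rho.index).copy()
        tab["rho"] = rho
        regression = fit_adjusted_model(tab, "rho", [c for c in exposures.columns])
    return contrast, regression
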