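"""Hierarchical empirical-Bayes fitting and iBIC model comparison.

The cohort model is a two-level random-effects model: each subject's
free value-model parameters (on an unconstrained scale — log for the
positive ``j``, ``m``, ``beta``; identity for ``f``, ``w``, ``e``, ``i``)
are drawn from independent group-level Gaussians, and the group means and
variances are fitted by type-II maximum likelihood.  The marginal
likelihood of each subject's choices is approximated by Laplace's method
around the subject's MAP estimate, and the whole procedure is an EM loop:

  E-step  per-subject MAP + curvature under the current group Gaussians,
  M-step  group means/variances from the MAPs plus the posterior-variance
          correction ``sigma_p^2 = mean_s[(theta_sp - mu_p)^2 + Var_sp]``.

Candidate models (subsets of free parameters; the softmax temperature is
always free) are compared by the integrated BIC,

    iBIC = -2 * sum_s log p(choices_s | group) + n_hyper * log(n_choices),

with two hyperparameters (mean, sd) per free parameter; smaller is better.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .task import Condition
from .values import (
    CONDITION_PARAMS,
    PARAM_TRANSFORMS,
    SubjectParams,
    counts_nll,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "SubjectFit",
    "GroupFit",
    "HierarchicalChoiceModel",
    "enumerate_model_space",
    "fit_subject_map",
    "em_fit_group",
    "laplace_evidence",
    "ibic",
    "pseudo_r2",
    "compare_models",
]

#: Group-mean initialisation on the unconstrained scale (identity params at
#: their objective default, log params at log 1 = 0).
_INIT_MEAN = {"f": -12.0, "j": 0.0, "m": 0.0, "w": 0.0, "e": 0.0, "i": 0.0, "beta": 0.0}
_INIT_SD = 1.5
_VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a condition and a subset of free value parameters.

    The softmax inverse temperature is always free and is not listed in
    ``free_params``.  Disabled parameters are pinned to their objective
    defaults (f=-12, j=m=1, w=e=i=0).
    """

    condition: Condition
    free_params: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        cond = Condition(self.condition)
        object.__setattr__(self, "condition", cond)
        allowed = set(CONDITION_PARAMS[cond])
        bad = set(self.free_params) - allowed
        if bad:
            raise ValueError(f"parameters {sorted(bad)} not valid in {cond.value}")
        ordered = tuple(p for p in CONDITION_PARAMS[cond] if p in self.free_params)
        object.__setattr__(self, "free_params", ordered)
        if not self.label:
            parts = "+".join(ordered + ("beta",))
            object.__setattr__(self, "label", f"{cond.value.lower()}:{parts}")

    @property
    def theta_names(self) -> tuple[str, ...]:
        """Free parameters on the fitting scale, beta last."""
        return self.free_params + ("beta",)

    @property
    def n_free(self) -> int:
        return len(self.theta_names)

    def to_params(self, theta: np.ndarray) -> SubjectParams:
        return SubjectParams.from_unconstrained(theta, self.theta_names)


@dataclass
class SubjectFit:
    """Per-subject MAP estimate with local curvature and Laplace evidence."""

    subject_id: str
    theta_map: np.ndarray
    hessian: np.ndarray  # negative Hessian of the log-posterior (precision)
    nll: float  # -log p(choices | theta_map)
    log_evidence: float
    n_choices: int
    converged: bool = True
    message: str = ""

    @property
    def posterior_var(self) -> np.ndarray:
        return np.diag(np.linalg.inv(self.hessian))


@dataclass
class GroupFit:
    """Fitted group hyperparameters and per-subject summaries for one model."""

    spec: ModelSpec
    group_mean: np.ndarray
    group_sd: np.ndarray
    subject_fits: list[SubjectFit]
    log_evidence: float
    ibic: float
    pseudo_r2: float
    n_choices: int
    n_iter: int
    converged: bool
    trace: list[float] = field(default_factory=list)

    def subject_params(self) -> dict[str, SubjectParams]:
        return {sf.subject_id: self.spec.to_params(sf.theta_map)
                for sf in self.subject_fits}

    def to_report(self) -> dict:
        """JSON-serialisable fit report."""
        return {
            "label": self.spec.label,
            "condition": self.spec.condition.value,
            "free_params": list(self.spec.theta_names),
            "transforms": {p: PARAM_TRANSFORMS[p] for p in self.spec.theta_names},
            "group_mean": dict(zip(self.spec.theta_names, self.group_mean.tolist())),
            "group_sd": dict(zip(self.spec.theta_names, self.group_sd.tolist())),
            "subjects": {
                sf.subject_id: {
                    "theta_map": sf.theta_map.tolist(),
                    "params": self.spec.to_params(sf.theta_map).to_dict(),
                    "nll": sf.nll,
                    "log_evidence": sf.log_evidence,
                    "converged": sf.converged,
                }
                for sf in self.subject_fits
            },
            "log_evidence": self.log_evidence,
            "ibic": self.ibic,
            "pseudo_r2": self.pseudo_r2,
            "n_choices": self.n_choices,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "em_trace": self.trace,
        }


def enumerate_model_space(
    condition: Condition | str,
    candidate_params: tuple[str, ...] | None = None,
) -> list[ModelSpec]:
    """All subsets of the candidate free parameters, each with a free beta.

    Ordered deterministically by (number of parameters, label); the empty
    subset is the beta-only baseline.
    """
    condition = Condition(condition)
    if candidate_params is None:
        candidate_params = CONDITION_PARAMS[condition]
    specs = []
    for r in range(len(candidate_params) + 1):
        for combo in itertools.combinations(candidate_params, r):
            specs.append(ModelSpec(condition, combo))
    return sorted(specs, key=lambda s: (s.n_free, s.label))


# ---------------------------------------------------------------------------
# Subject-level machinery
# ---------------------------------------------------------------------------


def trial_counts(trials: pd.DataFrame) -> np.ndarray:
    """Aggregate one subject's trials into (6, 6, 3) stage-1 choice counts.

    Subjective values depend on the trial only through its task-space cell,
    so the likelihood factorises over cells; this makes each likelihood
    evaluation O(36) instead of O(n_trials).
    """
    from .task import CHOICE_INDEX

    counts = np.zeros((6, 6, 3))
    ti = trials["env_threat_level"].to_numpy(int) - 1
    ni = trials["n_tokens"].to_numpy(int) // 2 - 1
    ci = trials["stage1_choice"].map(CHOICE_INDEX).to_numpy(int)
    np.add.at(counts, (ti, ni, ci), 1.0)
    return counts


def _neg_log_posterior(theta, counts, spec, mu, sd):
    p = spec.to_params(theta)
    nll = counts_nll(counts, p, spec.condition)
    prior = 0.5 * np.sum(((theta - mu) / sd) ** 2)
    return nll + prior


def _num_hessian(fun, x, h=1e-4):
    """Central-difference Hessian; symmetric by construction."""
    d = len(x)
    H = np.empty((d, d))
    f0 = fun(x)
    for a in range(d):
        for b in range(a, d):
            ea = np.zeros(d); ea[a] = h
            eb = np.zeros(d); eb[b] = h
            if a == b:
                H[a, a] = (fun(x + ea) - 2 * f0 + fun(x - ea)) / h**2
            else:
                H[a, b] = H[b, a] = (
                    fun(x + ea + eb) - fun(x + ea - eb)
                    - fun(x - ea + eb) + fun(x - ea - eb)
                ) / (4 * h**2)
    return H


def _make_positive_definite(H: np.ndarray, floor: float = 1e-6):
    """Eigenvalue-clip to the floor; returns (H_clipped, was_below_floor)."""
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    if np.all(vals >= floor):
        return H, False
    clipped = np.clip(vals, floor, None)
    return (vecs * clipped) @ vecs.T, bool(vals.min() < -1e-3 * max(1.0, abs(vals).max()))


def fit_subject_map(
    trials_or_counts,
    spec: ModelSpec,
    group_mean: np.ndarray,
    group_sd: np.ndarray,
    n_restarts: int = 5,
    seed: int | np.random.Generator = 0,
    x0: np.ndarray | None = None,
    subject_id: str = "S",
) -> SubjectFit:
    """Per-subject MAP estimate under a Gaussian group prior (the E-step).

    Maximises ``log p(choices|theta) + log N(theta | mu, sd)`` on the
    unconstrained scale by L-BFGS from the prior mean, ``n_restarts`` prior
    draws and (optionally) a warm start ``x0``; returns the best optimum
    with the negative Hessian of the log-posterior (regularised to positive
    definite with a warning if numerically indefinite) and the subject's
    Laplace log evidence.
    """
    if isinstance(trials_or_counts, pd.DataFrame):
        if len(trials_or_counts) == 0:
            raise ValueError("cannot fit a subject with zero trials")
        counts = trial_counts(trials_or_counts)
    else:
        counts = np.asarray(trials_or_counts, dtype=float)
    n_choices = int(counts.sum())
    if n_choices == 0:
        raise ValueError("cannot fit a subject with zero trials")
    mu = np.asarray(group_mean, float)
    sd = np.asarray(group_sd, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    obj = lambda th: _neg_log_posterior(th, counts, spec, mu, sd)
    starts = [mu.copy()]
    if x0 is not None:
        starts.append(np.asarray(x0, float))
    starts += [mu + sd * rng.standard_normal(len(mu)) for _ in range(n_restarts)]

    best = None
    n_fail = 0
    for s in starts:
        res = minimize(obj, s, method="L-BFGS-B")
        if not res.success:
            n_fail += 1
        if best is None or res.fun < best.fun:
            best = res
    converged = best is not None and np.isfinite(best.fun)
    if not converged:
        raise RuntimeError(f"subject {subject_id}: optimisation failed on all starts")
    if n_fail == len(starts):
        warnings.warn(f"subject {subject_id}: no start reported clean convergence; "
                      "keeping the best point found", RuntimeWarning)

    # Curvature = (PSD-clipped) likelihood Hessian + exact prior precision.
    # Clipping the likelihood part at zero keeps the posterior precision at
    # least as large as the prior's, so the Laplace variance can never
    # exceed the prior variance — weakly identified directions fall back to
    # the prior instead of exploding.
    nll_fun = lambda th: counts_nll(counts, spec.to_params(th), spec.condition)
    H_lik = _num_hessian(nll_fun, best.x)
    H_lik, was_indef = _make_positive_definite(H_lik, floor=0.0)
    if was_indef:
        warnings.warn(f"subject {subject_id}: indefinite likelihood curvature "
                      "clipped to PSD", RuntimeWarning)
    H = H_lik + np.diag(1.0 / sd**2)
    p_map = spec.to_params(best.x)
    nll = counts_nll(counts, p_map, spec.condition)
    fit = SubjectFit(
        subject_id=subject_id,
        theta_map=best.x,
        hessian=H,
        nll=nll,
        log_evidence=0.0,
        n_choices=n_choices,
        converged=n_fail < len(starts),
        message=str(best.message),
    )
    fit.log_evidence = laplace_evidence(fit, mu, sd)
    return fit


def laplace_evidence(
    subject_fit: SubjectFit, group_mean: np.ndarray, group_sd: np.ndarray
) -> float:
    """Laplace approximation to a subject's log marginal likelihood.

    log p(choices|group) ~= log p(choices|theta_MAP) + log p(theta_MAP|group)
                            + (d/2) log 2*pi - 1/2 log det(curvature).
    """
    mu = np.asarray(group_mean, float)
    sd = np.asarray(group_sd, float)
    d = len(mu)
    if d == 0:
        return -subject_fit.nll
    theta = subject_fit.theta_map
    log_prior = float(
        -0.5 * np.sum(((theta - mu) / sd) ** 2)
        - np.sum(np.log(sd)) - 0.5 * d * np.log(2 * np.pi)
    )
    sign, logdet = np.linalg.slogdet(subject_fit.hessian)
    if sign <= 0:
        raise np.linalg.LinAlgError("curvature not positive definite")
    return -subject_fit.nll + log_prior + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet


def ibic(total_log_evidence: float, n_hyper: int, n_total_choices: int) -> float:
    """Integrated BIC: ``-2 * evidence + n_hyper * log(n_choices)``."""
    return -2.0 * total_log_evidence + n_hyper * np.log(n_total_choices)


def pseudo_r2(total_nll: float, n_choices: int, n_options: int = 3) -> float:
    """McFadden pseudo-r^2 against the uniform chance model.

    ``1 - NLL_model / NLL_chance`` with ``NLL_chance = n * log(n_options)``;
    0 at chance, 1 for perfectly predicted deterministic data.
    """
    return 1.0 - total_nll / (n_choices * np.log(n_options))


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------


class HierarchicalChoiceModel(BaseEstimator):
    """Hierarchical random-effects fit of the subjective-value choice model.

    scikit-learn-style estimator: ``fit`` takes a trial-log DataFrame for a
    cohort (one condition; one row per trial, the canonical schema of
    :mod:`aactask.task`) and runs empirical-Bayes EM.  Group-level
    hyperparameters and per-subject MAP estimates are exposed as fitted
    attributes; ``predict_proba`` returns per-trial stage-1 choice
    probabilities under each subject's MAP parameters.

    Parameters
    ----------
    condition : str
        "APAV" or "APAP"; trials must match.
    free_params : tuple of str
        Free value parameters (subset valid for the condition); the softmax
        temperature is always free in addition.
    max_iter : int
        Maximum EM iterations.
    tol : float
        Convergence threshold on the largest absolute hyperparameter change.
    n_restarts : int
        Prior draws added to the deterministic starts of each subject MAP
        optimisation in the first E-step (later E-steps warm-start).
    random_state : int or None
        Seed for the restart draws.

    Attributes
    ----------
    group_mean_, group_sd_ : ndarray
        Fitted group Gaussians on the unconstrained scale, beta last.
    subject_fits_ : list of SubjectFit
    log_evidence_ : float
        Total Laplace evidence across subjects.
    ibic_ : float
    pseudo_r2_ : float
    n_iter_ : int
    converged_ : bool
    trace_ : list of float
        Total evidence after each EM iteration.
    """

    def __init__(
        self,
        condition: str = "APAV",
        free_params: tuple[str, ...] = (),
        max_iter: int = 200,
        tol: float = 1e-3,
        n_restarts: int = 5,
        var_floor: float = _VAR_FLOOR,
        random_state: int | None = 0,
    ):
        self.condition = condition
        self.free_params = free_params
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.var_floor = var_floor
        self.random_state = random_state

    @property
    def spec_(self) -> ModelSpec:
        return ModelSpec(Condition(self.condition), tuple(self.free_params))

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalChoiceModel":
        """Run EM on a cohort trial log.  Requires >= 2 subjects."""
        spec = self.spec_
        subjects = sorted(X["subject_id"].unique())
        if len(subjects) < 2:
            raise ValueError("hierarchical fitting requires at least 2 subjects")
        counts = {s: trial_counts(X[X["subject_id"] == s]) for s in subjects}
        d = spec.n_free
        mu = np.array([_INIT_MEAN[p] for p in spec.theta_names])
        sd = np.full(d, _INIT_SD)
        rng = np.random.default_rng(self.random_state)

        fits: dict[str, SubjectFit] = {}
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # E-step: MAP + curvature per subject (warm-started after iter 1)
            for s in subjects:
                fits[s] = fit_subject_map(
                    counts[s], spec, mu, sd,
                    n_restarts=self.n_restarts if it == 1 else 0,
                    seed=rng, subject_id=str(s),
                    x0=None if it == 1 else fits[s].theta_map,
                )
            total_ev = sum(f.log_evidence for f in fits.values())
            if trace and total_ev < trace[-1] - 1e-6:
                logger.warning(
                    "EM evidence decreased at iteration %d (%.4f -> %.4f)",
                    it, trace[-1], total_ev,
                )
            trace.append(total_ev)
            # M-step: Gaussian moments of the MAPs + posterior-variance correction
            thetas = np.array([fits[s].theta_map for s in subjects])
            pvars = np.array([fits[s].posterior_var for s in subjects])
            mu_new = thetas.mean(axis=0)
            var_new = ((thetas - mu_new) ** 2 + pvars).mean(axis=0)
            sd_new = np.sqrt(np.maximum(var_new, self.var_floor))
            delta = max(np.abs(mu_new - mu).max(), np.abs(sd_new - sd).max())
            mu, sd = mu_new, sd_new
            if delta < self.tol:
                converged = True
                break
        if not converged:
            logger.warning("EM did not converge in %d iterations (last delta above tol)",
                           self.max_iter)

        # final E-step so evidences are consistent with the final hyperparameters
        for s in subjects:
            fits[s] = fit_subject_map(
                counts[s], spec, mu, sd, n_restarts=0, seed=rng,
                subject_id=str(s), x0=fits[s].theta_map,
            )
        self.group_mean_ = mu
        self.group_sd_ = sd
        self.subject_fits_ = [fits[s] for s in subjects]
        self.log_evidence_ = float(sum(f.log_evidence for f in self.subject_fits_))
        n_choices = int(sum(f.n_choices for f in self.subject_fits_))
        self.n_choices_ = n_choices
        self.ibic_ = float(ibic(self.log_evidence_, 2 * d, n_choices))
        total_nll = float(sum(f.nll for f in self.subject_fits_))
        self.pseudo_r2_ = float(pseudo_r2(total_nll, n_choices))
        self.n_iter_ = it
        self.converged_ = converged
        self.trace_ = trace
        return self

    def _check_fitted(self):
        if not hasattr(self, "group_mean_"):
            raise RuntimeError("model is not fitted")

    def subject_params_(self) -> dict[str, SubjectParams]:
        self._check_fitted()
        spec = self.spec_
        return {f.subject_id: spec.to_params(f.theta_map) for f in self.subject_fits_}

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-trial stage-1 choice probabilities under each subject's MAP."""
        self._check_fitted()
        from .values import value_grids, choice_probs

        params = self.subject_params_()
        out = np.empty((len(X), 3))
        ti = X["env_threat_level"].to_numpy(int) - 1
        ni = X["n_tokens"].to_numpy(int) // 2 - 1
        for s, p in params.items():
            mask = (X["subject_id"] == s).to_numpy()
            if not mask.any():
                continue
            V, _, _, _ = value_grids(Condition(self.condition), p)
            probs = choice_probs(V, p.beta)  # (6,6,3)
            out[mask] = probs[ti[mask], ni[mask]]
        return out

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per choice under the subject MAPs."""
        self._check_fitted()
        from .task import CHOICE_INDEX

        probs = self.predict_proba(X)
        ci = X["stage1_choice"].map(CHOICE_INDEX).to_numpy(int)
        return float(np.log(probs[np.arange(len(X)), ci]).mean())

    def group_fit_(self) -> GroupFit:
        """Bundle the fitted state into a :class:`GroupFit` record."""
        self._check_fitted()
        return GroupFit(
            spec=self.spec_,
            group_mean=self.group_mean_,
            group_sd=self.group_sd_,
            subject_fits=self.subject_fits_,
            log_evidence=self.log_evidence_,
            ibic=self.ibic_,
            pseudo_r2=self.pseudo_r2_,
            n_choices=self.n_choices_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            trace=self.trace_,
        )


def em_fit_group(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    max_iter: int = 200,
    tol: float = 1e-3,
    n_restarts: int = 5,
    random_state: int | None = 0,
) -> GroupFit:
    """Functional wrapper: fit one model spec to a cohort trial log."""
    est = HierarchicalChoiceModel(
        condition=spec.condition.value,
        free_params=spec.free_params,
        max_iter=max_iter,
        tol=tol,
        n_restarts=n_restarts,
        random_state=random_state,
    )
    est.fit(cohort)
    return est.group_fit_()


def compare_models(
    cohort: pd.DataFrame,
    specs: list[ModelSpec],
    random_state: int | None = 0,
    **fit_kw,
) -> pd.DataFrame:
    """Fit every candidate spec and rank by iBIC.

    Returns a DataFrame (one row per spec, sorted by iBIC with the winner
    first) with columns label, n_free, n_hyper, ibic, delta_ibic,
    pseudo_r2, log_evidence, converged.  Ties break toward fewer
    hyperparameters, then label order.
    """
    if not specs:
        raise ValueError("at least one model spec is required")
    rows = []
    for spec in specs:
        gf = em_fit_group(cohort, spec, random_state=random_state, **fit_kw)
        rows.append({
            "label": spec.label,
            "n_free": spec.n_free,
            "n_hyper": 2 * spec.n_free,
            "ibic": gf.ibic,
            "pseudo_r2": gf.pseudo_r2,
            "log_evidence": gf.log_evidence,
            "converged": gf.converged,
        })
    table = pd.DataFrame(rows)
    table.sort_values(["ibic", "n_hyper", "label"], inplace=True, kind="stable")
    table["delta_ibic"] = table["ibic"] - table["ibic"].iloc[0]
    table.reset_index(drop=True, inplace=True)
    return table
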