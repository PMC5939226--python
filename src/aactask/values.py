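"""Subjective-value choice model for both task conditions.

A subject's stage-1 choice among accept/no-bomb, reject/bomb and explore is
driven by subjective action values built from a distorted estimate of the
activated-bomb probability,

    a = EnvThreat**j * n / 12,

where ``j`` is a power-law distortion of the threat prior.  Exploration
uncovers half of the sites, so an activated bomb is seen with probability
``a/2``; if nothing is seen the Bayes posterior of an activated bomb is
``k = (a/2) / (1 - a/2)``, distorted by a second exponent ``m``.  In the
approach-avoidance condition the perceived loss ``f`` (objectively -12
tokens) weights the bomb outcome; in the approach-approach condition an
exploration over-valuation ``e`` and a post-null-reveal accept bonus ``i``
may apply.  ``w`` scales an exploration bonus per bit of entropy of ``a``,
and the three values pass through a softmax with inverse temperature
``beta``.  All values are in token units; the explore fee is 2 tokens.

Parameter defaults recover the objective-value agent
(f=-12, j=m=1, w=e=i=0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import (
    CHOICE_INDEX,
    EXPLORE_FEE_TOKENS,
    LOSS_TOKENS,
    Choice,
    Condition,
    Gamble,
    binary_entropy,
    ev_true,
)

__all__ = [
    "SubjectParams",
    "ActionValues",
    "PARAM_NAMES",
    "PARAM_TRANSFORMS",
    "params_for_condition",
    "subjective_p",
    "posterior_no_see",
    "action_values",
    "values_apav",
    "values_apap",
    "value_grids",
    "choice_probs",
    "negative_log_likelihood",
    "trial_latents",
    "stage2_policy",
]

#: All free-parameter names, in canonical order.
PARAM_NAMES = ("f", "j", "m", "w", "e", "i", "beta")

#: Fitting-scale transform per parameter: "log" parameters are positive and
#: fitted as their logarithm; "identity" parameters are unconstrained reals.
PARAM_TRANSFORMS = {
    "f": "identity",
    "j": "log",
    "m": "log",
    "w": "identity",
    "e": "identity",
    "i": "identity",
    "beta": "log",
}

#: Parameters meaningful per condition (beta is always free and applies to both).
CONDITION_PARAMS = {
    Condition.APAV: ("f", "j", "m", "w"),
    Condition.APAP: ("j", "m", "w", "e", "i"),
}


@dataclass(frozen=True)
class SubjectParams:
    """One subject's value-model parameters for one condition.

    Attributes
    ----------
    f : float
        Perceived magnitude of the fixed loss, token units (Ap/Av only).
        Objectively -12.
    j : float
        Power-law distortion exponent of the environmental threat, > 0.
    m : float
        Power-law distortion exponent of the no-see posterior ``k``, > 0.
    w : float
        Exploration bonus per bit of entropy of ``a``.
    e : float
        Additive exploration over-valuation, tokens (Ap/Ap only).
    i : float
        Stage-2 accept bonus after a null reveal, tokens (Ap/Ap only).
    beta : float
        Softmax inverse temperature, >= 0.
    """

    f: float = LOSS_TOKENS
    j: float = 1.0
    m: float = 1.0
    w: float = 0.0
    e: float = 0.0
    i: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.j <= 0 or self.m <= 0:
            raise ValueError("distortion exponents j, m must be > 0")
        if self.beta < 0:
            raise ValueError("softmax inverse temperature beta must be >= 0")

    def to_unconstrained(self, free: tuple[str, ...]) -> np.ndarray:
        """Map the listed free parameters onto the unconstrained fit scale."""
        out = []
        for name in free:
            v = getattr(self, name)
            out.append(np.log(v) if PARAM_TRANSFORMS[name] == "log" else v)
        return np.asarray(out, dtype=float)

    @classmethod
    def from_unconstrained(
        cls, theta: np.ndarray, free: tuple[str, ...], **fixed
    ) -> "SubjectParams":
        """Inverse of :meth:`to_unconstrained`; unlisted parameters keep defaults."""
        kw = dict(fixed)
        for name, t in zip(free, np.asarray(theta, dtype=float)):
            if PARAM_TRANSFORMS[name] == "log":
                # clip so extreme optimiser probes stay finite
                kw[name] = float(np.exp(np.clip(t, -30.0, 30.0)))
            else:
                kw[name] = float(t)
        return cls(**kw)

    def replace(self, **kw) -> "SubjectParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}


def params_for_condition(condition: Condition | str) -> tuple[str, ...]:
    """Names of the value parameters applicable to a condition (beta excluded)."""
    return CONDITION_PARAMS[Condition(condition)]


@dataclass(frozen=True)
class ActionValues:
    """Subjective values of the three stage-1 actions plus intermediates."""

    v_accept_nobomb: float
    v_reject_bomb: float
    v_explore: float
    a: float  # subjective P(ActBomb)
    k: float  # posterior after a null reveal (undistorted)
    u: float  # entropy of a, bits

    def as_array(self) -> np.ndarray:
        return np.array([self.v_accept_nobomb, self.v_reject_bomb, self.v_explore])


def subjective_p(env_threat, n_tokens, j: float = 1.0):
    """Subjective activated-bomb probability ``a = EnvThreat**j * n / 12``.

    Clamped to [0, 1]; reduces to the objective ``P(ActBomb)`` at ``j=1``.
    """
    if j <= 0:
        raise ValueError("j must be > 0")
    env_threat = np.asarray(env_threat, dtype=float)
    n_tokens = np.asarray(n_tokens, dtype=float)
    a = np.clip(env_threat ** j * n_tokens / 12.0, 0.0, 1.0)
    return float(a) if a.ndim == 0 else a


def posterior_no_see(a):
    """Bayes posterior of an activated bomb after exploration reveals nothing.

    Exploration uncovers half of the sites, so P(see | activated) = 1/2 and

        k = P(act | no see) = (a/2) / (1 - a/2).
    """
    a = np.asarray(a, dtype=float)
    k = (a / 2.0) / (1.0 - a / 2.0)
    return float(k) if k.ndim == 0 else k


def _values_apav_arrays(a, n, p: SubjectParams):
    """Vectorised Ap/Av action values; returns (v_acc, v_rej, v_exp, k, u)."""
    u = _entropy_grid(a)
    k = posterior_no_see(a)
    km = k ** p.m
    v_accept = a * p.f + (1 - a) * n
    v_nosee = np.maximum(km * p.f + (1 - km) * n, 0.0)  # rejected if <= 0
    v_explore = (1 - a / 2.0) * v_nosee - EXPLORE_FEE_TOKENS + u * p.w
    return v_accept, np.zeros_like(np.asarray(a, float)), v_explore, k, u


def _values_apap_arrays(a, n, p: SubjectParams):
    """Vectorised Ap/Ap action values; returns (v_nobomb, v_bomb, v_exp, k, u)."""
    u = _entropy_grid(a)
    k = posterior_no_see(a)
    km = k ** p.m
    v_nobomb = (1 - a) * n
    v_bomb = a * n
    v_s2_accept = (1 - km) * n + p.i
    v_s2_reject = km * n
    # strict inequality as stated: ties resolve to the bomb/reject guess
    v_nosee = np.where(v_s2_accept > v_s2_reject, v_s2_accept, v_s2_reject)
    v_explore = (a / 2.0) * n + (1 - a / 2.0) * v_nosee - EXPLORE_FEE_TOKENS + p.e + u * p.w
    return v_nobomb, v_bomb, v_explore, k, u


def values_apav(gamble: Gamble, params: SubjectParams) -> ActionValues:
    """Subjective action values in the approach-avoidance condition.

    V(Accept) = a*f + (1-a)*n;  V(Reject) = 0;
    V(Explore) = (1 - a/2) * max(k^m*f + (1-k^m)*n, 0) - 2 + u*w,
    where a seen bomb is always rejected (V(See) = 0).
    """
    a = subjective_p(gamble.env_threat, gamble.n_tokens, params.j)
    va, vr, ve, k, u = _values_apav_arrays(a, gamble.n_tokens, params)
    return ActionValues(float(va), float(vr), float(ve), float(a), float(k), float(u))


def values_apap(gamble: Gamble, params: SubjectParams) -> ActionValues:
    """Subjective action values in the approach-approach condition.

    V(NoBomb) = (1-a)*n;  V(Bomb) = a*n;  a seen bomb is a guaranteed
    correct "bomb" guess (V(See) = n);  after a null reveal the better of
    V_Stage2Accept = (1-k^m)*n + i and V_Stage2Reject = k^m*n is taken.
    """
    a = subjective_p(gamble.env_threat, gamble.n_tokens, params.j)
    va, vr, ve, k, u = _values_apap_arrays(a, gamble.n_tokens, params)
    return ActionValues(float(va), float(vr), float(ve), float(a), float(k), float(u))


def action_values(gamble: Gamble, params: SubjectParams) -> ActionValues:
    """Dispatch on the gamble's condition."""
    if gamble.condition is Condition.APAV:
        return values_apav(gamble, params)
    return values_apap(gamble, params)


# Precomputed 6x6 threat/token meshes (threat-major), shared by the grid
# evaluators; the likelihood is evaluated on this grid thousands of times
# inside the hierarchical fit.
def _grid_mesh():
    from .task import ENV_THREAT_LEVELS, N_TOKEN_LEVELS

    return np.meshgrid(ENV_THREAT_LEVELS, N_TOKEN_LEVELS.astype(float), indexing="ij")


_GRID_T, _GRID_N = _grid_mesh()


def _entropy_grid(a: np.ndarray) -> np.ndarray:
    # fast binary entropy for the hot path; exact 0 at the endpoints
    p = np.clip(a, 1e-300, 1.0)
    q = np.clip(1.0 - a, 1e-300, 1.0)
    h = -(p * np.log2(p) + q * np.log2(q))
    return np.where((a <= 0.0) | (a >= 1.0), 0.0, h)


def value_grids(condition: Condition | str, params: SubjectParams):
    """Subjective values over the whole 6x6 grid.

    Returns ``(V, a, k, u)`` where ``V`` has shape (6, 6, 3) — threat level
    by token level by action, in canonical action order.
    """
    condition = Condition(condition)
    a = np.clip(_GRID_T ** params.j * _GRID_N / 12.0, 0.0, 1.0)
    fn = _values_apav_arrays if condition is Condition.APAV else _values_apap_arrays
    va, vr, ve, k, u = fn(a, _GRID_N, params)
    V = np.empty(a.shape + (3,))
    V[..., 0], V[..., 1], V[..., 2] = va, vr, ve
    return V, a, k, u


def choice_probs(values, beta: float) -> np.ndarray:
    """Softmax choice probabilities over the stage-1 actions.

    ``p_c \\propto exp(beta * V_c)``, computed with max-subtraction so large
    values cannot overflow.  ``beta=0`` yields the uniform distribution.
    Works on an :class:`ActionValues`, a length-3 vector, or an (..., 3)
    array of values.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if isinstance(values, ActionValues):
        values = values.as_array()
    v = np.asarray(values, dtype=float) * beta
    v = v - v.max(axis=-1, keepdims=True)
    ev = np.exp(v)
    return ev / ev.sum(axis=-1, keepdims=True)


def _trial_arrays(trials: pd.DataFrame):
    threat = trials["env_threat_level"].to_numpy(float) / 6.0
    n = trials["n_tokens"].to_numpy(float)
    return threat, n


def negative_log_likelihood(
    trials: pd.DataFrame,
    params: SubjectParams,
    condition: Condition | str | None = None,
) -> float:
    """Summed -log p of the observed stage-1 choices under ``params``.

    Stage-2 choices do not enter the likelihood: the value recursion fixes
    the stage-2 policy deterministically, so they carry no information about
    the parameters.  All trials must share one condition and have a stage-1
    choice recorded.
    """
    if len(trials) == 0:
        raise ValueError("cannot evaluate the likelihood of an empty dataset")
    conds = trials["condition"].unique()
    if condition is not None:
        condition = Condition(condition)
        if set(conds) - {condition.value}:
            raise ValueError(f"trials contain conditions {conds}, expected {condition}")
    elif len(conds) > 1:
        raise ValueError("trials mix conditions; pass them separately")
    else:
        condition = Condition(conds[0])
    if trials["stage1_choice"].isna().any():
        raise ValueError("all trials must have a stage-1 choice")

    V, _, _, _ = value_grids(condition, params)
    logp = _log_softmax(V * params.beta)  # (6, 6, 3)
    ti = trials["env_threat_level"].to_numpy(int) - 1
    ni = trials["n_tokens"].to_numpy(int) // 2 - 1
    ci = trials["stage1_choice"].map(CHOICE_INDEX).to_numpy(int)
    return float(-logp[ti, ni, ci].sum())


def _log_softmax(bv: np.ndarray) -> np.ndarray:
    bv = bv - bv.max(axis=-1, keepdims=True)
    return bv - np.log(np.exp(bv).sum(axis=-1, keepdims=True))


def counts_nll(counts: np.ndarray, params: SubjectParams, condition: Condition) -> float:
    """NLL from a (6, 6, 3) choice-count array — O(36) per evaluation.

    Equivalent to :func:`negative_log_likelihood` on the trials the counts
    were aggregated from; used heavily inside the hierarchical fit.
    """
    V, _, _, _ = value_grids(condition, params)
    logp = _log_softmax(V * params.beta)
    return float(-(counts * logp).sum())


def stage2_policy(
    condition: Condition | str,
    gamble_a: float,
    n_tokens: float,
    params: SubjectParams,
    saw_bomb: bool,
) -> Choice:
    """Deterministic stage-2 decision after exploring.

    A seen activated bomb forces reject/"bomb".  After a null reveal the
    Ap/Av subject accepts iff ``k^m*f + (1-k^m)*n > 0`` and the Ap/Ap
    subject guesses no-bomb iff ``(1-k^m)*n + i > k^m*n``.
    """
    condition = Condition(condition)
    if saw_bomb:
        return Choice.REJECT_BOMB
    km = posterior_no_see(gamble_a) ** params.m
    if condition is Condition.APAV:
        inner = km * params.f + (1 - km) * n_tokens
        return Choice.ACCEPT_NOBOMB if inner > 0 else Choice.REJECT_BOMB
    accept = (1 - km) * n_tokens + params.i
    reject = km * n_tokens
    return Choice.ACCEPT_NOBOMB if accept > reject else Choice.REJECT_BOMB


def trial_latents(trials: pd.DataFrame, params: SubjectParams) -> pd.DataFrame:
    """Model-derived latent quantities per trial (the fMRI hand-off table).

    Columns: the subjective probability ``a`` and its entropy ``u``, the
    objective ``ev_true``, the three action values, the value of the chosen
    option, the best unchosen value, their difference
    (``V(Chosen) - V(Best Unchosen)``), and a ``rejected`` flag (reject in
    Ap/Av, "bomb" in Ap/Ap) for the choice-by-value-difference split.
    """
    if trials["stage1_choice"].isna().any():
        raise ValueError("latents require completed stage-1 choices")
    conds = trials["condition"].unique()
    frames = []
    for cond in conds:
        condition = Condition(cond)
        sub = trials[trials["condition"] == cond]
        V, a, k, u = value_grids(condition, params)
        ev_grid = np.empty((6, 6))
        from .task import ENV_THREAT_LEVELS, N_TOKEN_LEVELS

        for r, t in enumerate(ENV_THREAT_LEVELS):
            for c, n in enumerate(N_TOKEN_LEVELS):
                ev_grid[r, c] = ev_true(Gamble(float(t), int(n), condition))
        ti = sub["env_threat_level"].to_numpy(int) - 1
        ni = sub["n_tokens"].to_numpy(int) // 2 - 1
        ci = sub["stage1_choice"].map(CHOICE_INDEX).to_numpy(int)
        vals = V[ti, ni]  # (n_trials, 3)
        v_chosen = vals[np.arange(len(sub)), ci]
        masked = vals.copy()
        masked[np.arange(len(sub)), ci] = -np.inf
        v_best_unchosen = masked.max(axis=1)
        out = sub[["subject_id", "trial_index", "condition",
                   "env_threat_level", "n_tokens", "stage1_choice"]].copy()
        out["a"] = a[ti, ni]
        out["u"] = u[ti, ni]
        out["ev_true"] = ev_grid[ti, ni]
        out["v_accept_nobomb"] = vals[:, 0]
        out["v_reject_bomb"] = vals[:, 1]
        out["v_explore"] = vals[:, 2]
        out["v_chosen"] = v_chosen
        out["v_best_unchosen"] = v_best_unchosen
        out["value_difference"] = v_chosen - v_best_unchosen
        out["rejected"] = (ci == CHOICE_INDEX[Choice.REJECT_BOMB]).astype(int)
        frames.append(out)
    result = pd.concat(frames)
    return result.sort_index()
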