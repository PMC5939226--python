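"""Objective task model for the 6x6 bomb-gamble paradigm.

The task crosses six environmental-threat levels (the background colour cues
a prior probability 1/6..1 that a bomb was planted somewhere in a 12-site
array) with six token counts (2, 4, ..., 12 activated tokens).  A planted
bomb sits uniformly at one of the 12 sites and is *activated* only if it
lies under an activated token, so

    P(ActBomb) = EnvThreat * n_tokens / 12.

Two interleaved conditions share this grid.  In the approach-avoidance
condition (Ap/Av) accepting wins 10 p per token unless an activated bomb is
present (fixed loss of 120 p), rejecting is worth nothing, and a 20 p fee
buys exploration: half of the sites are revealed, so an activated bomb is
seen with probability 1/2.  In the approach-approach control (Ap/Ap) the
subject instead guesses whether an activated bomb is present and wins
10 p per token for a correct guess, with no possible loss; exploration works
identically.  Model-level values are in token units (1 token = 10 p, the
fixed loss = -12 tokens, the explore fee = 2 tokens).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Choice",
    "Gamble",
    "TaskSpaceGrid",
    "ENV_THREAT_LEVELS",
    "N_TOKEN_LEVELS",
    "TOKEN_VALUE_PENCE",
    "LOSS_TOKENS",
    "EXPLORE_FEE_TOKENS",
    "p_act_bomb",
    "binary_entropy",
    "ev_true",
    "make_task_space",
    "all_gambles",
    "generate_session",
    "resolve_outcome",
]

#: The six background-colour threat priors, Methods grid 1/6 .. 1.
ENV_THREAT_LEVELS: np.ndarray = np.arange(1, 7) / 6.0
#: The six activated-token counts ("1 to 6 pairs").
N_TOKEN_LEVELS: np.ndarray = np.arange(2, 13, 2)

TOKEN_VALUE_PENCE = 10
LOSS_PENCE = -120
LOSS_TOKENS = -12.0
EXPLORE_FEE_PENCE = 20
EXPLORE_FEE_TOKENS = 2.0
N_SITES = 12


class Condition(str, enum.Enum):
    """Task condition: approach-avoidance or the approach-approach control."""

    APAV = "APAV"
    APAP = "APAP"


class Choice(str, enum.Enum):
    """Stage-1 (and stage-2) actions.

    ``ACCEPT_NOBOMB`` means "accept" in Ap/Av and "guess no bomb" in Ap/Ap;
    ``REJECT_BOMB`` means "reject" / "guess bomb"; ``EXPLORE`` pays the fee
    to reveal half of the sites (stage 1 only).
    """

    ACCEPT_NOBOMB = "ACCEPT_NOBOMB"
    REJECT_BOMB = "REJECT_BOMB"
    EXPLORE = "EXPLORE"


#: Canonical action ordering used by every probability triple in the package.
CHOICE_ORDER = (Choice.ACCEPT_NOBOMB, Choice.REJECT_BOMB, Choice.EXPLORE)
CHOICE_INDEX = {c: i for i, c in enumerate(CHOICE_ORDER)}
CHOICE_INDEX.update({c.value: i for i, c in enumerate(CHOICE_ORDER)})


@dataclass(frozen=True)
class Gamble:
    """One cell of the 6x6 task space.

    Parameters
    ----------
    env_threat : float
        Prior probability that a bomb was planted; one of {1/6, ..., 1}.
    n_tokens : int
        Number of activated tokens; one of {2, 4, ..., 12}.
    condition : Condition
        Which condition the gamble is played under (affects values only).
    """

    env_threat: float
    n_tokens: int
    condition: Condition = Condition.APAV

    def __post_init__(self) -> None:
        if not 0.0 < self.env_threat <= 1.0:
            raise ValueError(f"env_threat must be in (0, 1], got {self.env_threat}")
        if self.n_tokens not in set(int(n) for n in N_TOKEN_LEVELS):
            raise ValueError(f"n_tokens must be in {{2,4,...,12}}, got {self.n_tokens}")

    @property
    def p_act_bomb(self) -> float:
        return p_act_bomb(self.env_threat, self.n_tokens)

    @property
    def entropy(self) -> float:
        return float(binary_entropy(self.p_act_bomb))

    @property
    def env_threat_level(self) -> int:
        """1-based index of the threat level (1..6)."""
        return int(round(self.env_threat * 6))


def p_act_bomb(env_threat, n_tokens):
    """Probability of an activated bomb, ``env_threat * n_tokens / 12``.

    Accepts scalars or arrays; validates ranges on scalars and arrays alike.
    """
    env_threat = np.asarray(env_threat, dtype=float)
    n_tokens = np.asarray(n_tokens, dtype=float)
    if np.any(env_threat <= 0) or np.any(env_threat > 1):
        raise ValueError("env_threat must lie in (0, 1]")
    if np.any(n_tokens < 2) or np.any(n_tokens > N_SITES):
        raise ValueError("n_tokens must lie in {2, ..., 12}")
    out = env_threat * n_tokens / N_SITES
    return float(out) if out.ndim == 0 else out


def binary_entropy(p) -> np.ndarray | float:
    """Shannon entropy of a Bernoulli(p) variable, in bits; H(0)=H(1)=0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log2(np.where(p > 0, p, 1)), 0.0)
              + np.where(p < 1, (1 - p) * np.log2(np.where(p < 1, 1 - p, 1)), 0.0))
    h = np.abs(h)  # -0.0 -> 0.0 at the degenerate endpoints
    return float(h) if h.ndim == 0 else h


def ev_true(gamble: Gamble) -> float:
    """True (objective) expected value of the non-exploring gamble, in tokens.

    Ap/Av: ``EV = -12 * P(ActBomb) + n * (1 - P(ActBomb))`` — the value of
    accepting.  Ap/Ap: the better of the two guesses,
    ``max(P * n, (1 - P) * n)``.
    """
    p = gamble.p_act_bomb
    n = gamble.n_tokens
    if gamble.condition is Condition.APAV:
        return LOSS_TOKENS * p + n * (1 - p)
    return max(p * n, (1 - p) * n)


@dataclass(frozen=True)
class TaskSpaceGrid:
    """The five psychological-variable grids over the 6x6 task space.

    Rows index environmental threat (ascending 1/6..1), columns index token
    count (ascending 2..12).  All grids except ``ev`` are identical across
    conditions.
    """

    condition: Condition
    env_threat: np.ndarray
    n_tokens: np.ndarray
    p_act_bomb: np.ndarray
    entropy: np.ndarray
    ev: np.ndarray
    variable_names: tuple = field(
        default=("env_threat", "n_tokens", "p_act_bomb", "entropy", "ev")
    )

    def correlation_matrix(self) -> pd.DataFrame:
        """Pearson correlations between the five grids over the 36 cells."""
        flat = {name: getattr(self, name).ravel() for name in self.variable_names}
        return pd.DataFrame(flat).corr()


def make_task_space(condition: Condition | str = Condition.APAV) -> TaskSpaceGrid:
    """Build the five 6x6 variable grids for one condition."""
    condition = Condition(condition)
    T, N = np.meshgrid(ENV_THREAT_LEVELS, N_TOKEN_LEVELS.astype(float), indexing="ij")
    P = p_act_bomb(T, N)
    H = binary_entropy(P)
    ev = np.empty_like(P)
    for idx in np.ndindex(P.shape):
        g = Gamble(float(T[idx]), int(N[idx]), condition)
        ev[idx] = ev_true(g)
    return TaskSpaceGrid(condition, T, N, P, H, ev)


def all_gambles(condition: Condition | str = Condition.APAV) -> list[Gamble]:
    """The 36 distinct gambles of one condition, threat-major order."""
    condition = Condition(condition)
    return [
        Gamble(float(t), int(n), condition)
        for t, n in itertools.product(ENV_THREAT_LEVELS, N_TOKEN_LEVELS)
    ]


# ---------------------------------------------------------------------------
# Session generation and outcome resolution
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "subject_id", "block", "trial_index", "condition",
    "env_threat_level", "n_tokens", "bomb_planted", "bomb_activated",
    "stage1_choice", "reveal_saw_bomb", "stage2_choice", "payoff_pence",
]


def generate_session(
    n_reps: int = 18,
    n_blocks: int = 12,
    start_condition: Condition | str = Condition.APAV,
    seed: int | np.random.Generator = 0,
    subject_id: str = "S00",
) -> pd.DataFrame:
    """Generate one session's trial scaffold with latent bomb states.

    Each of the 36 gambles appears exactly ``n_reps`` times per condition.
    Trials are grouped into ``n_blocks`` alternating-condition blocks
    (default 12 blocks of 108 trials at ``n_reps=18``), shuffled within
    condition by ``seed``.  Bomb state is pre-sampled per trial: planted
    with probability ``env_threat``; if planted, its site is uniform over
    the 12 locations and it is activated iff the site falls among the
    ``n_tokens`` activated ones — marginally ``P(ActBomb)``.  Choice columns
    are left unset (NA) and ``payoff_pence`` is 0 until resolved.

    Returns a DataFrame with the canonical trial-log schema.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_blocks < 2 or n_blocks % 2:
        raise ValueError("n_blocks must be a positive even number")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start_condition = Condition(start_condition)
    other = Condition.APAP if start_condition is Condition.APAV else Condition.APAV

    per_cond_blocks = n_blocks // 2
    rows: list[dict] = []
    block_of = {start_condition: 0, other: 1}
    for cond in (start_condition, other):
        cells = np.repeat(np.arange(36), n_reps)
        rng.shuffle(cells)
        blocks = np.array_split(cells, per_cond_blocks)
        for b, cell_idx in enumerate(blocks):
            block_id = 2 * b + block_of[cond]
            for c in cell_idx:
                level = int(c // 6) + 1
                n_tok = int(N_TOKEN_LEVELS[c % 6])
                threat = level / 6.0
                planted = bool(rng.random() < threat)
                site = int(rng.integers(N_SITES)) if planted else -1
                activated = planted and site < n_tok
                rows.append({
                    "subject_id": subject_id,
                    "block": block_id,
                    "condition": cond.value,
                    "env_threat_level": level,
                    "n_tokens": n_tok,
                    "bomb_planted": int(planted),
                    "bomb_activated": int(activated),
                    "stage1_choice": pd.NA,
                    "reveal_saw_bomb": pd.NA,
                    "stage2_choice": pd.NA,
                    "payoff_pence": 0,
                })
    df = pd.DataFrame(rows)
    df.sort_values(["block"], kind="stable", inplace=True)
    df.reset_index(drop=True, inplace=True)
    df.insert(2, "trial_index", np.arange(len(df)))
    return df[TRIAL_COLUMNS]


def resolve_outcome(
    trial: pd.Series | dict,
    stage1: Choice | str,
    stage2: Choice | str | None = None,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Resolve one trial given its latent bomb state and the choices made.

    For exploring trials, ``reveal_saw_bomb`` is sampled: an activated bomb
    is seen with probability 1/2 (half of the sites are uncovered).  If the
    bomb is seen the stage-2 decision is forced by the reveal in practice,
    but whatever ``stage2`` is supplied is honoured for payoff purposes.

    Returns a dict with ``stage1_choice``, ``reveal_saw_bomb``,
    ``stage2_choice`` and ``payoff_pence``.

    Notes
    -----
    Payoffs, in pence: Ap/Av accept wins ``10 * n_tokens`` unless an
    activated bomb is present (then -120); reject is 0; exploring always
    costs the 20 p fee, once.  Ap/Ap: a correct guess about the activated
    bomb wins ``10 * n_tokens``, an incorrect one nothing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stage1 = Choice(stage1)
    cond = Condition(trial["condition"])
    n = int(trial["n_tokens"])
    activated = bool(trial["bomb_activated"])

    def settle(choice: Choice) -> int:
        if cond is Condition.APAV:
            if choice is Choice.ACCEPT_NOBOMB:
                return LOSS_PENCE if activated else TOKEN_VALUE_PENCE * n
            return 0
        guessed_bomb = choice is Choice.REJECT_BOMB
        return TOKEN_VALUE_PENCE * n if guessed_bomb == activated else 0

    if stage1 is not Choice.EXPLORE:
        if stage2 is not None:
            raise ValueError("stage2 choice given but stage-1 did not explore")
        return {
            "stage1_choice": stage1.value,
            "reveal_saw_bomb": pd.NA,
            "stage2_choice": pd.NA,
            "payoff_pence": settle(stage1),
        }

    if stage2 is None:
        raise ValueError("exploring trials require a stage-2 choice (or policy)")
    saw = bool(activated and rng.random() < 0.5)
    if callable(stage2):
        stage2 = stage2(saw)  # stage-2 policy reacting to the reveal
    stage2 = Choice(stage2)
    if stage2 is Choice.EXPLORE:
        raise ValueError("cannot explore twice in one trial")
    return {
        "stage1_choice": stage1.value,
        "reveal_saw_bomb": int(saw),
        "stage2_choice": stage2.value,
        "payoff_pence": settle(stage2) - EXPLORE_FEE_PENCE,
    }
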