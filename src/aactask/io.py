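"""Readers and writers for trial logs, latent tables, fit reports and configs.

All tables are plain tab-separated text with a single column-header row;
optional provenance lines (``# key: value``) may precede the header and are
skipped on read.  Reports and configs are JSON.  Writers are deterministic
given content: stable column order, floats at 6 significant digits, and the
literal ``NA`` for missing optional fields.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .task import TRIAL_COLUMNS, Choice, Condition

__all__ = [
    "read_trial_log",
    "write_trial_log",
    "write_table",
    "read_table",
    "write_report",
    "read_report",
    "TrialLogError",
]

_FLOAT_FMT = "%.6g"
_NA = "NA"


class TrialLogError(ValueError):
    """A trial log violated the documented schema; carries the 1-based line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


def _provenance(seed=None, config=None) -> list[str]:
    lines = [f"# aactask {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        lines.append(f"# config_sha256: {digest}")
    return lines


def write_table(df: pd.DataFrame, path, seed=None, config=None) -> None:
    """Write any DataFrame as provenance-headed TSV with stable formatting."""
    path = Path(path)
    with path.open("w") as fh:
        for line in _provenance(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep=_NA)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[_NA])


def write_trial_log(trials: pd.DataFrame, path, seed=None, config=None) -> None:
    """Write a trial log in the canonical column order."""
    write_table(trials[TRIAL_COLUMNS], path, seed=seed, config=config)


_CHOICES = {c.value for c in Choice}
_STAGE2 = {Choice.ACCEPT_NOBOMB.value, Choice.REJECT_BOMB.value}


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial log.

    Schema violations and impossible states (a reveal without exploration,
    a seen bomb on a bomb-free trial, a missing stage-2 choice after
    exploring) are rejected with the offending 1-based file line number.
    """
    path = Path(path)
    n_header = 1
    with path.open() as fh:
        for raw in fh:
            if raw.startswith("#"):
                n_header += 1
            else:
                break
    df = read_table(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogError(f"missing columns {missing}", line=n_header)

    def fail(mask: pd.Series, message: str):
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise TrialLogError(message, line=n_header + 1 + row)

    fail(~df["condition"].isin([c.value for c in Condition]), "unknown condition label")
    fail(~df["env_threat_level"].isin(range(1, 7)), "env_threat_level must be 1..6")
    fail(~df["n_tokens"].isin([2, 4, 6, 8, 10, 12]), "n_tokens must be in {2,...,12}")
    fail(~df["bomb_planted"].isin([0, 1]), "bomb_planted must be 0/1")
    fail(~df["bomb_activated"].isin([0, 1]), "bomb_activated must be 0/1")
    fail((df["bomb_activated"] == 1) & (df["bomb_planted"] == 0),
         "activated bomb requires a planted bomb")
    s1 = df["stage1_choice"]
    fail(s1.notna() & ~s1.isin(_CHOICES), "unknown stage1_choice")
    explored = s1 == Choice.EXPLORE.value
    fail(explored & df["reveal_saw_bomb"].isna(), "explored trial missing reveal")
    fail(explored & df["stage2_choice"].isna(), "explored trial missing stage-2 choice")
    fail(~explored & s1.notna() & df["reveal_saw_bomb"].notna(),
         "reveal recorded without exploration")
    fail(~explored & s1.notna() & df["stage2_choice"].notna(),
         "stage-2 choice recorded without exploration")
    fail(df["stage2_choice"].notna() & ~df["stage2_choice"].isin(_STAGE2),
         "stage2_choice must be ACCEPT_NOBOMB or REJECT_BOMB")
    fail((df["reveal_saw_bomb"] == 1) & (df["bomb_activated"] == 0),
         "bomb seen on a trial without an activated bomb")
    for col in ("reveal_saw_bomb",):
        fail(df[col].notna() & ~df[col].isin([0, 1]), f"{col} must be 0/1 or NA")
    return df[TRIAL_COLUMNS]


def write_report(report: dict, path, seed=None, config=None) -> None:
    """Write a JSON report with an embedded provenance block."""
    payload = dict(report)
    payload["provenance"] = {
        "package": f"aactask {__version__}",
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12] if config is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
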