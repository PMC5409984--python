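"""Risky-choice task designs.

Two study layouts are supported.  In Study 1 a session consists of 8 blocks
of 5 trials (40 trials); each block is tied to one of four 50/50 gambles
(the *risk context*) and the certain ("safe") offer varies trial to trial.
In Study 2 blocks hold 21 trials sampling a finer grid of 21 safe levels,
and every block additionally carries a secondary working-memory load: a
four-symbol sequence that is all zeros (low load) or a mix of digits and
letters (high load).

A session can be run in two presentation modes: ``dual`` (safe and risky
alternative shown together on every trial) or ``single`` (only the safe
alternative is shown and the gamble must be held in memory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GambleSpec",
    "TrialSpec",
    "BlockSpec",
    "SessionDesign",
    "make_gamble_set",
    "gamble_ev",
    "gamble_context_value",
    "sample_safe_values",
    "generate_session",
    "context_label",
]

# Block/trial timing (seconds)
FIXATION_S = 0.5
BLOCK_CUE_S = 8.0
BLANK_S = 0.5
CHOICE_WINDOW_S = 5.0
ITI_RANGE_S = (10.0, 12.0)
LOAD_SEQUENCE_S = 2.0  # presentation time of the secondary-memory sequence
LOAD_SEQUENCE_LEN = 4

STUDY1_N_BLOCKS = 8
STUDY1_TRIALS_PER_BLOCK = 5
STUDY1_LEVELS_PER_CONTEXT = 10
STUDY2_TRIALS_PER_BLOCK = 21


@dataclass(frozen=True)
class GambleSpec:
    """A 50/50 two-outcome gamble defining a risk context (amounts in CHF)."""

    low_outcome: float
    high_outcome: float
    risk_level: str  # "low" | "high"
    ev_level: str    # "low" | "high"
    probability: float = 0.5

    def __post_init__(self) -> None:
        if self.low_outcome > self.high_outcome:
            raise ValueError("low_outcome must not exceed high_outcome")

    @property
    def label(self) -> str:
        return context_label(self.risk_level, self.ev_level)


def context_label(risk_level: str, ev_level: str) -> str:
    return f"{risk_level}R-{ev_level}EV"


@dataclass(frozen=True)
class TrialSpec:
    block_index: int
    trial_index: int
    safe_value: float
    gamble: GambleSpec
    onset_s: float
    iti_s: float
    presentation: str  # "dual" | "single"


@dataclass
class BlockSpec:
    gamble: GambleSpec
    trials: list[TrialSpec] = field(default_factory=list)
    load: str = "none"  # "none" | "low" | "high"
    load_sequence: list[str] = field(default_factory=list)
    block_cue_duration_s: float = BLOCK_CUE_S


@dataclass
class SessionDesign:
    study: int
    experiment: str  # "dual" | "single"
    blocks: list[BlockSpec]
    seed: int

    @property
    def trials(self) -> list[TrialSpec]:
        return [t for b in self.blocks for t in b.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def events_table(self) -> pd.DataFrame:
        rows = []
        for b_idx, block in enumerate(self.blocks):
            for t in block.trials:
                g = t.gamble
                rows.append(
                    dict(
                        onset=t.onset_s,
                        duration=CHOICE_WINDOW_S,
                        block=b_idx,
                        trial=t.trial_index,
                        safe_value=t.safe_value,
                        gamble_low=g.low_outcome,
                        gamble_high=g.high_outcome,
                        risk_level=g.risk_level,
                        ev_level=g.ev_level,
                        context=g.label,
                        load=block.load,
                        presentation=t.presentation,
                    )
                )
        return pd.DataFrame(rows)

    def write(self, events_path: str | Path, manifest_path: str | Path | None = None) -> None:
        """Write the events table as TSV plus a JSON design manifest."""
        events_path = Path(events_path)
        self.events_table().to_csv(events_path, sep="\t", index=False)
        if manifest_path is None:
            manifest_path = events_path.with_suffix(".json")
        manifest = {
            "study": self.study,
            "experiment": self.experiment,
            "seed": self.seed,
            "n_blocks": len(self.blocks),
            "n_trials": self.n_trials,
            "blocks": [
                {
                    "gamble": [b.gamble.low_outcome, b.gamble.high_outcome],
                    "context": b.gamble.label,
                    "load": b.load,
                    "load_sequence": b.load_sequence,
                }
                for b in self.blocks
            ],
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))


def make_gamble_set() -> list[GambleSpec]:
    """The four risk contexts: 2 risk levels crossed with 2 EV levels."""
    return [
        GambleSpec(15.0, 45.0, "low", "low"),
        GambleSpec(40.0, 80.0, "low", "high"),
        GambleSpec(10.0, 50.0, "high", "low"),
        GambleSpec(30.0, 90.0, "high", "high"),
    ]


def gamble_ev(g: GambleSpec) -> float:
    """Expected value of the 50/50 gamble: the mean of its two outcomes."""
    return 0.5 * (g.low_outcome + g.high_outcome)


def gamble_context_value(g: GambleSpec) -> float:
    """Risk (context) value of the gamble: the population standard deviation
    of its two equiprobable outcomes, (high - low) / 2."""
    return 0.5 * (g.high_outcome - g.low_outcome)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_safe_values(
    g: GambleSpec, n: int, seed: int | np.random.Generator
) -> list[float]:
    """Draw ``n`` safe offers spanning the gamble's outcome range.

    The offers form an evenly spaced grid over [low, high], presented in a
    randomized order and constrained so that the mean offer stays within one
    grid step of the gamble's EV (which keeps experienced within-block EV
    close to the across-block EV).  Reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    span = g.high_outcome - g.low_outcome
    max_levels = int(round(span)) + 1  # distinct levels at 1-CHF resolution
    if n > max_levels:
        raise ValueError(
            f"n={n} exceeds the {max_levels} representable distinct safe levels "
            f"in [{g.low_outcome}, {g.high_outcome}]"
        )
    rng = _as_rng(seed)
    if n == 1:
        return [gamble_ev(g)]
    grid = np.linspace(g.low_outcome, g.high_outcome, n)
    step = span / (n - 1)
    target = gamble_ev(g)
    for _ in range(100):
        values = rng.permutation(grid)
        if abs(values.mean() - target) <= step:
            return [float(v) for v in values]
    raise RuntimeError("could not satisfy the EV-matching constraint")  # pragma: no cover


def _high_load_sequence(rng: np.random.Generator) -> list[str]:
    digits = rng.choice(list("123456789"), size=2, replace=False)
    letters = rng.choice(list("ABCDEFGHJKLMNPRSTUVWXYZ"), size=2, replace=False)
    seq = np.concatenate([digits, letters])
    return [str(s) for s in rng.permutation(seq)]


def generate_session(
    study: int,
    experiment: str,
    seed: int,
    n_blocks: int | None = None,
) -> SessionDesign:
    """Generate a full session timeline for one participant.

    Each block runs: [load sequence (Study 2 only)] -> 0.5 s fixation ->
    8 s risk-context cue -> 0.5 s blank -> trials.  Each trial opens a 5 s
    choice window followed by a uniform 10-12 s intertrial interval.

    Study 1: 8 blocks x 5 trials, two blocks per gamble, the 10 safe levels
    of each context split 5 + 5 over its two blocks.  Study 2: by default
    4 blocks (one per gamble) x 21 trials, secondary load counterbalanced
    low/high across blocks.
    """
    if study not in (1, 2):
        raise ValueError("study must be 1 or 2")
    if experiment not in ("dual", "single"):
        raise ValueError("experiment must be 'dual' or 'single'")
    rng = np.random.default_rng(seed)
    gambles = make_gamble_set()

    if study == 1:
        n_blocks = STUDY1_N_BLOCKS
        trials_per_block = STUDY1_TRIALS_PER_BLOCK
        # two blocks per gamble, order randomized
        block_gambles = list(rng.permutation(np.arange(n_blocks) % 4))
        loads = ["none"] * n_blocks
        # 10 distinct levels per context, split 5 + 5 across its two blocks
        per_context = {
            i: sample_safe_values(gambles[i], STUDY1_LEVELS_PER_CONTEXT, rng)
            for i in range(4)
        }
        consumed = {i: 0 for i in range(4)}
    else:
        if n_blocks is None:
            n_blocks = 4
        if n_blocks % 4 != 0:
            raise ValueError("Study 2 n_blocks must be a multiple of 4")
        trials_per_block = STUDY2_TRIALS_PER_BLOCK
        reps = n_blocks // 4
        block_gambles = list(rng.permutation(np.arange(n_blocks) % 4))
        # balanced low/high load; with >=2 blocks per gamble, balanced within gamble
        if reps % 2 == 0:
            loads_by_gamble: dict[int, list[str]] = {
                i: list(rng.permutation(["low", "high"] * (reps // 2))) for i in range(4)
            }
            loads = [loads_by_gamble[g].pop() for g in block_gambles]
        else:
            pool = list(rng.permutation(["low", "high"] * (n_blocks // 2)))
            loads = pool[:n_blocks]
        per_context = None
        consumed = None

    blocks: list[BlockSpec] = []
    t = 0.0
    for b_idx in range(n_blocks):
        g = gambles[block_gambles[b_idx]]
        load = loads[b_idx]
        if study == 2:
            load_seq = ["0"] * LOAD_SEQUENCE_LEN if load == "low" else _high_load_sequence(rng)
            t += LOAD_SEQUENCE_S
        else:
            load_seq = []
        t += FIXATION_S + BLOCK_CUE_S + BLANK_S
        if study == 1:
            i0 = consumed[block_gambles[b_idx]]
            safe_values = per_context[block_gambles[b_idx]][i0 : i0 + trials_per_block]
            consumed[block_gambles[b_idx]] += trials_per_block
        else:
            safe_values = sample_safe_values(g, trials_per_block, rng)
        trials = []
        for t_idx, v in enumerate(safe_values):
            iti = float(rng.uniform(*ITI_RANGE_S))
            trials.append(
                TrialSpec(
                    block_index=b_idx,
                    trial_index=t_idx,
                    safe_value=v,
                    gamble=g,
                    onset_s=t,
                    iti_s=iti,
                    presentation=experiment,
                )
            )
            t += CHOICE_WINDOW_S + iti
        blocks.append(
            BlockSpec(gamble=g, trials=trials, load=load, load_sequence=load_seq)
        )
    return SessionDesign(study=study, experiment=experiment, blocks=blocks, seed=int(seed))
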