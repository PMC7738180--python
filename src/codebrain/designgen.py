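"""Experiment design generators.

Two designs drive the pipeline:

* the code-comprehension task -- 6 runs x 20 trials (8 ``for``, 8 ``if``,
  4 ``fake``), each trial a function (24 s) / input (6 s) / question (6 s)
  sequence followed by a 5 s inter-trial interval;
* the multi-source interference task (MSIT) -- a blocked stimulus-response
  conflict design used to localize the executive multiple-demand network.

Schedules are plain records (one row per trial phase) wrapped in small
dataclasses, and round-trip through BIDS-style events TSV files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Phase durations in seconds.  Trials are back-to-back: function, 0.5 s
# fixation, input, 0.5 s fixation, question, then the inter-trial interval.
FUNCTION_S = 24.0
INPUT_S = 6.0
QUESTION_S = 6.0
ITI_S = 5.0
FIX_S = 0.5
TRIAL_S = FUNCTION_S + FIX_S + INPUT_S + FIX_S + QUESTION_S + ITI_S  # 42 s

N_RUNS = 6
REAL_PER_RUN = {"for": 8, "if": 8}
FAKE_PER_RUN = 4

MSIT_TRIAL_S = 1.75
MSIT_BLOCK_S = 42.0
MSIT_FIX_S = 15.0
MSIT_N_RUNS = 2
MSIT_BLOCKS_PER_KIND_PER_RUN = 4

EVENT_COLUMNS = ["onset", "duration", "trial_type", "run", "function_id", "phase", "answer"]


@dataclass
class TrialSchedule:
    """Code-task schedule: one row per trial phase, plus the counterbalance group."""

    trials: pd.DataFrame
    group: str

    def function_events(self) -> pd.DataFrame:
        """Rows for the modeled 24 s function phase only."""
        return self.trials[self.trials["phase"] == "function"].reset_index(drop=True)


@dataclass
class MsitBlock:
    kind: str  # "interference" | "control"
    trials: list[str] = field(default_factory=list)


@dataclass
class MsitSchedule:
    """MSIT schedule: per run, 15 s fixation, 8 interleaved blocks, 15 s fixation."""

    runs: list[list[MsitBlock]]

    def all_blocks(self, kind: str | None = None) -> list[MsitBlock]:
        blocks = [b for run in self.runs for b in run]
        if kind is not None:
            blocks = [b for b in blocks if b.kind == kind]
        return blocks


def enumerate_msit_interference() -> list[tuple[str, int]]:
    """Enumerate every MSIT interference trial type.

    An interference triplet has a target digit ``d`` in {1,2,3} at position
    ``p`` (1-based) with ``p != d``, flanked by two identical distractors
    ``x`` in {1,2,3} with ``x != d``.  Zero never appears.  For example
    ``'131'`` (target 3 at position 2) is valid, while ``'133'`` (target at
    its own position) or ``'121'`` are not.

    Returns a sorted list of ``(triplet, target_position)`` pairs; there are
    exactly 12.
    """
    out = []
    for d in (1, 2, 3):
        for x in (1, 2, 3):
            if x == d:
                continue
            for p in (1, 2, 3):
                if p == d:
                    continue
                digits = [str(x)] * 3
                digits[p - 1] = str(d)
                out.append(("".join(digits), p))
    return sorted(out)


def enumerate_msit_control() -> list[str]:
    """The three MSIT control trial types: distractors '0', target at its own position."""
    out = []
    for d in (1, 2, 3):
        digits = ["0", "0", "0"]
        digits[d - 1] = str(d)
        out.append("".join(digits))
    return sorted(out)  # ['003', '020', '100']


def build_stimulus_inventory() -> dict:
    """Describe the stimulus economy of the code task.

    96 base real functions (48 for-loop, 48 if-conditional), each written in
    two variants, give 192 distinct real stimuli; 48 fake (scrambled)
    functions complete the set.  Variants are counterbalanced across the two
    participant groups so that one participant never sees both variants of
    the same base function: group A sees variant 1 of even base ids and
    variant 2 of odd ids, group B the reverse.  Fake functions are split
    24 per group.
    """
    real = []
    for base_id in range(96):
        structure = "for" if base_id < 48 else "if"
        for variant in (1, 2):
            group = _variant_group(base_id, variant)
            real.append(
                {
                    "function_id": base_id,
                    "structure": structure,
                    "variant": variant,
                    "group": group,
                }
            )
    fake = [
        {"function_id": 1000 + i, "structure": "fake", "group": "A" if i < 24 else "B"}
        for i in range(48)
    ]
    real_df = pd.DataFrame(real)
    fake_df = pd.DataFrame(fake)
    return {
        "real": real_df,
        "fake": fake_df,
        "n_real_total": len(real_df),
        "n_real_per_group": int((real_df["group"] == "A").sum()),
        "n_fake_total": len(fake_df),
        "n_fake_per_group": int((fake_df["group"] == "A").sum()),
    }


def _variant_group(base_id: int, variant: int) -> str:
    if base_id % 2 == 0:
        return "A" if variant == 1 else "B"
    return "B" if variant == 1 else "A"


def build_code_schedule(group: str, seed: int) -> TrialSchedule:
    """Build one participant's 6-run code-task schedule.

    Each run holds 8 for, 8 if and 4 fake trials; over the session a
    participant sees 48 for (24 per variant), 48 if (24 per variant) and
    24 fake functions (12 fake-for, 12 fake-if).  Trial order within a run is
    a seeded uniform permutation; half of the real and half of the fake
    trials are keyed with correct answer "true".  Deterministic given
    ``(group, seed)``.
    """
    if group not in ("A", "B"):
        raise ValueError(f"group must be 'A' or 'B', got {group!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([{"A": 0, "B": 1}[group], seed & 0x7FFFFFFF])
    )

    inventory = build_stimulus_inventory()
    real = inventory["real"]
    mine = real[real["group"] == group]

    # Condition label: structure + variant, e.g. for1, if2.
    conditions: dict[str, list[int]] = {}
    for structure in ("for", "if"):
        for variant in (1, 2):
            ids = mine[(mine["structure"] == structure) & (mine["variant"] == variant)][
                "function_id"
            ].to_numpy()
            conditions[f"{structure}{variant}"] = list(rng.permutation(ids))
    fake_ids = inventory["fake"]
    fake_ids = fake_ids[fake_ids["group"] == group]["function_id"].to_numpy()
    fake_ids = list(rng.permutation(fake_ids))
    conditions["fake_for"] = fake_ids[:12]
    conditions["fake_if"] = fake_ids[12:]

    per_run = {"for1": 4, "for2": 4, "if1": 4, "if2": 4, "fake_for": 2, "fake_if": 2}
    answers = _balanced_answers(conditions, rng)

    rows = []
    for run in range(1, N_RUNS + 1):
        trial_specs = []
        for cond, n in per_run.items():
            for _ in range(n):
                fid = conditions[cond].pop()
                trial_specs.append((cond, fid))
        order = rng.permutation(len(trial_specs))
        t = 0.0
        for idx in order:
            cond, fid = trial_specs[idx]
            ans = answers[fid]
            for phase, dur, offset in (
                ("function", FUNCTION_S, 0.0),
                ("input", INPUT_S, FUNCTION_S + FIX_S),
                ("question", QUESTION_S, FUNCTION_S + FIX_S + INPUT_S + FIX_S),
                ("iti", ITI_S, TRIAL_S - ITI_S),
            ):
                rows.append(
                    {
                        "onset": t + offset,
                        "duration": dur,
                        "trial_type": cond,
                        "run": run,
                        "function_id": fid,
                        "phase": phase,
                        "answer": ans,
                    }
                )
            t += TRIAL_S
    return TrialSchedule(trials=pd.DataFrame(rows, columns=EVENT_COLUMNS), group=group)


def _balanced_answers(conditions: dict[str, list[int]], rng: np.random.Generator) -> dict[int, bool]:
    """Key half of each condition's trials as correct-answer 'true'."""
    answers: dict[int, bool] = {}
    for cond, ids in conditions.items():
        n = len(ids)
        vals = np.array([True] * (n // 2) + [False] * (n - n // 2))
        vals = rng.permutation(vals)
        for fid, v in zip(ids, vals):
            answers[int(fid)] = bool(v)
    return answers


def build_msit_schedule(seed: int) -> MsitSchedule:
    """Build the two-run MSIT schedule.

    Each run interleaves 4 interference and 4 control blocks (starting kind
    alternates with seed parity).  An interference block presents each of the
    12 interference triplets exactly twice; a control block presents each of
    the 3 control triplets exactly six times.  Within a block no two
    identical triplets appear in succession, and the 8 blocks of one kind
    (across both runs) all use distinct trial orders.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    interference = [t for t, _ in enumerate_msit_interference()]
    control = enumerate_msit_control()

    seen: dict[str, set[tuple[str, ...]]] = {"interference": set(), "control": set()}
    pools = {"interference": interference * 2, "control": control * 6}

    runs = []
    start_with_interference = seed % 2 == 0
    for _run in range(MSIT_N_RUNS):
        kinds = ["interference", "control"] if start_with_interference else ["control", "interference"]
        order = list(itertools.chain.from_iterable([kinds] * MSIT_BLOCKS_PER_KIND_PER_RUN))
        blocks = []
        for kind in order:
            trials = _order_block(pools[kind], seen[kind], rng)
            blocks.append(MsitBlock(kind=kind, trials=trials))
        runs.append(blocks)
    return MsitSchedule(runs=runs)


def _order_block(pool: list[str], seen: set[tuple[str, ...]], rng: np.random.Generator,
                 max_tries: int = 10_000) -> list[str]:
    """Shuffle a trial multiset with no adjacent repeats and a novel order."""
    for _ in range(max_tries):
        order = [pool[i] for i in rng.permutation(len(pool))]
        if any(a == b for a, b in zip(order, order[1:])):
            continue
        key = tuple(order)
        if key in seen:
            continue
        seen.add(key)
        return order
    raise RuntimeError("could not place MSIT trials without adjacent duplicates")


def write_events_tsv(schedule: TrialSchedule, path) -> None:
    """Write a schedule as a BIDS-style events TSV."""
    schedule.trials.to_csv(path, sep="\t", index=False)


def read_events_tsv(path, group: str = "A") -> TrialSchedule:
    """Read a schedule written by :func:`write_events_tsv`."""
    df = pd.read_csv(path, sep="\t")
    df["answer"] = df["answer"].astype(bool)
    return TrialSchedule(trials=df[EVENT_COLUMNS], group=group)
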