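"""Instructed fear-reversal task schedules.

The task has 80 trials in 4 blocks of 20. Within every block the nominal
CS+ cue is shown 12 times (4 reinforced with the shock, 8 unreinforced) and
the CS− cue 8 times, a 4/12 = 33% ≈ 30% reinforcement rate of the CS+.
The cue↔condition mapping flips at the start of blocks 2–4 ("instructed
reversals", announced to the subject), so each face serves as CS+ in two
blocks. Trial order is pseudorandomised under two constraints: no two
reinforced trials in a row, and the same nominal condition never occurs on
three consecutive trials. Both constraints are enforced across block
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ScheduleGenerationError, StructuralError

N_TRIALS = 80
N_BLOCKS = 4
TRIALS_PER_BLOCK = 20
REINFORCED_PER_BLOCK = 4
CSPLUS_UNREINFORCED_PER_BLOCK = 8
CSMINUS_PER_BLOCK = 8
#: 1-based trial indices immediately preceded by an instructed reversal
REVERSAL_TRIALS = (21, 41, 61)

CUES = ("A", "B")
CONDITIONS = ("CS+", "CS-")


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered conditioning trials for one run of the task.

    Attributes
    ----------
    block : per-trial block number, 1–4.
    cue : per-trial cue identity, "A" or "B" (the two face stimuli).
    condition : nominal condition of the presented cue, "CS+" or "CS-".
    reinforced : whether the shock (US) was delivered on the trial.
    instructed_reversal_before : True on trials immediately preceded by the
        instructed-reversal message (trials 21, 41, 61, 1-based).
    """

    block: np.ndarray
    cue: np.ndarray
    condition: np.ndarray
    reinforced: np.ndarray
    instructed_reversal_before: np.ndarray
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self):
        n = len(self.block)
        for name in ("cue", "condition", "reinforced", "instructed_reversal_before"):
            if len(getattr(self, name)) != n:
                raise StructuralError(f"schedule field '{name}' has inconsistent length")

    def __len__(self) -> int:
        return len(self.block)

    @property
    def n_trials(self) -> int:
        return len(self.block)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "block": self.block,
                "cue": self.cue,
                "condition": self.condition,
                "reinforced": self.reinforced.astype(int),
                "instructed_reversal_before": self.instructed_reversal_before.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int | None = None) -> "TrialSchedule":
        required = {"block", "cue", "condition", "reinforced", "instructed_reversal_before"}
        missing = required - set(df.columns)
        if missing:
            raise StructuralError(f"schedule table missing columns: {sorted(missing)}")
        df = df.sort_values("trial") if "trial" in df.columns else df
        return cls(
            block=df["block"].to_numpy(int),
            cue=df["cue"].to_numpy(str),
            condition=df["condition"].to_numpy(str),
            reinforced=df["reinforced"].to_numpy(bool),
            instructed_reversal_before=df["instructed_reversal_before"].to_numpy(bool),
            seed=seed,
        )


def _block_csplus_cue(block: int) -> str:
    # cue A starts as CS+; the mapping flips at every reversal
    return CUES[(block - 1) % 2]


def _sample_block_types(rng: np.random.Generator, prev_types: list[str]) -> list[str] | None:
    """One rejection-sampling attempt at a block's trial-type sequence.

    Types: "R" reinforced CS+, "P" unreinforced CS+, "M" CS−. Returns None
    if the permutation violates a constraint (given the trailing context of
    the previous block).
    """
    types = ["R"] * REINFORCED_PER_BLOCK + ["P"] * CSPLUS_UNREINFORCED_PER_BLOCK + ["M"] * CSMINUS_PER_BLOCK
    perm = [types[i] for i in rng.permutation(len(types))]
    seq = prev_types + perm
    for i in range(len(prev_types), len(seq)):
        if i >= 1 and seq[i] == "R" and seq[i - 1] == "R":
            return None
        if i >= 2:
            c0 = "+" if seq[i] in "RP" else "-"
            c1 = "+" if seq[i - 1] in "RP" else "-"
            c2 = "+" if seq[i - 2] in "RP" else "-"
            if c0 == c1 == c2:
                return None
    return perm


def generate_schedule(seed: int, max_attempts_per_block: int = 20_000) -> TrialSchedule:
    """Generate a pseudorandomised 80-trial schedule satisfying all constraints.

    Deterministic given ``seed``. Uses per-block rejection sampling
    conditioned on the tail of the previous block so constraints also hold
    across block boundaries.

    Raises
    ------
    ScheduleGenerationError
        If the retry cap is exceeded (reports the seed for diagnosis).
    """
    rng = np.random.default_rng(seed)
    all_types: list[str] = []
    for _block in range(1, N_BLOCKS + 1):
        prev_tail = all_types[-2:]
        for _attempt in range(max_attempts_per_block):
            perm = _sample_block_types(rng, prev_tail)
            if perm is not None:
                all_types.extend(perm)
                break
        else:
            raise ScheduleGenerationError(
                f"could not satisfy pseudorandomisation constraints for seed {seed} "
                f"within {max_attempts_per_block} attempts per block",
                seed=seed,
            )

    block = np.repeat(np.arange(1, N_BLOCKS + 1), TRIALS_PER_BLOCK)
    condition = np.array(["CS+" if t in ("R", "P") else "CS-" for t in all_types])
    reinforced = np.array([t == "R" for t in all_types])
    cue = np.empty(N_TRIALS, dtype=object)
    for i in range(N_TRIALS):
        plus_cue = _block_csplus_cue(block[i])
        minus_cue = CUES[1] if plus_cue == CUES[0] else CUES[0]
        cue[i] = plus_cue if condition[i] == "CS+" else minus_cue
    instructed = np.zeros(N_TRIALS, dtype=bool)
    instructed[[t - 1 for t in REVERSAL_TRIALS]] = True
    return TrialSchedule(
        block=block,
        cue=cue.astype(str),
        condition=condition,
        reinforced=reinforced,
        instructed_reversal_before=instructed,
        seed=seed,
    )


@dataclass(frozen=True)
class Violation:
    rule: str
    trials: tuple[int, ...]  # 1-based trial indices
    detail: str = ""

    def __str__(self):
        return f"{self.rule} at trials {self.trials}: {self.detail}"


def validate_schedule(schedule: TrialSchedule) -> list[Violation]:
    """Check every schedule constraint; an empty list means the schedule is valid.

    Rules checked: trial/block structure, per-block 4/8/8 trial-type counts,
    reversal markers at trials 21/41/61, cue↔condition mapping flipping at
    each reversal, no adjacent reinforced trials, and no nominal condition
    occurring three times in a row. The two pseudorandomisation rules are
    isolated here so the reading of the constraints can be re-pointed.
    """
    if len(schedule) != N_TRIALS:
        raise StructuralError(f"schedule must have {N_TRIALS} trials, got {len(schedule)}")
    v: list[Violation] = []
    blocks = schedule.block
    cond = schedule.condition
    reinf = schedule.reinforced
    cue = schedule.cue

    expected_blocks = np.repeat(np.arange(1, N_BLOCKS + 1), TRIALS_PER_BLOCK)
    if not np.array_equal(blocks, expected_blocks):
        v.append(Violation("block-structure", (), "blocks are not 4 consecutive runs of 20"))

    for b in range(1, N_BLOCKS + 1):
        m = blocks == b
        n_reinf = int(np.sum(reinf[m]))
        n_plus_unreinf = int(np.sum((cond[m] == "CS+") & ~reinf[m]))
        n_minus = int(np.sum(cond[m] == "CS-"))
        if (n_reinf, n_plus_unreinf, n_minus) != (
            REINFORCED_PER_BLOCK,
            CSPLUS_UNREINFORCED_PER_BLOCK,
            CSMINUS_PER_BLOCK,
        ):
            v.append(
                Violation(
                    "block-counts",
                    (b,),
                    f"block {b} has (reinforced, CS+ unreinforced, CS-) = "
                    f"({n_reinf}, {n_plus_unreinf}, {n_minus}), expected (4, 8, 8)",
                )
            )
        if np.any(reinf[m] & (cond[m] == "CS-")):
            bad = tuple(int(i) + 1 for i in np.where(m & reinf & (cond == "CS-"))[0])
            v.append(Violation("reinforced-cs-minus", bad, "US delivered on a CS- trial"))
        plus_cue = _block_csplus_cue(b)
        wrong = m & (((cond == "CS+") & (cue != plus_cue)) | ((cond == "CS-") & (cue == plus_cue)))
        if np.any(wrong):
            v.append(
                Violation(
                    "cue-mapping",
                    tuple(int(i) + 1 for i in np.where(wrong)[0]),
                    f"cue/condition mapping inconsistent with CS+ cue '{plus_cue}' in block {b}",
                )
            )

    expected_rev = np.zeros(N_TRIALS, dtype=bool)
    expected_rev[[t - 1 for t in REVERSAL_TRIALS]] = True
    if not np.array_equal(schedule.instructed_reversal_before, expected_rev):
        got = tuple(int(i) + 1 for i in np.where(schedule.instructed_reversal_before)[0])
        v.append(Violation("reversal-markers", got, f"expected markers before trials {REVERSAL_TRIALS}"))

    for i in range(1, N_TRIALS):
        if reinf[i] and reinf[i - 1]:
            v.append(Violation("adjacent-shocks", (i, i + 1), "two shocks delivered in a row"))
    for i in range(2, N_TRIALS):
        if cond[i] == cond[i - 1] == cond[i - 2]:
            v.append(
                Violation("triple-condition", (i - 1, i, i + 1), f"condition {cond[i]} three times in a row")
            )
    return v
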