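"""Sternberg item-recognition session scheduling.

Builds constraint-satisfying trial plans for the Sternberg working-memory
test: a 21-consonant symbol alphabet is partitioned into a 9-letter target
pool (probes that belong to the memorized set, TG = 1) and a 12-letter foil
pool (TG = 0).  A test session comprises four 12-trial blocks, one per set
size SZ = 1..4, each balanced 6/6 between target and foil probes, with no
more than three equal target flags in a row anywhere in the concatenated
test sequence.  The scheduler also covers practice gating (the test proper
starts after six consecutive error-free practice attempts) and the random
double-blind split of the cohort into exposed and sham-exposed groups.

Everything is deterministic given a seed; sequences that violate the
run-length constraint are repaired by bounded rejection sampling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The 21 uppercase consonants used as the symbol alphabet.
CONSONANTS: tuple[str, ...] = tuple("BCDFGHJKLMNPQRSTVWXYZ")

#: Default block structure: ascending set sizes, 12 trials each, half targets.
DEFAULT_BLOCK_ORDER: tuple[int, ...] = (1, 2, 3, 4)
TRIALS_PER_BLOCK = 12
TARGET_FRACTION = 0.5
MAX_RUN = 3
MAX_RESAMPLE_ATTEMPTS = 10_000


class ScheduleError(RuntimeError):
    """A scheduling constraint could not be satisfied."""


class InsufficientPracticeError(ValueError):
    """A practice outcome stream ended before the gate was satisfied."""


@dataclass(frozen=True)
class SymbolPools:
    """Disjoint target (TG=1 candidates) and foil (TG=0 candidates) letter pools."""

    target_pool: tuple[str, ...]
    foil_pool: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.target_pool) & set(self.foil_pool):
            raise ValueError("target and foil pools must be disjoint")
        if len(set(self.target_pool)) != len(self.target_pool):
            raise ValueError("duplicate letters in target pool")
        if len(set(self.foil_pool)) != len(self.foil_pool):
            raise ValueError("duplicate letters in foil pool")


@dataclass(frozen=True)
class Trial:
    """One probe event: the subject judges whether ``probe`` is in ``memory_set``."""

    subject_id: str
    block_sz: int
    position_in_block: int
    memory_set: tuple[str, ...]
    probe: str
    is_target: int
    phase: str = "test"
    memorize_duration_s: float = 5.0
    probe_window_ms: float = 1000.0


@dataclass
class Session:
    """An ordered, constraint-satisfying trial sequence for one subject."""

    subject_id: str
    exposed: int
    trials: list[Trial]
    seed: int

    @property
    def test_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.phase == "test"]


@dataclass
class CohortPlan:
    """Random double-blind assignment of subjects to exposed / sham groups."""

    n_exposed: int
    n_sham: int
    assignment: dict[str, int]
    seed: int

    @property
    def subject_ids(self) -> list[str]:
        return list(self.assignment)


def make_symbol_pools(
    seed: int,
    alphabet: tuple[str, ...] = CONSONANTS,
    n_target: int = 9,
    n_foil: int = 12,
) -> SymbolPools:
    """Partition the alphabet into a seeded random target / foil pool pair."""
    if n_target + n_foil != len(alphabet):
        raise ValueError(
            f"pool sizes {n_target}+{n_foil} must cover the {len(alphabet)}-letter alphabet"
        )
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    rng.shuffle(letters)
    return SymbolPools(
        target_pool=tuple(letters[:n_target]),
        foil_pool=tuple(letters[n_target:]),
    )


def max_run_length(flags) -> int:
    """Length of the longest run of equal consecutive values (0 for empty input)."""
    best = run = 0
    prev = object()
    for x in flags:
        run = run + 1 if x == prev else 1
        prev = x
        best = max(best, run)
    return best


def _sample_target_flags(
    rng: np.random.Generator,
    n_trials: int,
    n_targets: int,
    prev_tail: list[int],
    max_run: int,
    max_attempts: int,
) -> list[int]:
    """Balanced 0/1 block respecting the run-length cap, also across the boundary
    with ``prev_tail`` (the closing flags of the preceding block)."""
    base = [1] * n_targets + [0] * (n_trials - n_targets)
    for _ in range(max_attempts):
        flags = list(rng.permutation(base))
        if max_run_length(prev_tail + flags) <= max_run:
            return flags
    raise ScheduleError(
        f"could not satisfy run-length <= {max_run} after {max_attempts} attempts"
    )


def build_session(
    subject_id: str,
    exposed: int,
    pools: SymbolPools,
    seed: int,
    block_order: tuple[int, ...] = DEFAULT_BLOCK_ORDER,
    trials_per_block: int = TRIALS_PER_BLOCK,
    target_fraction: float = TARGET_FRACTION,
    max_run: int = MAX_RUN,
    max_attempts: int = MAX_RESAMPLE_ATTEMPTS,
    fresh_memory_set_per_block: bool = True,
) -> Session:
    """Build one subject's test session.

    Per block a memory set of ``block_sz`` distinct letters is sampled from the
    target pool; target probes are drawn from that set, foil probes from the
    foil pool.  The target-flag sequence of each block is balanced (6/6 by
    default) and rejection-sampled until no run exceeds ``max_run``, counting
    runs across block boundaries as well.
    """
    n_targets = round(trials_per_block * target_fraction)
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    tail: list[int] = []
    memory_set: tuple[str, ...] = ()
    for sz in block_order:
        if sz > len(pools.target_pool):
            raise ScheduleError(f"set size {sz} exceeds target pool size")
        if fresh_memory_set_per_block or len(memory_set) != sz:
            memory_set = tuple(
                rng.choice(len(pools.target_pool), size=sz, replace=False)
            )
            memory_set = tuple(pools.target_pool[i] for i in memory_set)
        flags = _sample_target_flags(
            rng, trials_per_block, n_targets, tail, max_run, max_attempts
        )
        for pos, tg in enumerate(flags):
            if tg:
                probe = memory_set[rng.integers(len(memory_set))]
            else:
                probe = pools.foil_pool[rng.integers(len(pools.foil_pool))]
            trials.append(
                Trial(
                    subject_id=subject_id,
                    block_sz=sz,
                    position_in_block=pos,
                    memory_set=memory_set,
                    probe=probe,
                    is_target=tg,
                )
            )
        # run-length bookkeeping never needs more than the last max_run flags
        tail = flags[-max_run:]
    return Session(subject_id=subject_id, exposed=exposed, trials=trials, seed=seed)


def practice_gate(outcome_stream, required: int = 6) -> int:
    """Number of practice attempts consumed before the test proper may start.

    Scans an ordered stream of correctness flags (1 correct / 0 error) and
    returns the 1-based index of the trial completing the first run of
    ``required`` consecutive correct outcomes.
    """
    run = 0
    for i, ok in enumerate(outcome_stream, start=1):
        run = run + 1 if ok else 0
        if run >= required:
            return i
    raise InsufficientPracticeError(
        f"stream exhausted without {required} consecutive error-free attempts"
    )


def assign_groups(subject_ids, n_exposed: int, seed: int) -> CohortPlan:
    """Uniformly random, seed-reproducible exposed / sham split of the cohort."""
    ids = list(subject_ids)
    if n_exposed > len(ids):
        raise ValueError(f"n_exposed={n_exposed} exceeds cohort size {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    exposed_idx = set(order[:n_exposed].tolist())
    assignment = {sid: int(i in exposed_idx) for i, sid in enumerate(ids)}
    return CohortPlan(
        n_exposed=n_exposed,
        n_sham=len(ids) - n_exposed,
        assignment=assignment,
        seed=seed,
    )


def default_cohort_plan(
    n_exposed: int = 34, n_sham: int = 31, seed: int = 0
) -> CohortPlan:
    """The study's 65-subject cohort (34 exposed / 31 sham)."""
    n = n_exposed + n_sham
    ids = [f"S{i:03d}" for i in range(1, n + 1)]
    return assign_groups(ids, n_exposed, seed)


_SESSION_COLUMNS = [
    "subject_id",
    "exposed",
    "phase",
    "block_sz",
    "position",
    "memory_set",
    "probe",
    "is_target",
]


def sessions_to_frame(sessions) -> pd.DataFrame:
    """Flatten sessions into a tidy one-row-per-trial table."""
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                (
                    s.subject_id,
                    s.exposed,
                    t.phase,
                    t.block_sz,
                    t.position_in_block,
                    "".join(t.memory_set),
                    t.probe,
                    t.is_target,
                )
            )
    return pd.DataFrame(rows, columns=_SESSION_COLUMNS)


def write_sessions_csv(sessions, path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"memory_set": str, "probe": str})
    missing = set(_SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session CSV missing columns: {sorted(missing)}")
    return df


def serialize_session(session: Session) -> str:
    """Canonical CSV text of one session (used for reproducibility checks)."""
    buf = io.StringIO()
    write_sessions_csv([session], buf)
    return buf.getvalue()
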