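"""Single-cell lineage simulation, as observed in a microfluidics device.

One cell per lineage is tracked: at each division, one of the two
daughters is kept with equiprobability (the other is washed away), so a
lineage is a single path of the underlying branching process.  Generation
0 is telomerase inactivation; the founder is type A, cycling normally,
with i.i.d. initial telomere lengths, and completes one cycle before its
first division, so arrest laws are first evaluated on generation-1
daughters.

Classification mirrors the experimental read-out: only cycle *durations*
are observable, a cycle is long when it lasts at least ``D`` = 180 min,
and a lineage is called type B iff some long cycle is later followed by a
normal one (a visibly non-terminal arrest).  A ground-truth type-B lineage
whose only arrest sequence runs straight into death is misclassified as
type A; the ``is_M`` flag marks those.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .arrest import (
    CYCLE_LABELS,
    CYCLE_NOR,
    CYCLE_NTA,
    CYCLE_SEN,
    DEATH_LABELS,
    DEATH_NONE,
    LawParams,
    TYPE_A,
    daughter_fates,
)
from .cycles import DurationBank
from .rng import RngHub, as_hub
from .telomeres import InitialDistribution, N_CHROMOSOMES, divide_batch

DEFAULT_MAX_GENERATIONS = 200


@dataclass
class LineageRecord:
    """One complete simulated lineage (completed cycles only)."""

    generations: np.ndarray        # 0..G, strictly increasing
    cycle_types: np.ndarray        # true cycle type codes per generation
    durations: np.ndarray          # minutes per generation
    shortest: np.ndarray           # shortest telomere (bp) per generation
    gen_first_nta: Optional[int]
    gen_sen: Optional[int]
    gen_death: Optional[int]       # generation of the daughter that died
    death_cause: str               # 'senescence' | 'accident' | '' if truncated
    observed_type: str             # 'A' | 'B' from durations only
    is_M: bool
    truncated: bool
    shortest_at_sen_onset: Optional[int] = None

    @property
    def n_cycles(self) -> int:
        return len(self.generations)


@dataclass
class LineageBatch:
    """Vectorized storage for ``n`` lineages simulated in lock-step."""

    cycle_types: np.ndarray     # (n, G+1) int8, -1 where the lineage has ended
    durations: np.ndarray       # (n, G+1) float, NaN where ended
    shortest: np.ndarray        # (n, G+1) int32, -1 where ended
    gen_death: np.ndarray       # (n,) int32, -1 if truncated
    death_cause: np.ndarray     # (n,) int8
    truncated: np.ndarray       # (n,) bool
    shortest_at_sen_onset: np.ndarray  # (n,) int32, -1 if never senescent
    D: float

    def __len__(self) -> int:
        return self.cycle_types.shape[0]

    # -- derived, ground-truth quantities -----------------------------------

    def _first_gen(self, code: int) -> np.ndarray:
        hit = self.cycle_types == code
        first = np.argmax(hit, axis=1)
        first[~hit.any(axis=1)] = -1
        return first

    @property
    def gen_first_nta(self) -> np.ndarray:
        """First true nta generation per lineage (-1 if none)."""
        return self._first_gen(CYCLE_NTA)

    @property
    def gen_sen(self) -> np.ndarray:
        """First true senescent generation per lineage (-1 if none)."""
        return self._first_gen(CYCLE_SEN)

    @property
    def lifespan(self) -> np.ndarray:
        """Number of completed cycles per lineage."""
        return (self.cycle_types >= 0).sum(axis=1)

    # -- observational classification ---------------------------------------

    def classify(self) -> tuple[np.ndarray, np.ndarray]:
        """(observed_type_is_B, is_M) from durations only."""
        completed = self.cycle_types >= 0
        long = completed & (self.durations >= self.D)
        normal = completed & ~long
        # does a normal cycle occur strictly after column g?
        normal_after = np.zeros_like(normal)
        if normal.shape[1] > 1:
            normal_after[:, :-1] = np.flip(
                np.maximum.accumulate(np.flip(normal[:, 1:], axis=1), axis=1), axis=1
            )
        observed_b = (long & normal_after).any(axis=1)
        had_nta = (self.cycle_types == CYCLE_NTA).any(axis=1)
        is_m = ~observed_b & had_nta
        return observed_b, is_m

    def records(self) -> list[LineageRecord]:
        observed_b, is_m = self.classify()
        first_nta = self.gen_first_nta
        first_sen = self.gen_sen
        out = []
        for i in range(len(self)):
            n = int((self.cycle_types[i] >= 0).sum())
            out.append(
                LineageRecord(
                    generations=np.arange(n),
                    cycle_types=self.cycle_types[i, :n].copy(),
                    durations=self.durations[i, :n].copy(),
                    shortest=self.shortest[i, :n].copy(),
                    gen_first_nta=None if first_nta[i] < 0 else int(first_nta[i]),
                    gen_sen=None if first_sen[i] < 0 else int(first_sen[i]),
                    gen_death=None if self.gen_death[i] < 0 else int(self.gen_death[i]),
                    death_cause=DEATH_LABELS[int(self.death_cause[i])],
                    observed_type="B" if observed_b[i] else "A",
                    is_M=bool(is_m[i]),
                    truncated=bool(self.truncated[i]),
                    shortest_at_sen_onset=(
                        None
                        if self.shortest_at_sen_onset[i] < 0
                        else int(self.shortest_at_sen_onset[i])
                    ),
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle table (one row per lineage x generation)."""
        observed_b, is_m = self.classify()
        rows = []
        for i in range(len(self)):
            n = int((self.cycle_types[i] >= 0).sum())
            cause = DEATH_LABELS[int(self.death_cause[i])]
            for g in range(n):
                rows.append(
                    (
                        i,
                        g,
                        CYCLE_LABELS[int(self.cycle_types[i, g])],
                        float(self.durations[i, g]),
                        int(self.shortest[i, g]),
                        "B" if observed_b[i] else "A",
                        bool(is_m[i]),
                        cause,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "lineage_id",
                "generation",
                "cycle_type_true",
                "duration_min",
                "shortest_telomere_bp",
                "observed_type",
                "is_M",
                "death_cause",
            ],
        )


def simulate_lineages(
    n_lineages: int,
    params: LawParams,
    dist: InitialDistribution,
    bank: DurationBank,
    rng: RngHub | int,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> LineageBatch:
    """Simulate ``n_lineages`` independent microfluidics lineages.

    All lineages advance generation-by-generation in lock-step; randomness
    flows through the hub's named streams so the run is exactly
    replayable from its seed.
    """
    hub = as_hub(rng)
    n = int(n_lineages)
    G = int(max_generations)

    L = dist.sample_matrices(n, hub.init)
    T = np.full(n, TYPE_A, dtype=np.int8)
    C = np.full(n, CYCLE_NOR, dtype=np.int8)
    alive = np.ones(n, dtype=bool)

    cycle_types = np.full((n, G + 1), -1, dtype=np.int8)
    durations = np.full((n, G + 1), np.nan)
    shortest = np.full((n, G + 1), -1, dtype=np.int32)
    gen_death = np.full(n, -1, dtype=np.int32)
    death_cause = np.full(n, DEATH_NONE, dtype=np.int8)
    onset_len = np.full(n, -1, dtype=np.int32)

    # generation 0: founder completes one normal cycle before dividing
    cycle_types[:, 0] = CYCLE_NOR
    durations[:, 0] = bank.sample_batch(T, C, hub.durations)
    shortest[:, 0] = L.min(axis=(1, 2))

    for g in range(1, G + 1):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        m = idx.size
        coupling = hub.telomeres.integers(0, 2, size=(m, N_CHROMOSOMES))
        pick = hub.telomeres.integers(0, 2, size=m).astype(bool)
        d1, d2 = divide_batch(L[idx], params.h, coupling)
        newL = np.where(pick[:, None, None], d1, d2)
        lmin = newL.min(axis=(1, 2))

        a, T_new, C_new, cause = daughter_fates(T[idx], C[idx], lmin, params, hub.fates)

        died = ~a
        gen_death[idx[died]] = g
        death_cause[idx[died]] = cause[died]
        alive[idx[died]] = False

        surv = idx[a]
        L[surv] = newL[a]
        onset = a & (C_new == CYCLE_SEN) & (C[idx] != CYCLE_SEN)
        onset_len[idx[onset]] = lmin[onset]
        T[surv] = T_new[a]
        C[surv] = C_new[a]
        cycle_types[surv, g] = C_new[a]
        shortest[surv, g] = lmin[a]
        durations[surv, g] = bank.sample_batch(T_new[a], C_new[a], hub.durations)

    truncated = alive.copy()
    return LineageBatch(
        cycle_types=cycle_types,
        durations=durations,
        shortest=shortest,
        gen_death=gen_death,
        death_cause=death_cause,
        truncated=truncated,
        shortest_at_sen_onset=onset_len,
        D=params.D,
    )


def simulate_lineage(
    params: LawParams,
    dist: InitialDistribution,
    bank: DurationBank,
    rng: RngHub | int,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> LineageRecord:
    """Simulate one lineage and return its record."""
    return simulate_lineages(1, params, dist, bank, rng, max_generations).records()[0]


def classify_lineage(
    record: LineageRecord, D: float
) -> tuple[str, bool]:
    """Classify one record from its durations only.

    Observed type B iff a long cycle (>= ``D``) is later followed by a
    normal one; ``is_M`` flags ground-truth type-B records observed as A.
    """
    dur = np.asarray(record.durations, dtype=float)
    long = dur >= D
    observed_b = False
    if dur.size > 1:
        normal_after = np.flip(np.maximum.accumulate(np.flip(~long[1:])))
        observed_b = bool(np.any(long[:-1] & normal_after))
    had_nta = bool((np.asarray(record.cycle_types) == CYCLE_NTA).any())
    observed = "B" if observed_b else "A"
    return observed, (observed == "A") and had_nta


CURVE_CATEGORIES = ("nta", "sen_A", "sen_B", "sen")


def arrest_generation_curves(batch: LineageBatch) -> dict[str, np.ndarray]:
    """Ascending generation-of-arrest curves, split by observed labels.

    ``nta``: generation of the first non-terminal arrest; ``sen_A`` /
    ``sen_B``: generation of the first senescent cycle among lineages
    observationally classified A / B; ``sen``: same, all lineages pooled.
    Lineages without the event do not contribute to that curve.
    """
    observed_b, _ = batch.classify()
    first_nta = batch.gen_first_nta
    first_sen = batch.gen_sen
    has_sen = first_sen >= 0
    return {
        "nta": np.sort(first_nta[first_nta >= 0]),
        "sen_A": np.sort(first_sen[has_sen & ~observed_b]),
        "sen_B": np.sort(first_sen[has_sen & observed_b]),
        "sen": np.sort(first_sen[has_sen]),
    }


def observed_type_b_proportion(batch: LineageBatch) -> float:
    """Fraction of lineages observationally classified as type B."""
    observed_b, _ = batch.classify()
    return float(observed_b.mean())
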