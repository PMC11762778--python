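"""Probability laws of cell-cycle arrest and the per-division fate kernel.

Each division, a daughter cell's fate depends on its mother's state and on
its own shortest telomere length ``l`` (measured after shortening):

* constant accidental death ``p_accident`` (telomere-independent);
* a senescent mother propagates senescence; each completed senescent cycle
  ends the sequence (death) with probability ``p_death``, so the number of
  consecutive senescent cycles is geometric with mean ``1/p_death``;
* a mother in non-terminal arrest (nta) exits back to normal cycling with
  probability ``p_repair`` per long cycle (repair or adaptation pooled),
  otherwise the arrest sequence continues;
* a normally cycling type-A mother's daughter enters terminal senescence
  with ``p_sen_A(l)`` (near-deterministic threshold at ``l_min_A``), else
  a first non-terminal arrest with ``p_nta(l)``, which converts the
  lineage to type B;
* a normally cycling type-B daughter enters senescence with the flat law
  ``p_sen_B(l)``, else a further nta with ``p_nta(l)``.

All the length-dependent laws share one functional form,
``p(l) = min(1, b * exp(-a * l))`` for ``l > l_min`` and ``p(l) = 1`` at or
below the hard threshold ``l_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Optional

import numpy as np
from numpy.random import Generator


class ParameterError(ValueError):
    """Arrest-law parameter out of its admissible range."""


class StateError(ValueError):
    """Unknown cell type / cycle-type combination."""


# integer codes used by the vectorized simulators
TYPE_A, TYPE_B = 0, 1
CYCLE_NOR, CYCLE_NTA, CYCLE_SEN = 0, 1, 2
DEATH_NONE, DEATH_ACCIDENT, DEATH_SENESCENCE = 0, 1, 2

TYPE_LABELS = {TYPE_A: "A", TYPE_B: "B"}
CYCLE_LABELS = {CYCLE_NOR: "nor", CYCLE_NTA: "nta", CYCLE_SEN: "sen"}
DEATH_LABELS = {DEATH_NONE: "", DEATH_ACCIDENT: "accident", DEATH_SENESCENCE: "senescence"}


@dataclass
class LawParams:
    """All arrest/shortening constants (defaults: best-fit WT values)."""

    a_nta: float = 0.02
    b_nta: float = 0.44
    a_sen_A: float = 0.19
    b_sen_A: float = 0.73
    a_sen_B: float = 0.0
    b_sen_B: float = 0.12
    l_min_A: float = 27.0
    l_min_B: float = 0.0
    p_accident: float = 4.3e-3
    p_repair: float = 0.65
    p_death: float = 0.58
    h: int = 7
    D: float = 180.0

    def __post_init__(self) -> None:
        for name in ("a_nta", "b_nta", "a_sen_A", "b_sen_A", "a_sen_B", "b_sen_B"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("l_min_A", "l_min_B"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("p_accident", "p_repair", "p_death"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if self.h < 0:
            raise ParameterError(f"h must be >= 0, got {self.h}")
        if self.D <= 0:
            raise ParameterError(f"D must be > 0, got {self.D}")

    def replace(self, **kwargs) -> "LawParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def eval_arrest_law(a: float, b: float, l_min: float, l):
    """``min(1, b e^{-a l})`` above the threshold, 1 at or below it."""
    if a < 0 or b < 0:
        raise ParameterError(f"law coefficients must be >= 0, got a={a}, b={b}")
    l = np.asarray(l, dtype=float)
    p = np.where(l <= l_min, 1.0, np.minimum(1.0, b * np.exp(-a * l)))
    return p if p.ndim else float(p)


def p_nta(params: LawParams, l):
    """Non-terminal-arrest onset law (no hard threshold)."""
    return eval_arrest_law(params.a_nta, params.b_nta, -np.inf, l)


def p_sen_A(params: LawParams, l):
    return eval_arrest_law(params.a_sen_A, params.b_sen_A, params.l_min_A, l)


def p_sen_B(params: LawParams, l):
    return eval_arrest_law(params.a_sen_B, params.b_sen_B, params.l_min_B, l)


def daughter_fates(
    mother_type: np.ndarray,
    mother_cycle: np.ndarray,
    shortest: np.ndarray,
    params: LawParams,
    rng: Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fate kernel for a batch of daughters.

    Events are resolved in a fixed order per daughter: accidental death,
    then inherited senescence (with the per-cycle death draw), then an
    inherited nta sequence (repair or continue), then — for normally
    cycling mothers — senescence onset before nta onset.

    Returns ``(alive, cell_type, cycle_type, death_cause)`` arrays.
    """
    mt = np.asarray(mother_type)
    mc = np.asarray(mother_cycle)
    l = np.asarray(shortest, dtype=float)
    n = mt.shape[0]
    if not np.isin(mt, (TYPE_A, TYPE_B)).all() or not np.isin(
        mc, (CYCLE_NOR, CYCLE_NTA, CYCLE_SEN)
    ).all():
        raise StateError("unknown cell type or cycle type code")

    # fixed draw layout (4 uniforms per daughter) keeps replay deterministic
    u_accident = rng.random(n)
    u_exit = rng.random(n)     # death draw (sen mothers) / repair draw (nta mothers)
    u_sen = rng.random(n)
    u_nta = rng.random(n)

    alive = np.ones(n, dtype=bool)
    cause = np.full(n, DEATH_NONE, dtype=np.int8)
    T = mt.astype(np.int8).copy()
    C = np.full(n, CYCLE_NOR, dtype=np.int8)

    # (1) accident, regardless of state
    acc = u_accident < params.p_accident
    alive[acc] = False
    cause[acc] = DEATH_ACCIDENT

    # (2) inherited senescence: absorbing; geometric exit by death
    sen = (mc == CYCLE_SEN) & alive
    C[mc == CYCLE_SEN] = CYCLE_SEN
    die = sen & (u_exit < params.p_death)
    alive[die] = False
    cause[die] = DEATH_SENESCENCE

    # (3) inherited nta sequence: repair/adapt back to (B, nor) or continue
    nta = (mc == CYCLE_NTA) & alive
    repaired = nta & (u_exit < params.p_repair)
    C[nta & ~repaired] = CYCLE_NTA
    # repaired cells already have C = nor; T stays B (enforced below)
    T[mc == CYCLE_NTA] = TYPE_B

    # (4) normally cycling mothers: senescence onset, then nta onset
    nor = (mc == CYCLE_NOR) & alive
    is_a = nor & (mt == TYPE_A)
    is_b = nor & (mt == TYPE_B)
    psen = np.zeros(n)
    psen[is_a] = p_sen_A(params, l[is_a])
    psen[is_b] = p_sen_B(params, l[is_b])
    onset = nor & (u_sen < psen)
    C[onset] = CYCLE_SEN
    fresh = nor & ~onset & (u_nta < p_nta(params, l))
    C[fresh] = CYCLE_NTA
    T[fresh] = TYPE_B

    return alive, T, C, cause


@dataclass
class CellState:
    """One cell's full state ``(L, T, C, tau, X)`` for scalar-path use."""

    L: np.ndarray
    T: int = TYPE_A
    C: int = CYCLE_NOR
    tau: float = np.nan
    generation: int = 0
    birth_time: float = 0.0
    ancestor: int = 0
    ever_nta: bool = False
    ever_nor_after_arrest: bool = False

    def __post_init__(self) -> None:
        if self.T == TYPE_A and self.ever_nta:
            raise StateError("a type-A cell cannot have experienced an nta")


@dataclass
class FateResult:
    alive: bool
    T: int
    C: int
    death_cause: int

    @property
    def death_label(self) -> str:
        return DEATH_LABELS[self.death_cause]


def next_cell_fate(
    mother: CellState,
    daughter_L: np.ndarray,
    params: LawParams,
    rng: Generator,
) -> FateResult:
    """Scalar fate of one daughter (thin wrapper over the batch kernel)."""
    if mother.T not in (TYPE_A, TYPE_B) or mother.C not in (
        CYCLE_NOR,
        CYCLE_NTA,
        CYCLE_SEN,
    ):
        raise StateError(f"unknown mother state T={mother.T}, C={mother.C}")
    l = int(np.min(daughter_L))
    alive, T, C, cause = daughter_fates(
        np.array([mother.T]),
        np.array([mother.C]),
        np.array([l], dtype=float),
        params,
        rng,
    )
    return FateResult(bool(alive[0]), int(T[0]), int(C[0]), int(cause[0]))
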