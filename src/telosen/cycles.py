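"""Empirical cell-cycle-duration banks and uniform resampling.

The model does not posit a parametric law for cycle durations: it
resamples, uniformly, from four empirical subdatasets split by
(cell type, cycle type) — normal cycles of type-A cells, normal cycles of
type-B cells, non-terminal-arrest cycles and senescent cycles (the last
two pooled across types).  The duration threshold ``D`` = 180 min
partitions the four banks: every normal duration is below ``D``, every
arrest duration at or above it.

A user bank is a CSV with columns ``cell_type, cycle_type,
duration_minutes``; when none is supplied, a synthetic bank emulates the
published shapes (normal cycles centred on the wild-type 90 min doubling
time; arrest cycles supported above 180 min with a heavy right tail).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from numpy.random import Generator

from .arrest import CYCLE_NOR, CYCLE_NTA, CYCLE_SEN, TYPE_A, TYPE_B, StateError

DEFAULT_D = 180.0

#: bank categories, keyed by (cell_type, cycle_type) labels
CATEGORIES = (("A", "nor"), ("B", "nor"), ("any", "nta"), ("any", "sen"))


class BankError(ValueError):
    """Invalid duration bank (empty category or D-partition violation)."""


@dataclass
class SyntheticBankSpec:
    """Parameters of the synthetic stand-in duration bank.

    Normal cycles are log-normal-shaped around the 90-min wild-type
    division time, clipped below the long-cycle threshold; arrest cycles
    are ``D`` plus a heavy-tailed log-normal excess.  All values are
    configuration, not constants, and are echoed in run manifests.
    """

    median_nor_A: float = 88.0
    sigma_nor_A: float = 0.17
    median_nor_B: float = 92.0
    sigma_nor_B: float = 0.20
    median_excess_nta: float = 60.0
    sigma_excess_nta: float = 0.80
    median_excess_sen: float = 120.0
    sigma_excess_sen: float = 0.90
    n_per_category: int = 500
    min_duration: float = 60.0
    max_duration: float = 1000.0
    D: float = DEFAULT_D

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DurationBank:
    """Four validated duration samples (minutes), resampled uniformly."""

    samples: dict[tuple[str, str], np.ndarray]
    D: float = DEFAULT_D
    source: str = "unspecified"

    def __post_init__(self) -> None:
        for key in CATEGORIES:
            if key not in self.samples:
                raise BankError(f"missing duration category {key}")
            arr = np.asarray(self.samples[key], dtype=float).ravel()
            if arr.size == 0:
                raise BankError(f"empty duration category {key}")
            if (arr <= 0).any():
                raise BankError(f"non-positive duration in category {key}")
            cycle = key[1]
            if cycle == "nor" and (arr >= self.D).any():
                bad = float(arr[arr >= self.D][0])
                raise BankError(
                    f"normal-cycle duration {bad} min in category {key} "
                    f"violates the D = {self.D} min partition"
                )
            if cycle in ("nta", "sen") and (arr < self.D).any():
                bad = float(arr[arr < self.D][0])
                raise BankError(
                    f"arrest duration {bad} min in category {key} "
                    f"is below the D = {self.D} min partition"
                )
            self.samples[key] = arr

    @property
    def min_duration(self) -> float:
        return min(float(arr.min()) for arr in self.samples.values())

    def _category(self, cell_type: int, cycle_type: int) -> tuple[str, str]:
        if cycle_type == CYCLE_NOR:
            if cell_type == TYPE_A:
                return ("A", "nor")
            if cell_type == TYPE_B:
                return ("B", "nor")
            raise StateError(f"unknown cell type code {cell_type}")
        if cycle_type == CYCLE_NTA:
            return ("any", "nta")
        if cycle_type == CYCLE_SEN:
            return ("any", "sen")
        raise StateError(f"unknown cycle type code {cycle_type}")

    def sample(self, cell_type: int, cycle_type: int, rng: Generator) -> float:
        """One uniform draw from the matching subdataset."""
        arr = self.samples[self._category(cell_type, cycle_type)]
        return float(arr[rng.integers(0, arr.size)])

    def sample_batch(
        self, cell_type: np.ndarray, cycle_type: np.ndarray, rng: Generator
    ) -> np.ndarray:
        """Uniform draws for a batch of cells, by category masks.

        Draws are consumed category-by-category in the fixed order of
        ``CATEGORIES`` so replays are deterministic.
        """
        ct = np.asarray(cell_type)
        cy = np.asarray(cycle_type)
        out = np.empty(ct.shape[0], dtype=float)
        masks = {
            ("A", "nor"): (cy == CYCLE_NOR) & (ct == TYPE_A),
            ("B", "nor"): (cy == CYCLE_NOR) & (ct == TYPE_B),
            ("any", "nta"): cy == CYCLE_NTA,
            ("any", "sen"): cy == CYCLE_SEN,
        }
        for key in CATEGORIES:
            mask = masks[key]
            k = int(mask.sum())
            if k:
                arr = self.samples[key]
                out[mask] = arr[rng.integers(0, arr.size, size=k)]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, c, d)
            for (t, c) in CATEGORIES
            for d in self.samples[(t, c)]
        ]
        return pd.DataFrame(rows, columns=["cell_type", "cycle_type", "duration_minutes"])


def sample_cycle_duration(
    bank: DurationBank, cell_type: int, cycle_type: int, rng: Generator
) -> float:
    """Functional alias for :meth:`DurationBank.sample`."""
    return bank.sample(cell_type, cycle_type, rng)


def load_bank(path: Union[str, Path], D: float = DEFAULT_D) -> DurationBank:
    """Load a duration bank from CSV and validate the D-partition."""
    df = pd.read_csv(path)
    required = {"cell_type", "cycle_type", "duration_minutes"}
    if not required.issubset(df.columns):
        raise BankError(f"bank file must have columns {sorted(required)}")
    samples: dict[tuple[str, str], list[float]] = {key: [] for key in CATEGORIES}
    for row in df.itertuples(index=False):
        t = str(row.cell_type)
        c = str(row.cycle_type)
        if c in ("nta", "sen"):
            key = ("any", c)
        elif c == "nor" and t in ("A", "B"):
            key = (t, "nor")
        else:
            raise BankError(f"unrecognized bank row (cell_type={t}, cycle_type={c})")
        samples[key].append(float(row.duration_minutes))
    return DurationBank({k: np.asarray(v) for k, v in samples.items()}, D=D,
                        source=str(path))


def synthetic_bank(
    rng: Generator, spec: Optional[SyntheticBankSpec] = None
) -> DurationBank:
    """Generate the synthetic stand-in bank from ``spec``."""
    spec = spec or SyntheticBankSpec()
    n = spec.n_per_category

    def lognorm(median: float, sigma: float, size: int) -> np.ndarray:
        return median * np.exp(sigma * rng.standard_normal(size))

    nor_a = np.clip(lognorm(spec.median_nor_A, spec.sigma_nor_A, n),
                    spec.min_duration, spec.D - 1.0)
    nor_b = np.clip(lognorm(spec.median_nor_B, spec.sigma_nor_B, n),
                    spec.min_duration, spec.D - 1.0)
    nta = np.clip(spec.D + lognorm(spec.median_excess_nta, spec.sigma_excess_nta, n),
                  spec.D, spec.max_duration)
    sen = np.clip(spec.D + lognorm(spec.median_excess_sen, spec.sigma_excess_sen, n),
                  spec.D, spec.max_duration)
    samples = {
        ("A", "nor"): nor_a,
        ("B", "nor"): nor_b,
        ("any", "nta"): nta,
        ("any", "sen"): sen,
    }
    return DurationBank(samples, D=spec.D, source="synthetic")


def get_bank(
    source: Union[str, Path, SyntheticBankSpec, None],
    rng: Optional[Generator] = None,
    D: float = DEFAULT_D,
) -> DurationBank:
    """Resolve a bank from a CSV path, a synthetic spec, or the default.

    A synthetic source requires ``rng`` (the bank is itself a random,
    seed-stamped dataset standing in for the published subdatasets).
    """
    if isinstance(source, (str, Path)):
        return load_bank(source, D=D)
    spec = source if isinstance(source, SyntheticBankSpec) else SyntheticBankSpec(D=D)
    if rng is None:
        raise BankError("a synthetic bank needs an rng stream")
    return synthetic_bank(rng, spec)
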