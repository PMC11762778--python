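"""Competing-cell population dynamics under daily saturation and dilution.

Cells grow in continuous time: a cell born at time ``t`` with cycle
duration ``tau`` divides at ``t + tau`` into two daughters, each of which
independently receives a fate (accident, senescence propagation/death,
arrest onset, ...) and a new cycle duration.  As soon as the living count
reaches the saturation cap ``N_sat = r_sat * N_init`` the culture stops
dividing: pending divisions are frozen and resume, with their remaining
cycle time intact, after the next dilution.  Every 24 h the population is
diluted by sampling ``N_dil`` cells uniformly without replacement.

Internally the event queue is processed in sub-windows no wider than the
shortest bank duration, so every daughter born inside a window divides in
a later window and each window can be handled as one vectorized batch in
time order (the ordering is what decides which cells divide before the
cap is hit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .arrest import (
    CYCLE_NOR,
    CYCLE_NTA,
    CYCLE_SEN,
    LawParams,
    TYPE_A,
    TYPE_B,
    daughter_fates,
)
from .cycles import DurationBank
from .rng import RngHub, as_hub
from .telomeres import InitialDistribution, N_CHROMOSOMES, divide_batch

MINUTES_PER_HOUR = 60.0


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass
class ExperimentConfig:
    """Serial-dilution culture protocol."""

    n_init: int = 300
    r_sat: float = 1000.0
    n_dil: Optional[int] = None          # defaults to n_init
    n_days: int = 10
    dilution_period_h: float = 24.0
    snapshot_interval_h: float = 1.0
    ancestry_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_init < 1:
            raise ConfigError(f"n_init must be >= 1, got {self.n_init}")
        if self.r_sat <= 1:
            raise ConfigError(f"r_sat must be > 1, got {self.r_sat}")
        if self.n_dil is None:
            self.n_dil = self.n_init
        if self.n_dil > self.n_sat:
            raise ConfigError(f"n_dil={self.n_dil} exceeds N_sat={self.n_sat}")
        if self.n_days < 1 or self.dilution_period_h <= 0:
            raise ConfigError("need n_days >= 1 and a positive dilution period")
        if self.ancestry_bins < 1:
            raise ConfigError("ancestry_bins must be >= 1")

    @property
    def n_sat(self) -> int:
        return int(round(self.r_sat * self.n_init))


class _Cells:
    """Structure-of-arrays container for the living population."""

    __slots__ = ("L", "T", "C", "gen", "anc", "ever_nta", "ever_nor_after", "t_div")

    def __init__(self, **arrays):
        for name in self.__slots__:
            setattr(self, name, arrays[name])

    @property
    def count(self) -> int:
        return self.T.shape[0]

    def select(self, idx) -> None:
        for name in self.__slots__:
            setattr(self, name, getattr(self, name)[idx])

    @classmethod
    def concat(cls, a: "_Cells", b: dict) -> "_Cells":
        return cls(
            **{
                name: np.concatenate([getattr(a, name), b[name]])
                for name in cls.__slots__
            }
        )


@dataclass
class PopulationResult:
    """Everything a population run records."""

    snapshots: pd.DataFrame
    onsets: pd.DataFrame              # one row per senescence onset
    ancestry: pd.DataFrame            # living-cell share per ancestor bin, per day
    end_of_day_counts: np.ndarray     # pre-dilution counts, days 1..n
    n_sat: int
    extinction_time_h: Optional[float]
    config: ExperimentConfig
    params: LawParams

    @property
    def extinct(self) -> bool:
        return self.extinction_time_h is not None

    def hsl_hours(self) -> float:
        return compute_hsl(
            self.end_of_day_counts,
            self.n_sat,
            period_h=self.config.dilution_period_h,
            extinction_time_h=self.extinction_time_h,
        )


def summarize_population(cells: _Cells | dict, time_h: float) -> dict:
    """All per-timepoint aggregates for one snapshot row.

    The telomere mode is the most frequent integer length over every
    telomere of every living cell; ties break toward the smallest length
    (``np.argmax`` returns the first maximum).
    """
    if isinstance(cells, dict):
        cells = _Cells(**cells)
    n = cells.count
    row: dict = {"time_h": time_h, "count": n}
    if n == 0:
        for k in (
            "frac_A", "frac_B", "frac_nor", "frac_nta", "frac_sen",
            "telo_mean", "telo_mode", "shortest_mean", "shortest_min",
            "shortest_max", "gen_mean", "gen_var",
        ):
            row[k] = np.nan
        return row
    flat = cells.L.reshape(n, -1)
    per_cell_min = flat.min(axis=1)
    counts = np.bincount(flat.ravel())
    total = counts.sum()
    mean_len = float((np.arange(counts.size) * counts).sum() / total)
    row["frac_A"] = float((cells.T == TYPE_A).mean())
    row["frac_B"] = float((cells.T == TYPE_B).mean())
    row["frac_nor"] = float((cells.C == CYCLE_NOR).mean())
    row["frac_nta"] = float((cells.C == CYCLE_NTA).mean())
    row["frac_sen"] = float((cells.C == CYCLE_SEN).mean())
    row["telo_mean"] = mean_len
    row["telo_mode"] = int(np.argmax(counts))
    row["shortest_mean"] = float(per_cell_min.mean())
    row["shortest_min"] = int(per_cell_min.min())
    row["shortest_max"] = int(per_cell_min.max())
    row["gen_mean"] = float(cells.gen.mean())
    row["gen_var"] = float(cells.gen.var())
    return row


def _ancestry_row(cells: _Cells, time_h: float, bins: int) -> dict:
    row = {"time_h": time_h}
    n = cells.count
    for b in range(bins):
        row[f"bin_{b}"] = float((cells.anc == b).sum()) / n if n else np.nan
    return row


def run_population_experiment(
    config: ExperimentConfig,
    params: LawParams,
    dist: InitialDistribution,
    bank: DurationBank,
    rng: RngHub | int,
) -> PopulationResult:
    """Run one serial-dilution senescence experiment."""
    hub = as_hub(rng)
    n_sat = config.n_sat
    day_min = config.dilution_period_h * MINUTES_PER_HOUR
    snap_min = config.snapshot_interval_h * MINUTES_PER_HOUR

    # founders: type A, normal cycle, i.i.d. telomeres, ancestry bins by
    # ranking on the founder's shortest telomere (equally sized bins)
    n0 = config.n_init
    L0 = dist.sample_matrices(n0, hub.init).astype(np.int16)
    founder_min = L0.reshape(n0, -1).min(axis=1)
    order = np.argsort(founder_min, kind="stable")
    anc = np.empty(n0, dtype=np.int16)
    anc[order] = (np.arange(n0) * config.ancestry_bins) // n0
    T0 = np.full(n0, TYPE_A, dtype=np.int8)
    C0 = np.full(n0, CYCLE_NOR, dtype=np.int8)
    cells = _Cells(
        L=L0,
        T=T0,
        C=C0,
        gen=np.zeros(n0, dtype=np.int32),
        anc=anc,
        ever_nta=np.zeros(n0, dtype=bool),
        ever_nor_after=np.zeros(n0, dtype=bool),
        t_div=bank.sample_batch(T0, C0, hub.durations),
    )

    window = min(snap_min, max(bank.min_duration, 1.0))
    snapshots: list[dict] = []
    ancestry_rows: list[dict] = []
    onset_chunks: list[tuple] = []
    end_of_day_counts: list[int] = []
    extinction_time: Optional[float] = None

    snapshots.append(summarize_population(cells, 0.0))
    ancestry_rows.append(_ancestry_row(cells, 0.0, config.ancestry_bins))

    def process_batch(idx: np.ndarray, t_cap: float) -> tuple[int, Optional[float]]:
        """Divide cells ``idx`` (time-sorted) until the count hits n_sat.

        Returns (number of divisions executed, saturation instant or None).
        """
        times = cells.t_div[idx]
        parents = cells.L[idx]
        m = idx.size
        coupling = hub.telomeres.integers(0, 2, size=(m, N_CHROMOSOMES))
        d1, d2 = divide_batch(parents, params.h, coupling)
        lmin1 = d1.reshape(m, -1).min(axis=1)
        lmin2 = d2.reshape(m, -1).min(axis=1)
        a1, T1, C1, _ = daughter_fates(cells.T[idx], cells.C[idx], lmin1, params, hub.fates)
        a2, T2, C2, _ = daughter_fates(cells.T[idx], cells.C[idx], lmin2, params, hub.fates)

        net = a1.astype(np.int64) + a2.astype(np.int64) - 1
        traj = cells.count + np.cumsum(net)
        hit = traj >= n_sat
        if hit.any():
            k = int(np.argmax(hit)) + 1
            t_sat = float(times[k - 1])
        else:
            k = m
            t_sat = None

        exec_idx = idx[:k]
        mother_C = cells.C[exec_idx]
        mother_ever_nta = cells.ever_nta[exec_idx]
        mother_ever_nor = cells.ever_nor_after[exec_idx]
        mother_gen = cells.gen[exec_idx] + 1
        mother_anc = cells.anc[exec_idx]
        t_birth = times[:k]

        new = {name: [] for name in _Cells.__slots__}
        for a, Td, Cd, Ld, lm in (
            (a1[:k], T1[:k], C1[:k], d1[:k], lmin1[:k]),
            (a2[:k], T2[:k], C2[:k], d2[:k], lmin2[:k]),
        ):
            keep = a
            onset = keep & (Cd == CYCLE_SEN) & (mother_C != CYCLE_SEN)
            if onset.any():
                onset_chunks.append(
                    (
                        t_birth[onset] / MINUTES_PER_HOUR,
                        Td[onset].copy(),
                        mother_ever_nta[onset] & mother_ever_nor[onset],
                        lm[onset].astype(np.int32),
                    )
                )
            new["L"].append(Ld[keep])
            new["T"].append(Td[keep])
            new["C"].append(Cd[keep])
            new["gen"].append(mother_gen[keep])
            new["anc"].append(mother_anc[keep])
            e_nta = mother_ever_nta[keep] | (Cd[keep] == CYCLE_NTA)
            new["ever_nta"].append(e_nta)
            new["ever_nor_after"].append(
                mother_ever_nor[keep] | (e_nta & (Cd[keep] == CYCLE_NOR))
            )
            dur = bank.sample_batch(Td[keep], Cd[keep], hub.durations)
            new["t_div"].append(t_birth[keep] + dur)

        merged = {name: np.concatenate(new[name]) for name in _Cells.__slots__}
        survivor_mask = np.ones(cells.count, dtype=bool)
        survivor_mask[exec_idx] = False
        cells.select(survivor_mask)
        for name in _Cells.__slots__:
            setattr(
                cells, name, np.concatenate([getattr(cells, name), merged[name]])
            )
        return k, t_sat

    for day in range(config.n_days):
        day_start = day * day_min
        day_end = day_start + day_min
        saturated_at: Optional[float] = None
        frozen_row: Optional[dict] = None
        next_snap = day_start + snap_min

        t = day_start
        while t < day_end - 1e-9:
            t_hi = min(t + window, day_end)
            if saturated_at is None:
                # daughters born in [t, t_hi) cannot divide before t_hi
                # because every bank duration >= the window width
                # boundary events belong to this window; daughters born
                # strictly inside it divide strictly after t_hi
                pending = np.nonzero(cells.t_div < t_hi + 1e-9)[0]
                if pending.size:
                    order = np.argsort(cells.t_div[pending], kind="stable")
                    _, t_sat = process_batch(pending[order], t_hi)
                    if t_sat is not None:
                        saturated_at = t_sat
            if t_hi >= next_snap - 1e-6 or t_hi >= day_end - 1e-9:
                if saturated_at is not None and frozen_row is not None:
                    row = dict(frozen_row)  # composition frozen at saturation
                    row["time_h"] = t_hi / MINUTES_PER_HOUR
                else:
                    row = summarize_population(cells, t_hi / MINUTES_PER_HOUR)
                    if saturated_at is not None:
                        frozen_row = row
                snapshots.append(row)
                while next_snap <= t_hi + 1e-6:
                    next_snap += snap_min
            t = t_hi
            if cells.count == 0:
                break

        end_of_day_counts.append(cells.count)
        ancestry_rows.append(
            _ancestry_row(cells, day_end / MINUTES_PER_HOUR, config.ancestry_bins)
        )
        if cells.count == 0:
            extinction_time = day_end / MINUTES_PER_HOUR
            break

        # daily dilution: uniform without-replacement sample of n_dil cells
        if cells.count > config.n_dil:
            keep = hub.dilution.choice(cells.count, size=config.n_dil, replace=False)
            cells.select(np.sort(keep))
        # frozen cells resume with their remaining cycle time intact
        if saturated_at is not None:
            cells.t_div = cells.t_div + (day_end - saturated_at)

    if cells.count == 0 and extinction_time is None:
        extinction_time = config.n_days * config.dilution_period_h

    snap_df = pd.DataFrame(snapshots)
    if onset_chunks:
        o_time = np.concatenate([c[0] for c in onset_chunks])
        o_type = np.concatenate([c[1] for c in onset_chunks])
        o_obs_b = np.concatenate([c[2] for c in onset_chunks])
        o_len = np.concatenate([c[3] for c in onset_chunks])
    else:
        o_time = np.empty(0)
        o_type = np.empty(0, dtype=np.int8)
        o_obs_b = np.empty(0, dtype=bool)
        o_len = np.empty(0, dtype=np.int32)
    labels = np.array(["A", "B"])
    onsets_df = pd.DataFrame(
        {
            "time_h": o_time,
            "type_true": labels[o_type.astype(int)],
            "observed_type": labels[o_obs_b.astype(int)],
            "shortest_at_onset_bp": o_len,
        }
    )
    ancestry_df = pd.DataFrame(ancestry_rows)
    return PopulationResult(
        snapshots=snap_df,
        onsets=onsets_df,
        ancestry=ancestry_df,
        end_of_day_counts=np.asarray(end_of_day_counts, dtype=float),
        n_sat=n_sat,
        extinction_time_h=extinction_time,
        config=config,
        params=params,
    )


def dilute(count: int, n_dil: int, rng) -> np.ndarray:
    """Indices of the cells retained at a dilution (uniform, no replacement)."""
    if n_dil >= count:
        return np.arange(count)
    return np.sort(rng.choice(count, size=n_dil, replace=False))


def compute_hsl(
    end_of_day_counts,
    n_sat: float,
    period_h: float = 24.0,
    extinction_time_h: Optional[float] = None,
) -> float:
    """Half-saturation-limit time (hours since telomerase inactivation).

    Linear interpolation between the last day whose pre-dilution count is
    still at least ``n_sat / 2`` and the first day below it.  Counts are
    indexed from day 1 (the first dilution).  Returns ``inf`` when the
    culture never falls below half-saturation (right-censored).  If the
    very first day is already below half-saturation the crossing was not
    observed; the extinction time (if any) or the first measurement time
    is returned.
    """
    counts = np.asarray(end_of_day_counts, dtype=float)
    if counts.size < 1:
        raise ValueError("need at least one end-of-day count")
    half = n_sat / 2.0
    below = counts < half
    if not below.any():
        return float("inf")
    j = int(np.argmax(below))
    if j == 0:
        if extinction_time_h is not None and extinction_time_h <= period_h:
            return float(extinction_time_h)
        return float(period_h)
    i = j - 1
    frac = (counts[i] - half) / (counts[i] - counts[j])
    return float((i + 1) * period_h + period_h * frac)
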