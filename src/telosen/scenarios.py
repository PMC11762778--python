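"""In-silico perturbation experiments on the calibrated model.

Three scans quantify how population senescence kinetics — summarized by
the half-saturation-limit time (HSL) — respond to perturbations of the
initial state or of telomere-independent mortality:

* translating the whole initial telomere-length distribution by a signed
  number of bp (telomere-length homeostasis mutants);
* stretching or compressing only the left flank of the distribution (the
  shortest telomeres) via the dilation parameter ``l_0``;
* scaling the constant accidental mortality ``p_accident`` (cytotoxic
  stress, repair mutants such as rad51), in population mode (HSL) or in
  lineage mode (median generation of senescence onset).

Every scan is run with paired seeds: all conditions of replicate ``i``
reuse bit-identical RNG streams, so per-replicate differences against the
control isolate the parameter effect (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arrest import LawParams
from .cycles import DurationBank
from .lineage import simulate_lineages
from .population import ExperimentConfig, PopulationResult, run_population_experiment
from .rng import RngHub, as_hub, replicate_sequences
from .telomeres import InitialDistribution

RAD51_P_ACCIDENT = 0.054  # constant mortality measured for rad51 deletion


def _daily_mean_telomere(result: PopulationResult) -> pd.DataFrame:
    """End-of-day population mean telomere length (pre-dilution)."""
    snaps = result.snapshots
    period = result.config.dilution_period_h
    days = np.arange(1, len(result.end_of_day_counts) + 1)
    rows = []
    for d in days:
        at = snaps[np.isclose(snaps["time_h"], d * period)]
        if len(at):
            rows.append((int(d), float(at["telo_mean"].iloc[-1])))
    return pd.DataFrame(rows, columns=["day", "telo_mean"])


def _paired_runs(
    conditions: dict,
    make_inputs,
    config: ExperimentConfig,
    params: LawParams,
    bank: DurationBank,
    n_replicates: int,
    rng: RngHub | int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every condition against every paired replicate seed.

    ``make_inputs(condition_value)`` returns the ``(params, dist)`` pair
    for that condition; seeds are shared across conditions.
    """
    seeds = replicate_sequences(rng, n_replicates)
    hsl_rows = []
    track_rows = []
    for label, value in conditions.items():
        run_params, run_dist = make_inputs(value)
        for i, seq in enumerate(seeds):
            result = run_population_experiment(
                config, run_params, run_dist, bank, RngHub(seq)
            )
            hsl_rows.append((label, value, i, result.hsl_hours()))
            for day, telo in _daily_mean_telomere(result).itertuples(index=False):
                track_rows.append((label, value, i, day, telo))
    hsl = pd.DataFrame(hsl_rows, columns=["condition", "value", "replicate", "hsl_h"])
    tracks = pd.DataFrame(
        track_rows, columns=["condition", "value", "replicate", "day", "telo_mean"]
    )
    return hsl, tracks


def _summarize_paired(hsl: pd.DataFrame, control_label) -> pd.DataFrame:
    """Per-condition HSL statistics and paired differences vs the control."""
    control = hsl[hsl["condition"] == control_label].set_index("replicate")["hsl_h"]
    rows = []
    for label, grp in hsl.groupby("condition", sort=False):
        by_rep = grp.set_index("replicate")["hsl_h"]
        finite = np.isfinite(by_rep)
        paired = by_rep[finite & np.isfinite(control.reindex(by_rep.index))]
        delta = paired - control.reindex(paired.index)
        rows.append(
            {
                "condition": label,
                "value": grp["value"].iloc[0],
                "n": len(by_rep),
                "n_censored": int((~finite).sum()),
                "mean_hsl_h": float(by_rep[finite].mean()) if finite.any() else np.nan,
                "sd_hsl_h": float(by_rep[finite].std(ddof=1))
                if finite.sum() > 1
                else np.nan,
                "mean_delta_hsl_h": float(delta.mean()) if len(delta) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_translation_scan(
    deltas: Sequence[float],
    config: ExperimentConfig,
    params: LawParams,
    dist: InitialDistribution,
    bank: DurationBank,
    n_replicates: int = 10,
    rng: RngHub | int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Translate the whole initial distribution by each ``delta`` (bp).

    Returns ``(summary, daily mean-telomere tracks)``; the summary's
    ``mean_delta_hsl_h`` column is the paired-seed HSL shift against the
    ``delta = 0`` control.
    """
    deltas = list(deltas)
    if 0 not in deltas:
        deltas = [0, *deltas]

    def make_inputs(delta):
        return params, dist.with_updates(l_trans=dist.l_trans + delta)

    hsl, tracks = _paired_runs(
        {d: d for d in deltas}, make_inputs, config, params, bank, n_replicates, rng
    )
    return _summarize_paired(hsl, 0), tracks


def run_left_tail_scan(
    l0_values: Sequence[float],
    config: ExperimentConfig,
    params: LawParams,
    dist: InitialDistribution,
    bank: DurationBank,
    n_replicates: int = 10,
    rng: RngHub | int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vary only the left-flank dilation ``l_0`` (shortest telomeres)."""
    values = list(l0_values)
    if dist.l_0 not in values:
        values = [dist.l_0, *values]
    for v in values:
        if v >= dist.l_mode - dist.l_inf:
            raise ValueError(
                f"l_0={v} collapses the left flank "
                f"(must be < {dist.l_mode - dist.l_inf})"
            )

    def make_inputs(l0):
        return params, dist.with_updates(l_0=l0)

    hsl, tracks = _paired_runs(
        {v: v for v in values}, make_inputs, config, params, bank, n_replicates, rng
    )
    return _summarize_paired(hsl, dist.l_0), tracks


def run_mortality_scan(
    multipliers: Sequence[float],
    config: ExperimentConfig,
    params: LawParams,
    dist: InitialDistribution,
    bank: DurationBank,
    mode: str = "population",
    n_replicates: int = 10,
    n_lineages: int = 1000,
    rng: RngHub | int = 0,
) -> pd.DataFrame:
    """Scale ``p_accident`` by each multiplier.

    ``population`` mode reports HSL statistics per mortality level;
    ``lineage`` mode reports the median generation of senescence onset
    (among lineages that senesce) per level, as in microfluidics.
    """
    multipliers = list(multipliers)
    if 1 not in multipliers:
        multipliers = [1, *multipliers]
    for m in multipliers:
        if m * params.p_accident > 1:
            raise ValueError(f"multiplier {m} drives p_accident above 1")

    if mode == "population":

        def make_inputs(mult):
            return params.replace(p_accident=mult * params.p_accident), dist

        hsl, _ = _paired_runs(
            {m: m for m in multipliers},
            make_inputs,
            config,
            params,
            bank,
            n_replicates,
            rng,
        )
        summary = _summarize_paired(hsl, 1)
        summary = summary.rename(columns={"value": "multiplier"})
        summary["p_accident"] = summary["multiplier"] * params.p_accident
        return summary

    if mode == "lineage":
        # the same seed for every level keeps the comparison paired
        seed = replicate_sequences(rng, 1)[0]
        rows = []
        for m in multipliers:
            level = params.replace(p_accident=m * params.p_accident)
            batch = simulate_lineages(n_lineages, level, dist, bank, RngHub(seed))
            sen = batch.gen_sen
            sen = sen[sen >= 0]
            rows.append(
                {
                    "multiplier": m,
                    "p_accident": m * params.p_accident,
                    "n_lineages": n_lineages,
                    "n_senescent": int(sen.size),
                    "median_onset_generation": float(np.median(sen))
                    if sen.size
                    else np.nan,
                    "median_lifespan": float(np.median(batch.lifespan)),
                }
            )
        return pd.DataFrame(rows)

    raise ValueError(f"mode must be 'population' or 'lineage', got {mode!r}")


def rad51_lineage_experiment(
    params: LawParams,
    dist: InitialDistribution,
    bank: DurationBank,
    rng: RngHub | int = 0,
    n_experiments: int = 1000,
    lineages_per_experiment: int = 11,
) -> pd.DataFrame:
    """Virtual rad51-deletion microfluidics assay.

    Constant mortality is raised to 5.4% and many small experiments (11
    lineages each, mirroring the experimental sample size) are simulated;
    the per-experiment median lineage lifespan and its envelope across
    experiments summarize the accelerated senescence.
    """
    level = params.replace(p_accident=RAD51_P_ACCIDENT)
    hub = as_hub(rng)
    rows = []
    for i, child in enumerate(hub.spawn(n_experiments)):
        batch = simulate_lineages(lineages_per_experiment, level, dist, bank, child)
        rows.append(
            {
                "experiment": i,
                "median_lifespan": float(np.median(batch.lifespan)),
                "mean_lifespan": float(np.mean(batch.lifespan)),
            }
        )
    return pd.DataFrame(rows)
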