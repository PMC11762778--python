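"""Inference of the ten free model parameters from arrest-generation curves.

The free parameters are the two coefficients of each of the three arrest
laws (nta, sen-A, sen-B), the two hard length thresholds, and the two
dilation parameters of the initial length distribution:
``(a_nta, b_nta, a_sen_A, b_sen_A, a_sen_B, b_sen_B, l_min_A, l_min_B,
l_0, l_1)``.

A candidate parameter vector is scored by simulating batches of lineages
and comparing their arrest-generation curves (first nta; first senescent
cycle among observed-A, among observed-B, and overall) to the target
curves.  The default cost quantile-matches each sorted curve onto a
common rank grid and sums mean squared differences, plus a squared
penalty on the observed type-B proportion; it is deterministic given its
inputs and pluggable, so an alternative published cost can be dropped in.
Candidate evaluations reuse a fixed set of simulation seeds (common
random numbers), which turns the noisy objective into a deterministic one
and makes the whole fit reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .arrest import LawParams
from .cmaes import CmaResult, cma_es_minimize
from .cycles import DurationBank
from .lineage import (
    CURVE_CATEGORIES,
    arrest_generation_curves,
    observed_type_b_proportion,
    simulate_lineages,
)
from .rng import RngHub, as_hub
from .telomeres import InitialDistribution

FREE_PARAMETERS = (
    "a_nta",
    "b_nta",
    "a_sen_A",
    "b_sen_A",
    "a_sen_B",
    "b_sen_B",
    "l_min_A",
    "l_min_B",
    "l_0",
    "l_1",
)


@dataclass
class FitSpec:
    """Search space and evaluation budget of one calibration run."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # decay rates above ~0.3/bp are indistinguishable from a hard
            # threshold, so the search box stops there
            "a_nta": (0.0, 0.3),
            "b_nta": (0.0, 1.05),
            "a_sen_A": (0.0, 0.3),
            "b_sen_A": (0.0, 1.05),
            "a_sen_B": (0.0, 0.3),
            "b_sen_B": (0.0, 1.05),
            "l_min_A": (0.0, 200.0),
            "l_min_B": (0.0, 200.0),
            "l_0": (0.0, 200.0),
            "l_1": (1.0, 200.0),
        }
    )
    n_lineages: int = 200
    n_repeats: int = 2
    max_evals: int = 3000
    n_restarts: int = 3
    refine_fraction: float = 0.4    # tail of the budget at higher fidelity
    refine_scale: int = 4           # lineage multiplier during refinement
    sigma0: float = 0.4
    refine_sigma0: float = 0.05
    accept_margin: float = 1.0      # significance floor for the release stage
    popsize: Optional[int] = 12
    max_generations: int = 200
    quantile_grid: int = 21
    pb_weight: float = 200.0

    def __post_init__(self) -> None:
        if set(self.bounds) != set(FREE_PARAMETERS):
            raise ValueError(
                f"bounds must cover exactly the free parameters {FREE_PARAMETERS}"
            )
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")


@dataclass
class FitResult:
    params: LawParams
    dist: InitialDistribution
    best_values: dict[str, float]
    best_cost: float
    cost_trace: list[float]
    n_evals: int
    converged: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "best_parameters": self.best_values,
                "best_cost": self.best_cost,
                "n_evals": self.n_evals,
                "converged": self.converged,
                "cost_trace": self.cost_trace,
            },
            indent=2,
        )


def _rank_quantiles(curve: np.ndarray, k: int) -> np.ndarray:
    return np.quantile(np.asarray(curve, dtype=float), np.linspace(0, 1, k))


def cost_function(
    sim_curves: dict[str, np.ndarray],
    target_curves: dict[str, np.ndarray],
    sim_pb: Optional[float] = None,
    target_pb: Optional[float] = None,
    quantile_grid: int = 21,
    pb_weight: float = 200.0,
) -> float:
    """Quantile-matched squared distance between two curve sets.

    Empty *target* categories are skipped with a warning; an empty
    *simulated* category against a non-empty target is penalized by the
    target's own squared quantiles (the candidate produced none of an
    event class the data contains).
    """
    total = 0.0
    for cat in CURVE_CATEGORIES:
        target = np.asarray(target_curves.get(cat, ()), dtype=float)
        sim = np.asarray(sim_curves.get(cat, ()), dtype=float)
        if target.size == 0:
            warnings.warn(f"empty target category {cat!r}; skipped", stacklevel=2)
            continue
        tq = _rank_quantiles(target, quantile_grid)
        if sim.size == 0:
            total += float(np.mean(tq**2))
            continue
        sq = _rank_quantiles(sim, quantile_grid)
        total += float(np.mean((sq - tq) ** 2))
    if sim_pb is not None and target_pb is not None:
        total += pb_weight * float(sim_pb - target_pb) ** 2
    return total


def params_from_vector(
    values: dict[str, float], base: Optional[LawParams] = None
) -> tuple[LawParams, dict[str, float]]:
    """Split a free-parameter dict into LawParams updates and dilations."""
    base = base or LawParams()
    law_updates = {
        k: float(values[k])
        for k in ("a_nta", "b_nta", "a_sen_A", "b_sen_A", "a_sen_B", "b_sen_B")
    }
    law_updates["l_min_A"] = float(values["l_min_A"])
    law_updates["l_min_B"] = float(values["l_min_B"])
    return base.replace(**law_updates), {
        "l_0": float(values["l_0"]),
        "l_1": float(values["l_1"]),
    }


def fit_parameters(
    target_curves: dict[str, np.ndarray],
    spec: FitSpec,
    dist_base: InitialDistribution,
    bank: DurationBank,
    rng: RngHub | int,
    target_pb: Optional[float] = None,
    base_params: Optional[LawParams] = None,
    cost: Callable[..., float] = cost_function,
) -> FitResult:
    """CMA-ES fit of the ten free parameters to target curves."""
    hub = as_hub(rng)
    base_params = base_params or LawParams()
    names = list(FREE_PARAMETERS)
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    # the left dilation may not collapse the left flank of the base density
    left_width = dist_base.l_mode - dist_base.l_inf
    if left_width > 0:
        hi[names.index("l_0")] = min(hi[names.index("l_0")], left_width - 1.0)

    eval_seeds = [int(s) for s in
                  hub.misc.integers(0, 2**31 - 1, size=2 * spec.n_repeats)]

    def unscale(u: np.ndarray) -> dict[str, float]:
        return {n: float(lo[i] + u[i] * (hi[i] - lo[i])) for i, n in enumerate(names)}

    def make_objective(n_lineages: int, seeds: list[int]):
        def per_seed(u: np.ndarray) -> list[float]:
            values = unscale(u)
            params, dil = params_from_vector(values, base_params)
            try:
                dist = dist_base.with_updates(**dil)
            except ValueError:
                return [1e12] * len(seeds)
            costs = []
            for s in seeds:
                batch = simulate_lineages(
                    n_lineages, params, dist, bank, s, spec.max_generations
                )
                costs.append(
                    cost(
                        arrest_generation_curves(batch),
                        target_curves,
                        sim_pb=observed_type_b_proportion(batch),
                        target_pb=target_pb,
                        quantile_grid=spec.quantile_grid,
                        pb_weight=spec.pb_weight,
                    )
                )
            return costs

        def objective(u: np.ndarray) -> float:
            return float(np.mean(per_seed(u)))

        objective.per_seed = per_seed
        return objective

    # Staged fit.  The full 10-parameter landscape is rugged and carries
    # near-degeneracies (steep exponential vs hard threshold; threshold
    # vs left-dilation), so the budget is split into two phases:
    #
    # 1. a reduced 6-parameter stage fits the arrest-law coefficients
    #    with the type-B senescence channel held at its parsimonious
    #    null (length-independent: a_sen_B = 0, l_min_B = 0, rate
    #    moment-matched to the target arrest-to-senescence gap) and the
    #    dilations pinned at the configured baseline distribution — a
    #    low-dimensional problem CMA-ES solves reliably, restarted;
    # 2. all 10 parameters are then released and refined from that
    #    anchor at higher fidelity (more lineages per evaluation, fresh
    #    seeds) so the polish does not fit the exploration seeds' noise.
    bounds_box = (np.zeros(len(names)), np.ones(len(names)))
    explore_evals = int(spec.max_evals * (1 - spec.refine_fraction))
    refine_evals = spec.max_evals - explore_evals

    def scaled(values: dict[str, float]) -> np.ndarray:
        return np.array(
            [
                np.clip((values.get(n, 0.5 * (lo[i] + hi[i])) - lo[i])
                        / (hi[i] - lo[i]), 0.0, 1.0)
                for i, n in enumerate(names)
            ]
        )

    sen_b_curve = np.asarray(target_curves.get("sen_B", ()), dtype=float)
    nta_curve = np.asarray(target_curves.get("nta", ()), dtype=float)
    gap = 8.0
    if sen_b_curve.size and nta_curve.size:
        gap = max(float(np.median(sen_b_curve) - np.median(nta_curve)), 1.0)
    pinned = {
        "a_sen_B": 0.0,
        "l_min_B": 0.0,
        "l_0": float(dist_base.l_0),
        "l_1": float(dist_base.l_1),
    }
    null_anchor = scaled({**pinned, "b_sen_B": float(np.clip(1.0 / gap, 0.02, 1.0))})
    stage1_free = np.array(
        [names.index(n) for n in
         ("a_nta", "b_nta", "a_sen_A", "b_sen_A", "l_min_A", "b_sen_B")]
    )

    explore = make_objective(spec.n_lineages, eval_seeds[: spec.n_repeats])

    def reduced(u6: np.ndarray) -> float:
        full = null_anchor.copy()
        full[stage1_free] = u6
        return explore(full)

    n_restarts = max(1, spec.n_restarts)
    per_restart = max(explore_evals // n_restarts, 1)
    best6 = None
    best6_f = np.inf
    trace: list[float] = []
    n_evals = 0
    for r in range(n_restarts):
        if r == 0:
            x0 = null_anchor[stage1_free]
        else:
            x0 = hub.misc.uniform(0.15, 0.85, size=stage1_free.size)
        cand = cma_es_minimize(
            reduced, x0, spec.sigma0, hub.misc,
            bounds=(np.zeros(6), np.ones(6)),
            max_evals=per_restart, popsize=spec.popsize,
        )
        n_evals += cand.n_evals
        trace.extend(min(v, best6_f) for v in cand.trace)
        if cand.f_best < best6_f:
            best6, best6_f = cand.x_best, cand.f_best

    anchor = null_anchor.copy()
    anchor[stage1_free] = best6
    res = CmaResult(anchor, best6_f, n_evals, trace, False)

    if refine_evals > 0:
        refine = make_objective(
            spec.refine_scale * spec.n_lineages, eval_seeds[spec.n_repeats :]
        )

        # polish the reduced fit at high fidelity first: with the
        # dilations still pinned there is no threshold/dilation ridge,
        # so this is where the type-A threshold is actually pinned down
        def reduced_hi(u6: np.ndarray) -> float:
            full = null_anchor.copy()
            full[stage1_free] = u6
            return refine(full)

        polish6_evals = refine_evals // 2
        release_evals = refine_evals - polish6_evals
        polished6 = cma_es_minimize(
            reduced_hi, anchor[stage1_free], 0.06, hub.misc,
            bounds=(np.zeros(6), np.ones(6)),
            max_evals=polish6_evals, popsize=spec.popsize,
        )
        n_evals += polished6.n_evals
        trace.extend(polished6.trace)
        anchor = null_anchor.copy()
        anchor[stage1_free] = polished6.x_best

        anchor_costs = refine.per_seed(anchor)
        f_anchor = float(np.mean(anchor_costs))
        n_evals += 1
        polished = cma_es_minimize(
            refine, anchor, spec.refine_sigma0, hub.misc, bounds=bounds_box,
            max_evals=release_evals, popsize=spec.popsize,
        )
        n_evals += polished.n_evals
        trace.extend(min(v, f_anchor) for v in polished.trace)
        # accept the released 10-parameter solution only if it beats the
        # anchored one by more than the seed-to-seed noise of the cost:
        # near-degenerate directions (threshold vs left dilation) are
        # otherwise walked by noise-fitting alone
        noise = float(np.std(anchor_costs)) / max(np.sqrt(len(anchor_costs)), 1.0)
        margin = 2.0 * noise + spec.accept_margin
        if polished.f_best < f_anchor - margin:
            res = CmaResult(polished.x_best, polished.f_best, n_evals, trace,
                            polished.converged)
        else:
            res = CmaResult(anchor, f_anchor, n_evals, trace, False)

    best_values = unscale(res.x_best)
    # thresholds are biologically integer bp
    best_values["l_min_A"] = float(round(best_values["l_min_A"]))
    best_values["l_min_B"] = float(round(best_values["l_min_B"]))
    params, dil = params_from_vector(best_values, base_params)
    return FitResult(
        params=params,
        dist=dist_base.with_updates(**dil),
        best_values=best_values,
        best_cost=res.f_best,
        cost_trace=res.trace,
        n_evals=res.n_evals,
        converged=res.converged,
    )
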