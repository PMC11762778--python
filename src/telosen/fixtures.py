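"""Deterministic synthetic datasets standing in for unpublished inputs.

Three kinds of fixture can be generated, each seed-stamped and written
with a JSON manifest recording the exact generating parameters so tests
can close the loop (re-derive a quantity from the files and compare it to
the manifest):

* ``initial_lengths`` — a plain-text sample (one integer bp per line)
  standing in for the telomerase-positive equilibrium length
  distribution;
* ``duration_bank`` — a CSV cell-cycle-duration bank in the four
  (cell type, cycle type) categories;
* ``lineage_targets`` — arrest-generation curves simulated under stated
  "true" parameters, the ground truth for calibration-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .arrest import LawParams
from .cycles import SyntheticBankSpec, synthetic_bank
from .lineage import (
    arrest_generation_curves,
    observed_type_b_proportion,
    simulate_lineages,
)
from .rng import RngHub
from .telomeres import InitialDistribution

KINDS = ("initial_lengths", "duration_bank", "lineage_targets")


class FixtureError(ValueError):
    """Unknown fixture kind or mismatched spec."""


def _write_manifest(out_dir: Path, manifest: dict) -> Path:
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def generate_fixture_dataset(
    kind: str,
    out_dir: Union[str, Path],
    seed: int,
    spec: Optional[dict] = None,
) -> dict:
    """Write one fixture dataset; returns its manifest (also saved).

    ``spec`` overrides the defaults of the corresponding module
    (distribution parameters, bank spec fields, or true law parameters
    plus ``n_lineages`` for targets).
    """
    if kind not in KINDS:
        raise FixtureError(f"unknown fixture kind {kind!r}; expected one of {KINDS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = dict(spec or {})
    hub = RngHub(seed)

    if kind == "initial_lengths":
        n = int(spec.pop("n_samples", 5000))
        dist = InitialDistribution(**spec)
        lengths = dist.sample_lengths(n, hub.init)
        path = out_dir / "initial_lengths.txt"
        np.savetxt(path, lengths, fmt="%d")
        manifest = {
            "kind": kind,
            "seed": seed,
            "n_samples": n,
            "distribution": {
                k: getattr(dist, k)
                for k in ("l_inf", "l_mode", "l_sup", "l_trans", "l_0", "l_1")
            },
            "files": [path.name],
        }

    elif kind == "duration_bank":
        bank_spec = SyntheticBankSpec(**spec)
        bank = synthetic_bank(hub.misc, bank_spec)
        path = out_dir / "duration_bank.csv"
        bank.to_frame().to_csv(path, index=False)
        manifest = {
            "kind": kind,
            "seed": seed,
            "bank_spec": bank_spec.to_dict(),
            "files": [path.name],
        }

    elif kind == "lineage_targets":
        n = int(spec.pop("n_lineages", 2000))
        law_fields = set(LawParams().to_dict())
        law_spec = {k: spec.pop(k) for k in list(spec) if k in law_fields}
        params = LawParams(**law_spec)
        dist = InitialDistribution(**spec)
        bank = synthetic_bank(hub.misc)
        batch = simulate_lineages(n, params, dist, bank, hub)
        curves = arrest_generation_curves(batch)
        rows = [
            (cat, int(g)) for cat in curves for g in curves[cat]
        ]
        path = out_dir / "target_curves.csv"
        pd.DataFrame(rows, columns=["category", "generation"]).to_csv(
            path, index=False
        )
        manifest = {
            "kind": kind,
            "seed": seed,
            "n_lineages": n,
            "true_params": params.to_dict(),
            "distribution": {
                k: getattr(dist, k)
                for k in ("l_inf", "l_mode", "l_sup", "l_trans", "l_0", "l_1")
            },
            "observed_type_b_proportion": observed_type_b_proportion(batch),
            "files": [path.name],
        }

    _write_manifest(out_dir, manifest)
    return manifest


def load_target_curves(path: Union[str, Path]) -> dict[str, np.ndarray]:
    """Read a ``lineage_targets`` curves CSV back into curve arrays."""
    df = pd.read_csv(path)
    return {
        cat: np.sort(grp["generation"].to_numpy())
        for cat, grp in df.groupby("category")
    }
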