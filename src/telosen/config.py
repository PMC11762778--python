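"""YAML configuration: one file resolves every model and protocol input.

The file has four optional sections; every key inside uses the model's
standard symbol names, and an empty (or absent) file resolves to the
wild-type best-fit defaults:

.. code-block:: yaml

    laws:                  # arrest/shortening constants
      a_nta: 0.02
      p_accident: 0.0043
    initial_distribution:  # base support, dilations, translation
      l_inf: 100
      l_mode: 300
      l_sup: 500
      l_trans: 0
      l_0: 40
      l_1: 58
      sample_file: null    # plain-text lengths overriding the base density
    durations:             # bank CSV path or synthetic-bank parameters
      bank_file: null
      median_nor_A: 88.0
    experiment:            # serial-dilution protocol
      n_init: 300
      r_sat: 1000
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Union

import yaml

from .arrest import LawParams
from .cycles import DurationBank, SyntheticBankSpec, get_bank
from .population import ExperimentConfig
from .rng import RngHub
from .telomeres import InitialDistribution, load_length_sample


class ConfigFileError(ValueError):
    """Malformed configuration file."""

SECTIONS = ("laws", "initial_distribution", "durations", "experiment")


@dataclass
class RunConfig:
    """Fully resolved parameter bundle for any simulation entry point."""

    laws: LawParams = field(default_factory=LawParams)
    dist: InitialDistribution = field(default_factory=InitialDistribution)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    bank_file: Optional[str] = None
    bank_spec: SyntheticBankSpec = field(default_factory=SyntheticBankSpec)

    def resolve_bank(self, rng: RngHub) -> DurationBank:
        source = self.bank_file if self.bank_file else self.bank_spec
        return get_bank(source, rng=rng.misc, D=self.laws.D)

    def to_dict(self) -> dict:
        dist_keys = ("l_inf", "l_mode", "l_sup", "l_trans", "l_0", "l_1")
        return {
            "laws": self.laws.to_dict(),
            "initial_distribution": {k: getattr(self.dist, k) for k in dist_keys},
            "durations": {"bank_file": self.bank_file, **self.bank_spec.to_dict()},
            "experiment": {
                f.name: getattr(self.experiment, f.name)
                for f in dc_fields(ExperimentConfig)
            },
        }


def _pick(section: dict, cls, section_name: str, extra_keys=()) -> dict:
    valid = {f.name for f in dc_fields(cls)}
    unknown = set(section) - valid - set(extra_keys)
    if unknown:
        raise ConfigFileError(
            f"unknown key(s) {sorted(unknown)} in section {section_name!r}; "
            f"valid keys: {sorted(valid | set(extra_keys))}"
        )
    return {k: v for k, v in section.items() if k in valid}


def load_config(path: Union[str, Path, None] = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` gives all defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigFileError(f"top level of {path} must be a mapping")
        raw = loaded
    unknown = set(raw) - set(SECTIONS)
    if unknown:
        raise ConfigFileError(
            f"unknown section(s) {sorted(unknown)}; valid sections: {SECTIONS}"
        )

    try:
        laws = LawParams(**_pick(raw.get("laws", {}) or {}, LawParams, "laws"))

        dist_section = dict(raw.get("initial_distribution", {}) or {})
        sample_file = dist_section.pop("sample_file", None)
        dist_kwargs = _pick(dist_section, InitialDistribution, "initial_distribution")
        dist_kwargs.pop("base_sample", None)
        if sample_file:
            sample = load_length_sample(sample_file)
            dist_kwargs = {
                k: v
                for k, v in dist_kwargs.items()
                if k in ("l_trans", "l_0", "l_1")
            }
            dist = InitialDistribution(base_sample=sample, **dist_kwargs)
        else:
            dist = InitialDistribution(**dist_kwargs)

        dur_section = dict(raw.get("durations", {}) or {})
        bank_file = dur_section.pop("bank_file", None)
        bank_spec = SyntheticBankSpec(
            **_pick(dur_section, SyntheticBankSpec, "durations")
        )

        experiment = ExperimentConfig(
            **_pick(raw.get("experiment", {}) or {}, ExperimentConfig, "experiment")
        )
    except ConfigFileError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigFileError(f"invalid configuration: {exc}") from exc

    return RunConfig(
        laws=laws,
        dist=dist,
        experiment=experiment,
        bank_file=bank_file,
        bank_spec=bank_spec,
    )


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Write the fully resolved configuration back to YAML."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
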