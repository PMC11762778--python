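"""Seeding discipline shared by every simulator in the package.

A single integer seed fans out into named, statistically independent
sub-streams (one per source of randomness in the model).  Adding a new
observable, or reading an extra statistic, never consumes draws from an
existing stream, so any reported number can be replayed exactly from
(seed, code version) alone.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from numpy.random import Generator, PCG64, SeedSequence

#: the named streams, in spawn order (order is part of the replay contract)
STREAM_NAMES: tuple[str, ...] = (
    "init",        # initial telomere-length draws
    "telomeres",   # per-division Bernoulli coupling + daughter choice
    "fates",       # arrest / repair / death draws
    "durations",   # cell-cycle duration resampling
    "dilution",    # daily without-replacement sampling
    "misc",        # anything else (bank synthesis, optimizer, ...)
)

SeedLike = Union[int, SeedSequence, "RngHub"]


class RngHub:
    """A bundle of named, independent `numpy.random.Generator` streams."""

    def __init__(self, seed: SeedLike = 0):
        if isinstance(seed, RngHub):
            seed = seed.seed_sequence
        if isinstance(seed, SeedSequence):
            self.seed_sequence = seed
        else:
            self.seed_sequence = SeedSequence(int(seed))
        children = self.seed_sequence.spawn(len(STREAM_NAMES))
        self._streams: dict[str, Generator] = {
            name: Generator(PCG64(child))
            for name, child in zip(STREAM_NAMES, children)
        }

    def __getattr__(self, name: str) -> Generator:
        try:
            return self.__dict__["_streams"][name]
        except KeyError:
            raise AttributeError(f"no RNG stream named {name!r}") from None

    def stream(self, name: str) -> Generator:
        return self._streams[name]

    def spawn(self, n: int) -> list["RngHub"]:
        """Derive ``n`` child hubs (e.g. one per replicate), reproducibly."""
        return [RngHub(child) for child in self.seed_sequence.spawn(n)]

    def __repr__(self) -> str:  # pragma: no cover
        return f"RngHub(entropy={self.seed_sequence.entropy})"


def as_hub(seed: SeedLike) -> RngHub:
    """Coerce an int / SeedSequence / RngHub into an RngHub."""
    return seed if isinstance(seed, RngHub) else RngHub(seed)


def spawn_hubs(seed: SeedLike, n: int) -> list[RngHub]:
    return as_hub(seed).spawn(n)


def replicate_sequences(seed: SeedLike, n: int) -> list[SeedSequence]:
    """``n`` child seed-sequences, for paired-seed experimental designs.

    Constructing a fresh :class:`RngHub` from the *same* child sequence
    yields bit-identical streams, which is how scans pair conditions.
    """
    return list(as_hub(seed).seed_sequence.spawn(n))
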