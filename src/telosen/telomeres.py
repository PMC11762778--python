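"""Telomere length state and the coupled asymmetric shortening rule.

A haploid *S. cerevisiae* cell carries 16 chromosomes, hence 32 telomeres,
stored as a 2x16 integer matrix of lengths in bp (row = chromosome end,
column = chromosome).  At each division, for every chromosome exactly one
of its two telomeres is shortened by the replication overhang ``h`` (7 bp
by default) with equiprobability; the end shortened in one daughter is the
end left intact in the other, so the two daughters are complementary.
Chromosomes are mutually independent.

The initial (generation-0) lengths are i.i.d. draws from a transformed
base distribution: the telomerase-positive equilibrium distribution, which
is not available in closed form, is stood in for by a triangular density
over a configurable support (or by a user-supplied sample file), then
reshaped by a mode-preserving two-sided dilation (``l_0`` on the left
flank, ``l_1`` on the right) and a global translation ``l_trans``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from numpy.random import Generator

N_CHROMOSOMES = 16
N_TELOMERES = 2 * N_CHROMOSOMES
MATRIX_SHAPE = (2, N_CHROMOSOMES)


class TelomereError(ValueError):
    """Invalid telomere matrix or distribution parameters."""


def validate_matrix(lengths: np.ndarray) -> np.ndarray:
    """Check a 2x16 nonnegative integer telomere matrix; return it as int64."""
    arr = np.asarray(lengths)
    if arr.shape != MATRIX_SHAPE:
        raise TelomereError(
            f"telomere matrix must have shape {MATRIX_SHAPE}, got {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise TelomereError("telomere lengths must be integers (bp)")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise TelomereError("telomere lengths must be >= 0")
    return arr.astype(np.int64)


def divide_with_coupling(
    parent: np.ndarray, h: int, coupling: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic division given the per-chromosome coupling bits.

    ``coupling[j] == 1`` means end 1 of chromosome ``j`` is shortened in
    daughter 1 (and end 2 in daughter 2); ``0`` is the mirror case.
    Lengths clamp at zero: a telomere cannot carry negative repeats.
    """
    parent = np.asarray(parent, dtype=np.int64)
    b = np.asarray(coupling, dtype=np.int64)
    d1 = parent.copy()
    d2 = parent.copy()
    d1[0] -= h * b
    d1[1] -= h * (1 - b)
    d2[0] -= h * (1 - b)
    d2[1] -= h * b
    np.clip(d1, 0, None, out=d1)
    np.clip(d2, 0, None, out=d2)
    return d1, d2


def divide_telomeres(
    parent: np.ndarray, h: int, rng: Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One cell division: returns the two complementary daughter matrices."""
    parent = validate_matrix(parent)
    if h < 0:
        raise TelomereError(f"overhang h must be >= 0, got {h}")
    coupling = rng.integers(0, 2, size=N_CHROMOSOMES)
    return divide_with_coupling(parent, h, coupling)


def divide_batch(
    parents: np.ndarray, h: int, coupling: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized division of ``n`` parents, coupling shape (n, 16)."""
    b = np.asarray(coupling, dtype=parents.dtype)
    d1 = parents.copy()
    d2 = parents.copy()
    d1[:, 0, :] -= h * b
    d1[:, 1, :] -= h * (1 - b)
    d2[:, 0, :] -= h * (1 - b)
    d2[:, 1, :] -= h * b
    np.clip(d1, 0, None, out=d1)
    np.clip(d2, 0, None, out=d2)
    return d1, d2


# ---------------------------------------------------------------------------
# Initial length distribution
# ---------------------------------------------------------------------------


@dataclass
class InitialDistribution:
    """Transformed initial telomere-length distribution (bp).

    The base density is triangular on ``[l_inf, l_sup]`` with mode
    ``l_mode`` unless ``base_sample`` provides empirical lengths to
    resample instead.  The transform dilates ``[l_inf, l_mode]`` to
    ``[l_inf + l_0, l_mode]`` and ``[l_mode, l_sup]`` to
    ``[l_mode, l_mode + l_1]`` (the mode is a fixed point), then adds the
    signed translation ``l_trans``, rounds half-up to integer bp and
    clamps at zero.
    """

    l_inf: float = 100.0
    l_mode: float = 300.0
    l_sup: float = 500.0
    l_trans: float = 0.0
    l_0: float = 40.0
    l_1: float = 58.0
    base_sample: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.base_sample is not None:
            sample = np.asarray(self.base_sample, dtype=float).ravel()
            if sample.size == 0:
                raise TelomereError("base_sample must be non-empty")
            if (sample < 0).any():
                raise TelomereError("base_sample lengths must be >= 0")
            self.base_sample = sample
            self.l_inf = float(sample.min())
            self.l_sup = float(sample.max())
            # empirical mode of the rounded sample; ties -> smallest length
            counts = np.bincount(np.floor(sample + 0.5).astype(int))
            self.l_mode = float(np.argmax(counts))
            self.l_mode = min(max(self.l_mode, self.l_inf), self.l_sup)
        if not (self.l_inf <= self.l_mode <= self.l_sup):
            raise TelomereError(
                f"need l_inf <= l_mode <= l_sup, got "
                f"({self.l_inf}, {self.l_mode}, {self.l_sup})"
            )
        if self.l_mode > self.l_inf and self.l_0 >= self.l_mode - self.l_inf:
            raise TelomereError(
                f"l_0={self.l_0} collapses the left flank "
                f"(requires l_0 < l_mode - l_inf = {self.l_mode - self.l_inf})"
            )
        if self.l_sup > self.l_mode and self.l_1 <= 0:
            raise TelomereError(
                f"l_1={self.l_1} collapses the right flank (requires l_1 > 0)"
            )

    # -- transform ----------------------------------------------------------

    def transform(self, x):
        """Apply the mode-preserving dilation + translation to length(s) x."""
        scalar = np.isscalar(x) or np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if (x < self.l_inf - 1e-9).any() or (x > self.l_sup + 1e-9).any():
            raise TelomereError(
                f"x outside the base support [{self.l_inf}, {self.l_sup}]"
            )
        left_w = self.l_mode - self.l_inf
        right_w = self.l_sup - self.l_mode
        y = np.empty_like(x)
        lo = x <= self.l_mode
        if left_w > 0:
            y[lo] = (
                self.l_inf
                + self.l_0
                + (x[lo] - self.l_inf) * (left_w - self.l_0) / left_w
            )
        else:
            y[lo] = self.l_mode
        hi = ~lo
        if right_w > 0:
            y[hi] = self.l_mode + (x[hi] - self.l_mode) * self.l_1 / right_w
        else:
            y[hi] = self.l_mode
        y += self.l_trans
        out = np.floor(y + 0.5).astype(np.int64)  # round half-up
        np.clip(out, 0, None, out=out)
        return int(out[0]) if scalar else out

    @property
    def support(self) -> tuple[int, int]:
        """Transformed support (min, max) in integer bp (before clamping)."""
        lo = self.l_inf + self.l_0 + self.l_trans
        hi = self.l_mode + (self.l_1 if self.l_sup > self.l_mode else 0.0)
        hi += self.l_trans
        return (max(int(np.floor(lo + 0.5)), 0), max(int(np.floor(hi + 0.5)), 0))

    # -- sampling -----------------------------------------------------------

    def _sample_base(self, n: int, rng: Generator) -> np.ndarray:
        if self.base_sample is not None:
            idx = rng.integers(0, self.base_sample.size, size=n)
            return self.base_sample[idx]
        width = self.l_sup - self.l_inf
        if width <= 0:
            return np.full(n, float(self.l_mode))
        # inverse-CDF draw from the triangular density
        c = (self.l_mode - self.l_inf) / width
        u = rng.random(n)
        x = np.empty(n)
        lo = u < c
        if c > 0:
            x[lo] = self.l_inf + np.sqrt(u[lo] * c) * width
        x[~lo] = self.l_sup - np.sqrt(np.maximum((1 - u[~lo]) * (1 - c), 0)) * width
        return x

    def sample_lengths(self, n: int, rng: Generator) -> np.ndarray:
        """``n`` i.i.d. integer lengths from the transformed distribution."""
        return self.transform(self._sample_base(n, rng))

    def sample_matrix(self, rng: Generator) -> np.ndarray:
        """One cell's 2x16 matrix of i.i.d. initial lengths."""
        return self.sample_lengths(N_TELOMERES, rng).reshape(MATRIX_SHAPE)

    def sample_matrices(self, n_cells: int, rng: Generator) -> np.ndarray:
        """(n_cells, 2, 16) initial matrices, all entries i.i.d."""
        flat = self.sample_lengths(n_cells * N_TELOMERES, rng)
        return flat.reshape(n_cells, *MATRIX_SHAPE)

    def with_updates(self, **kwargs) -> "InitialDistribution":
        """A copy with some parameters replaced (used by the scans)."""
        params = dict(l_trans=self.l_trans, l_0=self.l_0, l_1=self.l_1)
        if self.base_sample is None:
            params.update(l_inf=self.l_inf, l_mode=self.l_mode, l_sup=self.l_sup)
        params.update(kwargs)
        return InitialDistribution(base_sample=self.base_sample, **params)


def sample_initial_matrix(dist: InitialDistribution, rng: Generator) -> np.ndarray:
    """Functional alias for :meth:`InitialDistribution.sample_matrix`."""
    return dist.sample_matrix(rng)


def transform_distribution(x, dist: InitialDistribution):
    """Functional alias for :meth:`InitialDistribution.transform`."""
    return dist.transform(x)


def load_length_sample(path: Union[str, Path]) -> np.ndarray:
    """Read a plain-text initial-length sample: one integer bp per line."""
    lengths = np.loadtxt(path, dtype=float, ndmin=1)
    if lengths.size == 0:
        raise TelomereError(f"no lengths found in {path}")
    return lengths
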