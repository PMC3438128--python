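"""Empirical background distributions by real randomization.

For an experimental set of n promoters, the background for a target is
built by repeatedly drawing random sets of the same size n from the
genomic promoter pool and recomputing the four statistics on each draw.
Draws are without replacement within one repetition (a random set of
promoters is a subset) and independent across repetitions. One RNG
stream, seeded from the configuration, is consumed in repetition order
(set 1 ... set n_reps), so identical inputs give bit-identical samples.

All targets share the same sequence of random sets, which makes their
background distributions directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iupac_motifs import IUPACPattern
from .promoter_io import PromoterSet
from .scanner import Target, count_occurrences, resolve_targets

__all__ = [
    "RandomizationConfig",
    "BackgroundDistribution",
    "draw_random_set",
    "sample_index_matrix",
    "background_sample",
    "background_from_counts",
]

PARAM_COLUMNS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class RandomizationConfig:
    """Randomization settings.

    n_reps:
        Number of random reference sets. 1000 is generally sufficient for
        genome-scale pools; with small pools (fewer than ~10x the
        experimental set size) 3000-5000 repetitions are recommended.
    seed:
        Seed for the single RNG stream.
    exclude_experimental:
        Drop the experimental promoters from the sampling frame. Off by
        default: the background is drawn from the full genomic pool.
    """

    n_reps: int = 1000
    seed: int | None = None
    exclude_experimental: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 100:
            raise ValueError("n_reps must be at least 100")
        if self.n_reps < 1000:
            warnings.warn(
                f"n_reps={self.n_reps} is below the recommended 1000",
                stacklevel=3,
            )

    def check_pool_ratio(self, pool_size: int, set_size: int) -> None:
        if pool_size < 10 * set_size and self.n_reps < 3000:
            warnings.warn(
                f"pool size {pool_size} is less than 10x the experimental "
                f"set size {set_size}; consider raising n_reps to 3000-5000",
                stacklevel=3,
            )


@dataclass
class BackgroundDistribution:
    """Background samples of the four statistics for one target."""

    target: str
    samples: pd.DataFrame  # n_reps rows, columns I, II, III, IV
    draw_tally: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def n_reps(self) -> int:
        return len(self.samples)


def sample_index_matrix(
    rng: np.random.Generator, pool_size: int, n: int, n_sets: int
) -> np.ndarray:
    """Draw ``n_sets`` uniform without-replacement samples of ``n`` indices
    from ``range(pool_size)``, as an (n_sets, n) matrix.

    Uses Floyd's sampling algorithm vectorised across sets: iteration i
    considers index j = pool_size - n + i and draws one candidate per set,
    so the RNG stream is consumed in a fixed, documented order. Row order
    of the returned indices is not itself uniformly shuffled; all derived
    statistics are order-invariant.
    """
    if n > pool_size:
        raise ValueError(f"cannot draw {n} promoters from a pool of {pool_size}")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    occupied = np.zeros((n_sets, pool_size), dtype=bool)
    out = np.empty((n_sets, n), dtype=np.int64)
    rows = np.arange(n_sets)
    for i, j in enumerate(range(pool_size - n, pool_size)):
        t = rng.integers(0, j + 1, size=n_sets)
        t = np.where(occupied[rows, t], j, t)
        occupied[rows, t] = True
        out[:, i] = t
    return out


def draw_random_set(
    pool: PromoterSet, n: int, rng: np.random.Generator
) -> list[str]:
    """One random reference set: n distinct gene IDs drawn uniformly
    without replacement from the pool, in shuffled order."""
    idx = sample_index_matrix(rng, len(pool), n, 1)[0]
    rng.shuffle(idx)
    ids = pool.gene_ids
    return [ids[i] for i in idx]


def _parameter_samples(counts: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Statistics I-IV for each sampled set; counts is the per-promoter
    occurrence vector, idx an (n_sets, n) index matrix."""
    sub = counts[idx]
    n = idx.shape[1]
    out = np.empty((idx.shape[0], 4))
    out[:, 0] = (sub > 0).sum(axis=1)
    out[:, 1] = sub.mean(axis=1)
    out[:, 2] = sub.sum(axis=1)
    out[:, 3] = sub.var(axis=1, ddof=1) if n > 1 else 0.0
    return out


def background_from_counts(
    count_matrix: pd.DataFrame,
    n: int,
    config: RandomizationConfig,
    rng: np.random.Generator | None = None,
    frame: np.ndarray | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, int], np.ndarray]:
    """Background samples for every target column of a precomputed
    per-promoter count matrix.

    Returns (per-target sample frames, draw tally, raw index matrix).
    ``frame`` optionally restricts the sampling frame to a subset of row
    positions (used by ``exclude_experimental``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool_ids = np.asarray(count_matrix.index)
    positions = np.arange(len(pool_ids)) if frame is None else np.asarray(frame)
    config.check_pool_ratio(len(positions), n)
    idx = positions[sample_index_matrix(rng, len(positions), n, config.n_reps)]
    tally_arr = np.bincount(idx.ravel(), minlength=len(pool_ids))
    tally = {
        gid: int(c) for gid, c in zip(pool_ids, tally_arr) if c > 0
    }
    samples = {
        name: pd.DataFrame(
            _parameter_samples(count_matrix[name].to_numpy(), idx),
            columns=list(PARAM_COLUMNS),
        )
        for name in count_matrix.columns
    }
    return samples, tally, idx


def background_sample(
    pool: PromoterSet,
    n: int,
    targets: Sequence[Target | str],
    config: RandomizationConfig,
    registry: Mapping[str, IUPACPattern] | None = None,
    strand_policy: str = "auto_antisense",
    return_indices: bool = False,
):
    """Background distributions for all targets over shared random sets.

    The pool is scanned once for all targets, then ``config.n_reps``
    random sets of size ``n`` are drawn and the four statistics computed
    per set. With ``return_indices`` the raw (n_reps, n) index matrix is
    appended to the result (the "randomization indices").
    """
    targets = resolve_targets(targets, registry)
    counts = count_occurrences(pool, targets, registry, strand_policy)
    samples, tally, idx = background_from_counts(counts, n, config)
    backgrounds = [
        BackgroundDistribution(name, samples[name], tally) for name in counts.columns
    ]
    if return_indices:
        return backgrounds, idx
    return backgrounds
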