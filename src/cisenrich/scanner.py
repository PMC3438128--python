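"""Motif and module scanning, and the four per-dataset statistics.

Single motifs are fixed-length IUPAC words matched by sliding-window
enumeration. Under the ``auto_antisense`` strand policy a motif is
searched as both its Watson and its Crick word on the stored strand; a
Watson/Crick pair occupying the same span (dyad-symmetric words such as
BACGTV) is reported once.

A module is an ordered list of 2-3 member motifs forming one composite
cis-regulatory unit: member hits must appear in 5'→3' start order on the
Watson coordinates, must not overlap, and consecutive members are
separated by a flexible gap of at most ``max_gap`` bp (default 100).
Module orientation matters: GRE-AUX2 and AUX2-GRE are distinct targets.
Each member hit may individually lie on either strand.

The per-dataset statistics ("parameters") are:

I.   number of promoters containing at least one occurrence;
II.  mean occurrences per promoter (motif density);
III. total occurrences;
IV.  sample variance of per-promoter occurrence counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .iupac_motifs import IUPACPattern, compile_word, reverse_complement
from .promoter_io import PromoterSet

__all__ = [
    "MatchHit",
    "ModuleSpec",
    "ModuleInstance",
    "ParameterVector",
    "Target",
    "scan_motif",
    "scan_module",
    "count_occurrences",
    "dataset_parameters",
    "parameters_from_counts",
    "resolve_targets",
]

STRAND_POLICIES = ("watson_only", "auto_antisense")


@dataclass(frozen=True)
class MatchHit:
    """One motif occurrence: 0-based half-open span on the stored strand."""

    gene_id: str
    motif_name: str
    start: int
    end: int
    strand: str  # "watson" or "crick"


@dataclass(frozen=True)
class ModuleSpec:
    """An ordered, orientation-specific multi-motif module."""

    name: str
    members: tuple[str, ...]
    max_gap: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not 2 <= len(self.members) <= 3:
            raise ValueError(
                f"module {self.name!r}: needs 2-3 members, got {len(self.members)}"
            )
        if self.max_gap < 0:
            raise ValueError(f"module {self.name!r}: max_gap must be >= 0")

    @classmethod
    def from_members(cls, members: Sequence[str], max_gap: int = 100) -> "ModuleSpec":
        return cls("-".join(members), tuple(members), max_gap)


Target = Union[IUPACPattern, ModuleSpec]


@dataclass(frozen=True)
class ModuleInstance:
    """One qualifying tuple of member hits (one hit per member, in order)."""

    gene_id: str
    module_name: str
    hits: tuple[MatchHit, ...]


@dataclass(frozen=True)
class ParameterVector:
    """The four per-dataset statistics for one target."""

    p1_promoters_with: int
    p2_mean_per_promoter: float
    p3_total: int
    p4_variance: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.p1_promoters_with,
                self.p2_mean_per_promoter,
                self.p3_total,
                self.p4_variance,
            ]
        )


PARAMETER_IDS = ("I", "II", "III", "IV")
PARAMETER_LABELS = {
    "I": "promoters with motif",
    "II": "mean occurrences per promoter",
    "III": "total occurrences",
    "IV": "variance of per-promoter occurrences",
}


def _check_policy(strand_policy: str) -> None:
    if strand_policy not in STRAND_POLICIES:
        raise ValueError(
            f"unknown strand policy {strand_policy!r}; expected one of {STRAND_POLICIES}"
        )


def _start_positions(
    sequence: str, pattern: IUPACPattern, strand_policy: str
) -> tuple[list[int], set[int]]:
    """Sorted deduplicated start positions plus the subset of starts that
    match the Watson word (for strand attribution)."""
    watson = {m.start() for m in compile_word(pattern.word).finditer(sequence)}
    starts = set(watson)
    if strand_policy == "auto_antisense":
        crick_word = reverse_complement(pattern).word
        if crick_word != pattern.word:
            starts |= {
                m.start() for m in compile_word(crick_word).finditer(sequence)
            }
    return sorted(starts), watson


def scan_motif(
    sequence: str,
    pattern: IUPACPattern,
    strand_policy: str = "auto_antisense",
    gene_id: str = "",
) -> list[MatchHit]:
    """All occurrences of *pattern* in *sequence*, sorted by start.

    Overlapping self-matches are enumerated individually (plain sliding
    window); a Watson/Crick pair on the same span is reported once, as a
    Watson hit. A pattern longer than the sequence yields an empty list.
    """
    _check_policy(strand_policy)
    k = len(pattern)
    starts, watson = _start_positions(sequence, pattern, strand_policy)
    return [
        MatchHit(
            gene_id,
            pattern.name,
            s,
            s + k,
            "watson" if s in watson else "crick",
        )
        for s in starts
    ]


def _resolve_members(
    spec: ModuleSpec, registry: Mapping[str, IUPACPattern]
) -> list[IUPACPattern]:
    try:
        return [registry[name] for name in spec.members]
    except KeyError as exc:
        raise KeyError(
            f"module {spec.name!r}: unknown member motif {exc.args[0]!r}"
        ) from None


def scan_module(
    sequence: str,
    spec: ModuleSpec,
    registry: Mapping[str, IUPACPattern],
    strand_policy: str = "auto_antisense",
    gene_id: str = "",
) -> list[ModuleInstance]:
    """All qualifying member-hit tuples of *spec* in *sequence*.

    Every combination of one hit per member satisfying the chained
    ordering, non-overlap and gap constraints is returned; hits are not
    "used up" by one instance (no greedy pairing).
    """
    _check_policy(strand_policy)
    member_hits = [
        scan_motif(sequence, pat, strand_policy, gene_id)
        for pat in _resolve_members(spec, registry)
    ]
    instances: list[ModuleInstance] = []

    def extend(k: int, chain: list[MatchHit]) -> None:
        if k == len(member_hits):
            instances.append(ModuleInstance(gene_id, spec.name, tuple(chain)))
            return
        prev_end = chain[-1].end if chain else None
        for hit in member_hits[k]:
            if prev_end is None or (
                hit.start >= prev_end and hit.start - prev_end <= spec.max_gap
            ):
                chain.append(hit)
                extend(k + 1, chain)
                chain.pop()

    extend(0, [])
    return instances


# ---------------------------------------------------------------------------
# Pool-level counting
#
# Scanning a genomic pool promoter-by-promoter pays the regex set-up cost
# tens of thousands of times. Instead, promoters are joined into one string
# with an "X" separator wide enough that no word can straddle a boundary
# ("X" belongs to no IUPAC class, so the separator itself can never match),
# and each motif is located in a single pass.

def _pool_motif_starts(
    big: str,
    offsets: np.ndarray,
    pattern: IUPACPattern,
    strand_policy: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(promoter index, local start) arrays for all hits in the joined pool."""
    starts, _ = _start_positions(big, pattern, strand_policy)
    g = np.asarray(starts, dtype=np.int64)
    idx = np.searchsorted(offsets, g, side="right") - 1
    return idx, g - offsets[idx]


def _count_chains(member_starts: list[np.ndarray], lengths: list[int], max_gap: int) -> int:
    """Number of qualifying hit tuples, by suffix dynamic programming:
    ways[i] of member k = number of chain completions from hit i."""
    ways = np.ones(len(member_starts[-1]), dtype=np.int64)
    for k in range(len(member_starts) - 2, -1, -1):
        nxt = member_starts[k + 1]
        ends = member_starts[k] + lengths[k]
        cum = np.concatenate(([0], np.cumsum(ways)))
        lo = np.searchsorted(nxt, ends, side="left")
        hi = np.searchsorted(nxt, ends + max_gap, side="right")
        ways = cum[hi] - cum[lo]
    return int(ways.sum())


def resolve_targets(
    targets: Iterable[Target | str],
    registry: Mapping[str, IUPACPattern] | None,
) -> list[Target]:
    """Normalise a mixed target list; bare strings name registry motifs."""
    out: list[Target] = []
    for t in targets:
        if isinstance(t, str):
            if registry is None or t not in registry:
                raise KeyError(f"unknown motif name {t!r}")
            out.append(registry[t])
        elif isinstance(t, (IUPACPattern, ModuleSpec)):
            out.append(t)
        else:
            raise TypeError(f"not a motif or module: {t!r}")
    names = [t.name for t in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate target names")
    if not out:
        raise ValueError("no targets given")
    return out


def count_occurrences(
    promoters: PromoterSet,
    targets: Sequence[Target | str],
    registry: Mapping[str, IUPACPattern] | None = None,
    strand_policy: str = "auto_antisense",
) -> pd.DataFrame:
    """Per-promoter occurrence counts: genes x targets integer matrix.

    Motif counts are hit counts; module counts are qualifying-tuple
    counts. This matrix is the single scanning product the whole
    enrichment pipeline (observed statistics, randomized backgrounds,
    false-positive-rate trials) aggregates over.
    """
    _check_policy(strand_policy)
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    targets = resolve_targets(targets, registry)

    motifs: dict[str, IUPACPattern] = {}
    for t in targets:
        if isinstance(t, IUPACPattern):
            motifs[t.name] = t
        else:
            for pat in _resolve_members(t, registry or {}):
                motifs[pat.name] = pat

    seqs = promoters.sequences()
    n = len(seqs)
    sep = "X" * max(len(p) for p in motifs.values())
    big = sep.join(seqs)
    offsets = np.zeros(n, dtype=np.int64)
    if n > 1:
        offsets[1:] = np.cumsum(
            [len(s) + len(sep) for s in seqs[:-1]], dtype=np.int64
        )

    # one pass per motif; hits grouped per promoter for module chaining
    per_motif: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for name, pat in motifs.items():
        idx, local = _pool_motif_starts(big, offsets, pat, strand_policy)
        bounds = np.searchsorted(idx, np.arange(n + 1))
        per_motif[name] = (idx, local, bounds)

    counts = np.zeros((n, len(targets)), dtype=np.int64)
    for j, t in enumerate(targets):
        if isinstance(t, IUPACPattern):
            idx, _, _ = per_motif[t.name]
            counts[:, j] = np.bincount(idx, minlength=n)
        else:
            lengths = [len(motifs[m]) for m in t.members]
            member_data = [per_motif[m] for m in t.members]
            # only promoters containing every member can host an instance
            candidates = np.unique(member_data[0][0])
            for _, (midx, _, _) in zip(t.members[1:], member_data[1:]):
                candidates = np.intersect1d(
                    candidates, np.unique(midx), assume_unique=True
                )
            for p in candidates:
                starts = [
                    local[bounds[p] : bounds[p + 1]]
                    for (_, local, bounds) in member_data
                ]
                counts[p, j] = _count_chains(starts, lengths, t.max_gap)

    return pd.DataFrame(
        counts, index=list(promoters.gene_ids), columns=[t.name for t in targets]
    )


def parameters_from_counts(counts: np.ndarray) -> ParameterVector:
    """The four statistics from a per-promoter count vector. Parameter IV
    uses the n−1 sample variance (0 for a single promoter)."""
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("empty count vector")
    var = float(c.var(ddof=1)) if c.size > 1 else 0.0
    return ParameterVector(
        p1_promoters_with=int((c > 0).sum()),
        p2_mean_per_promoter=float(c.mean()),
        p3_total=int(c.sum()),
        p4_variance=var,
    )


def dataset_parameters(
    promoters: PromoterSet,
    target: Target | str,
    registry: Mapping[str, IUPACPattern] | None = None,
    strand_policy: str = "auto_antisense",
) -> ParameterVector:
    """Compute parameters I-IV for one target over a promoter set."""
    counts = count_occurrences(promoters, [target], registry, strand_policy)
    return parameters_from_counts(counts.iloc[:, 0].to_numpy())
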