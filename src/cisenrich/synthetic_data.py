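"""Synthetic promoter pools with planted motif/module structure.

Generates genome-scale pools of fixed-length i.i.d. promoters with a
controllable GC content, then plants concrete instantiations of motifs
or modules into chosen fractions of the pool and of a designated
experimental subset. Planting overwrites bases in place (no insertion),
so promoter lengths stay constant, like fixed-window upstream dumps.
A planted site may incidentally create extra matches of other targets;
the recorded truth covers planted spans only, so downstream checks
should assert "at least the planted occurrences", not equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .iupac_motifs import IUPAC_CLASSES, IUPACPattern
from .promoter_io import PromoterSet, write_promoters
from .scanner import ModuleSpec, Target

__all__ = [
    "Planting",
    "ScenarioConfig",
    "PlantedInstance",
    "ScenarioTruth",
    "generate_pool",
    "plant_target",
    "make_scenario",
    "write_scenario",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Planting:
    """One target planted at rate ``q_bg`` pool-wide and topped up to
    ``q_exp`` within the experimental subset (presence fractions)."""

    target: Target
    q_bg: float = 0.0
    q_exp: float = 0.0

    def __post_init__(self) -> None:
        for q in (self.q_bg, self.q_exp):
            if not 0.0 <= q <= 1.0:
                raise ValueError("presence fractions must be in [0, 1]")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults mirror a genome-scale situation: ~30000 promoters of 1000 bp
    (an Arabidopsis-sized upstream dump) at balanced GC, with an
    experimental set of 200 genes.
    """

    pool_size: int = 30000
    promoter_length: int = 1000
    gc_content: float = 0.5
    experimental_size: int = 200
    plantings: tuple[Planting, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content <= 1.0:
            raise ValueError("gc_content must be in (0, 1]")
        if self.experimental_size > self.pool_size:
            raise ValueError("experimental_size exceeds pool_size")


@dataclass(frozen=True)
class PlantedInstance:
    target: str
    gene_id: str
    spans: tuple[tuple[int, int], ...]  # one (start, end) per member motif


@dataclass
class ScenarioTruth:
    """Ground truth of planted instances, re-discoverable by the scanner."""

    instances: list[PlantedInstance] = field(default_factory=list)

    def for_target(self, target_name: str) -> list[PlantedInstance]:
        return [i for i in self.instances if i.target == target_name]

    def planted_genes(self, target_name: str) -> set[str]:
        return {i.gene_id for i in self.for_target(target_name)}

    def to_json(self) -> str:
        return json.dumps(
            [
                {"target": i.target, "gene_id": i.gene_id, "spans": list(map(list, i.spans))}
                for i in self.instances
            ],
            indent=1,
        )


def generate_pool(
    pool_size: int = 30000,
    promoter_length: int = 1000,
    gc_content: float = 0.5,
    rng: np.random.Generator | int | None = None,
    label: str = "synthetic pool",
) -> PromoterSet:
    """Pool of i.i.d. random promoters with P(G)=P(C)=gc/2, P(A)=P(T)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    base_idx = rng.choice(4, size=(pool_size, promoter_length), p=[at, gc, gc, at])
    rows = _ALPHABET[base_idx].view(f"S{promoter_length}").ravel()
    width = len(str(pool_size - 1))
    records = {
        f"SYN{i:0{width}d}": rows[i].decode("ascii") for i in range(pool_size)
    }
    return PromoterSet(label, records, provenance="synthetic")


def _instantiate_word(pattern: IUPACPattern, rng: np.random.Generator) -> str:
    """One concrete word: each degenerate position resolved uniformly."""
    return "".join(
        rng.choice(sorted(IUPAC_CLASSES[c])) if len(IUPAC_CLASSES[c]) > 1 else c
        for c in pattern.word
    )


def _layout(
    target: Target,
    registry: Mapping[str, IUPACPattern] | None,
    length: int,
    rng: np.random.Generator,
) -> tuple[list[str], list[tuple[int, int]]]:
    """Concrete member words and spans for one planted instance, placed
    uniformly at random; module gaps drawn uniformly in [0, max_gap]."""
    if isinstance(target, IUPACPattern):
        words = [_instantiate_word(target, rng)]
        gaps: list[int] = []
    else:
        if registry is None:
            raise ValueError("planting a module requires a motif registry")
        words = [_instantiate_word(registry[m], rng) for m in target.members]
        gaps = [int(rng.integers(0, target.max_gap + 1)) for _ in words[1:]]
    span = sum(map(len, words)) + sum(gaps)
    if span > length:
        raise ValueError(
            f"target {target.name!r} (span {span}) does not fit in a "
            f"promoter of length {length}"
        )
    start = int(rng.integers(0, length - span + 1))
    spans = []
    pos = start
    for i, w in enumerate(words):
        spans.append((pos, pos + len(w)))
        pos += len(w) + (gaps[i] if i < len(gaps) else 0)
    return words, spans


def _overlaps(spans: Sequence[tuple[int, int]], taken: Sequence[tuple[int, int]]) -> bool:
    return any(s < te and ts < e for s, e in spans for ts, te in taken)


def _plant_into(
    sequences: dict[str, str],
    gene_ids: Sequence[str],
    target: Target,
    registry: Mapping[str, IUPACPattern] | None,
    rng: np.random.Generator,
    taken: dict[str, list[tuple[int, int]]],
    truth: ScenarioTruth,
    max_tries: int = 100,
) -> None:
    for gid in gene_ids:
        seq = sequences[gid]
        for _ in range(max_tries):
            words, spans = _layout(target, registry, len(seq), rng)
            if not _overlaps(spans, taken.get(gid, ())):
                break
        else:
            raise ValueError(
                f"could not place {target.name!r} in promoter {gid!r} "
                f"without clobbering previously planted sites"
            )
        for w, (s, e) in zip(words, spans):
            seq = seq[:s] + w + seq[e:]
        sequences[gid] = seq
        taken.setdefault(gid, []).extend(spans)
        truth.instances.append(PlantedInstance(target.name, gid, tuple(spans)))


def plant_target(
    pset: PromoterSet,
    target: Target,
    fraction: float,
    rng: np.random.Generator | int | None = None,
    registry: Mapping[str, IUPACPattern] | None = None,
) -> tuple[PromoterSet, ScenarioTruth]:
    """Plant one concrete instance of *target* into exactly
    ``round(fraction * n)`` promoters, chosen uniformly. Returns a new
    promoter set and the truth record of planted spans."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sequences = dict(pset.records)
    truth = ScenarioTruth()
    k = round(fraction * len(pset))
    if k:
        chosen = rng.choice(len(pset), size=k, replace=False)
        ids = [pset.gene_ids[i] for i in chosen]
        _plant_into(sequences, ids, target, registry, rng, {}, truth)
    return (
        PromoterSet(pset.label, sequences, provenance=pset.provenance),
        truth,
    )


def make_scenario(
    config: ScenarioConfig,
    registry: Mapping[str, IUPACPattern] | None = None,
) -> tuple[PromoterSet, list[str], ScenarioTruth]:
    """Build a full scenario: pool with background planting, an
    experimental subset topped up to its target presence fractions, and
    the combined ground truth.

    For each planting, ``round(q_bg * pool_size)`` promoters pool-wide
    receive one instance; then enough additional *experimental* promoters
    are planted for the subset to hold ``round(q_exp * experimental_size)``
    planted promoters in total (never removing background plants, so an
    effective q_exp below q_bg is not enforceable and is left as-is).
    """
    rng = np.random.default_rng(config.seed)
    pool = generate_pool(
        config.pool_size, config.promoter_length, config.gc_content, rng
    )
    sequences = dict(pool.records)
    truth = ScenarioTruth()
    taken: dict[str, list[tuple[int, int]]] = {}

    all_ids = list(pool.gene_ids)
    for planting in config.plantings:
        k = round(planting.q_bg * config.pool_size)
        if k:
            chosen = rng.choice(config.pool_size, size=k, replace=False)
            _plant_into(
                sequences,
                [all_ids[i] for i in chosen],
                planting.target,
                registry,
                rng,
                taken,
                truth,
            )

    exp_pos = rng.choice(config.pool_size, size=config.experimental_size, replace=False)
    experimental_ids = [all_ids[i] for i in sorted(exp_pos)]

    for planting in config.plantings:
        want = round(planting.q_exp * config.experimental_size)
        already = truth.planted_genes(planting.target.name)
        unplanted = [g for g in experimental_ids if g not in already]
        extra = want - (config.experimental_size - len(unplanted))
        if extra > 0:
            chosen = rng.choice(len(unplanted), size=extra, replace=False)
            _plant_into(
                sequences,
                [unplanted[i] for i in chosen],
                planting.target,
                registry,
                rng,
                taken,
                truth,
            )

    pool = PromoterSet(pool.label, sequences, provenance="synthetic")
    return pool, experimental_ids, truth


def write_scenario(
    outdir: str | Path,
    pool: PromoterSet,
    experimental_ids: Sequence[str],
    truth: ScenarioTruth,
) -> None:
    """Emit pool FASTA, experimental gene list and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_promoters(pool, outdir / "pool.fa")
    (outdir / "experimental.txt").write_text(
        "\n".join(experimental_ids) + "\n"
    )
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
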