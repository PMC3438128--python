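"""Report generation and the command-line interface.

Two output styles mirror common practice for promoter cis-element
surveys: a *significance matrix* (targets x datasets, each cell coding
direction, the parameter used and a corrected-p bin) and a ranked
*occurrence list* of the significantly enriched targets ordered by the
number of promoters they occur in, split into single / bipartite /
tripartite combination classes.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import click
import numpy as np
import pandas as pd

from .iupac_motifs import IUPACPattern, default_registry, load_registry
from .promoter_io import load_gene_list, load_promoters, write_promoters
from .randomization import RandomizationConfig
from .scanner import (
    ModuleSpec,
    Target,
    count_occurrences,
    scan_module,
    scan_motif,
)
from .stats import (
    EnrichmentResult,
    SignificanceRecord,
    enrichment_analysis,
    false_positive_rate,
)
from . import synthetic_data

__all__ = [
    "OccurrenceEntry",
    "occurrence_list",
    "significance_matrix",
    "plot_significance_heatmap",
    "run_cli",
    "main",
]


@dataclass(frozen=True)
class OccurrenceEntry:
    target: str
    promoters_with: int
    rank: str  # "3" or a tie span "3-6"
    param2_flag: bool  # significant via motif density (parameter II) only
    combination: str  # "single", "bipartite", "tripartite"


_CLASS_BY_SIZE = {1: "single", 2: "bipartite", 3: "tripartite"}


def _combination_class(name: str, targets: Sequence[Target] | None) -> str:
    if targets is not None:
        for t in targets:
            if t.name == name:
                size = len(t.members) if isinstance(t, ModuleSpec) else 1
                return _CLASS_BY_SIZE[size]
    return _CLASS_BY_SIZE.get(min(name.count("-") + 1, 3), "single")


def occurrence_list(
    records: Sequence[SignificanceRecord],
    counts: Mapping[str, int],
    n: int,
    min_frac: float = 0.05,
    alpha: float = 0.05,
    targets: Sequence[Target] | None = None,
) -> list[OccurrenceEntry]:
    """Ranked list of significantly enriched targets.

    A target is listed when some parameter reaches corrected significance
    (p_corrected <= alpha) and it is present in at least ``min_frac`` of
    the analysed promoters (the presence filter applies to reporting
    only, never to the statistics). Within each combination class,
    entries are ordered by the number of promoters containing the target
    (parameter I), ties sharing a rank span; targets significant solely
    through parameter II carry an asterisk flag (density-only calls,
    the fallback for overabundant motifs).
    """
    by_target: dict[str, list[SignificanceRecord]] = {}
    for rec in records:
        by_target.setdefault(rec.target, []).append(rec)
    floor = math.ceil(min_frac * n)

    selected: list[tuple[str, int, bool, str]] = []
    for name, recs in by_target.items():
        sig = [
            r for r in recs if r.p_corrected is not None and r.p_corrected <= alpha
        ]
        if not sig:
            continue
        p1 = int(counts[name])
        if p1 < floor:
            continue
        param2_only = all(r.parameter == "II" for r in sig)
        selected.append((name, p1, param2_only, _combination_class(name, targets)))

    entries: list[OccurrenceEntry] = []
    for cls in ("single", "bipartite", "tripartite"):
        group = sorted(
            (s for s in selected if s[3] == cls), key=lambda s: (-s[1], s[0])
        )
        pos = 0
        while pos < len(group):
            tie_end = pos
            while tie_end + 1 < len(group) and group[tie_end + 1][1] == group[pos][1]:
                tie_end += 1
            rank = (
                f"{pos + 1}" if tie_end == pos else f"{pos + 1}-{tie_end + 1}"
            )
            for name, p1, p2only, _ in group[pos : tie_end + 1]:
                entries.append(OccurrenceEntry(name, p1, rank, p2only, cls))
            pos = tie_end + 1
    return entries


def occurrence_frame(entries: Sequence[OccurrenceEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "combination": e.combination,
                "rank": e.rank + ("*" if e.param2_flag else ""),
                "target": e.target,
                "promoters_with": e.promoters_with,
            }
            for e in entries
        ]
    )


_P_BINS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _cell_code(recs: list[SignificanceRecord], alpha: float) -> str:
    """Cell code for one target x dataset: parameter I preferred, elevated
    to parameter II when I's background fails the Gaussian screen."""
    by_param = {r.parameter: r for r in recs}
    order = ["I", "II"]
    if "I" in by_param and not by_param["I"].gaussian_ok:
        order = ["II", "I"]
    for pid in order:
        rec = by_param.get(pid)
        if rec is None or rec.p_corrected is None or rec.p_corrected > alpha:
            continue
        if rec.direction == "none":
            continue
        stars = next(s for thr, s in _P_BINS if rec.p_corrected <= thr or thr == 0.05)
        sign = "+" if rec.direction == "enriched" else "-"
        return f"{sign}{pid}{stars}"
    return ""


def significance_matrix(
    records: Sequence[SignificanceRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Targets x datasets matrix of significance codes.

    Codes read ``<sign><parameter><stars>``: ``+`` enrichment / ``-``
    depletion, the parameter used (I, or II when I is non-Gaussian or
    only II is significant), and stars binning the corrected p-value
    (``*`` <= 0.05, ``**`` <= 0.01, ``***`` <= 0.001). Empty cells are
    non-significant.
    """
    cells: dict[tuple[str, str], list[SignificanceRecord]] = {}
    for rec in records:
        cells.setdefault((rec.target, rec.dataset), []).append(rec)
    targets = list(dict.fromkeys(r.target for r in records))
    datasets = list(dict.fromkeys(r.dataset for r in records))
    data = {
        ds: [_cell_code(cells.get((t, ds), []), alpha) for t in targets]
        for ds in datasets
    }
    return pd.DataFrame(data, index=targets)


def plot_significance_heatmap(
    records: Sequence[SignificanceRecord], path: str | Path, alpha: float = 0.05
) -> None:
    """Signed -log10(corrected p) heatmap of the chosen cell per target x
    dataset (blue enrichment, red depletion)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = significance_matrix(records, alpha)
    by_key = {}
    for rec in records:
        if rec.p_corrected is not None:
            key = (rec.target, rec.dataset, rec.parameter)
            by_key[key] = rec
    values = np.zeros(matrix.shape)
    for i, t in enumerate(matrix.index):
        for j, ds in enumerate(matrix.columns):
            code = matrix.iloc[i, j]
            if not code:
                continue
            pid = code[1:].rstrip("*")
            rec = by_key[(t, ds, pid)]
            v = -math.log10(max(rec.p_corrected, 1e-300))
            values[i, j] = v if code[0] == "+" else -v
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.8 * len(matrix.columns), 1.0 + 0.3 * len(matrix.index))
    )
    vmax = max(1.0, np.abs(values).max())
    im = ax.imshow(values, cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    fig.colorbar(im, ax=ax, label="signed -log10 corrected p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# CLI

def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    _atomic_write_text(path, df.to_csv(sep="\t", index=index))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_registry_opt(motifs: str | None):
    return default_registry() if motifs is None else load_registry(motifs)


def _parse_modules(
    module_args: Sequence[str],
    registry: Mapping[str, IUPACPattern],
    max_gap: int,
) -> list[ModuleSpec]:
    specs = []
    for arg in module_args:
        members = arg.split("-")
        unknown = [m for m in members if m not in registry]
        if unknown:
            raise click.UsageError(
                f"module {arg!r}: unknown member motif(s) {unknown}"
            )
        specs.append(ModuleSpec(arg, tuple(members), max_gap))
    return specs


def _manifest(out_dir: Path, params: dict, inputs: dict[str, Path], t0: float) -> None:
    manifest = {
        "tool": "cisenrich",
        "parameters": params,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in inputs.items()
        },
        "runtime_seconds": round(time.monotonic() - t0, 2),
    }
    _atomic_write_text(out_dir / "manifest.json", json.dumps(manifest, indent=1) + "\n")


@click.group(name="cisenrich")
def cli() -> None:
    """Randomization-based promoter cis-element enrichment analysis."""


@cli.command()
@click.option("--pool", type=click.Path(), required=True, help="Promoter pool FASTA.")
@click.option("--genes", "genes_path", type=click.Path(), default=None, help="Gene-ID list (one per line); omit to scan the whole pool.")
@click.option("--motifs", type=click.Path(), default=None, help="Motif registry TSV (default: built-in registry).")
@click.option("--modules", multiple=True, help="Module as dash-joined motif names, e.g. GRE-AUX2 (repeatable).")
@click.option("--max-gap", default=100, show_default=True, help="Maximal gap between module members (bp).")
@click.option("--strand", type=click.Choice(["auto", "watson"]), default="auto", show_default=True)
@click.option("--id-regex", default=None, help="Regex override for gene-ID extraction from FASTA headers.")
@click.option("--exclude-ids", type=click.Path(), default=None, help="IDs to drop from the pool.")
@click.option("--out-dir", type=click.Path(), default=".", show_default=True)
def scan(pool, genes_path, motifs, modules, max_gap, strand, id_regex, exclude_ids, out_dir):
    """Enumerate motif hits and module instances; write a BED-like hit
    table and a per-promoter count matrix."""
    t0 = time.monotonic()
    registry = _load_registry_opt(motifs)
    policy = "auto_antisense" if strand == "auto" else "watson_only"
    excl = load_gene_list(exclude_ids) if exclude_ids else ()
    pset = load_promoters(pool, id_regex=id_regex, exclude_ids=excl)
    if genes_path:
        from .promoter_io import subset_by_genes

        pset, missing = subset_by_genes(pset, load_gene_list(genes_path))
        if missing:
            click.echo(f"warning: {len(missing)} gene IDs not in pool", err=True)
    specs = _parse_modules(modules, registry, max_gap)
    targets: list[Target] = list(registry.values()) + specs

    rows = []
    for gid, seq in pset.records.items():
        for pat in registry.values():
            for h in scan_motif(seq, pat, policy, gid):
                rows.append((gid, h.start, h.end, h.strand, h.motif_name))
        for spec in specs:
            for inst in scan_module(seq, spec, registry, policy, gid):
                lo = min(h.start for h in inst.hits)
                hi = max(h.end for h in inst.hits)
                rows.append((gid, lo, hi, ".", inst.module_name))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hits = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand", "name"])
    _write_tsv(hits, out / "hits.tsv")
    matrix = count_occurrences(pset, targets, registry, policy)
    _write_tsv(matrix.rename_axis("gene_id"), out / "counts.tsv", index=True)
    _manifest(out, {"command": "scan", "strand": strand, "max_gap": max_gap},
              {"pool": Path(pool)}, t0)
    click.echo(f"scanned {len(pset)} promoters, {len(hits)} hits -> {out}")


@cli.command()
@click.option("--pool", type=click.Path(), required=True, help="Genomic promoter pool FASTA.")
@click.option("--genes", "genes_path", type=click.Path(), required=True, help="Experimental gene-ID list.")
@click.option("--motifs", type=click.Path(), default=None, help="Motif registry TSV (default: built-in registry).")
@click.option("--modules", multiple=True, help="Module as dash-joined motif names (repeatable).")
@click.option("--max-gap", default=100, show_default=True)
@click.option("--strand", type=click.Choice(["auto", "watson"]), default="auto", show_default=True)
@click.option("--reps", default=1000, show_default=True, help="Number of random reference sets.")
@click.option("--seed", default=None, type=int)
@click.option("--alpha", default=None, type=float, help="Significance level (default 0.05 corrected, 0.01 uncorrected).")
@click.option("--correction", type=click.Choice(["bonferroni", "none"]), default="bonferroni", show_default=True)
@click.option("--family-size", default=None, type=int, help="Bonferroni family size (default: targets x 4).")
@click.option("--exclude-experimental", is_flag=True, help="Drop experimental promoters from the sampling frame.")
@click.option("--id-regex", default=None)
@click.option("--exclude-ids", type=click.Path(), default=None)
@click.option("--dump-indices", is_flag=True, help="Write draw tally and raw background parameter samples.")
@click.option("--heatmap", is_flag=True, help="Also write a PNG significance heatmap.")
@click.option("--out-dir", type=click.Path(), default=".", show_default=True)
def enrich(pool, genes_path, motifs, modules, max_gap, strand, reps, seed, alpha,
           correction, family_size, exclude_experimental, id_regex, exclude_ids,
           dump_indices, heatmap, out_dir):
    """Run the full randomization enrichment analysis and write
    significance records plus the ranked occurrence list."""
    t0 = time.monotonic()
    registry = _load_registry_opt(motifs)
    policy = "auto_antisense" if strand == "auto" else "watson_only"
    excl = load_gene_list(exclude_ids) if exclude_ids else ()
    pset = load_promoters(pool, id_regex=id_regex, exclude_ids=excl)
    gene_ids = load_gene_list(genes_path)
    specs = _parse_modules(modules, registry, max_gap)
    targets: list[Target] = list(registry.values()) + specs
    config = RandomizationConfig(
        n_reps=reps, seed=seed, exclude_experimental=exclude_experimental
    )
    result = enrichment_analysis(
        pset, gene_ids, targets, config, registry, policy,
        alpha=alpha, correction=correction, family_size=family_size,
        dataset_label=Path(genes_path).stem,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.to_frame(), out / "records.tsv")
    counts_p1 = {t: result.observed[t].p1_promoters_with for t in result.observed}
    entries = occurrence_list(
        result.records, counts_p1, result.n, alpha=result.alpha, targets=targets
    )
    _write_tsv(occurrence_frame(entries), out / "occurrence.tsv")
    _write_tsv(
        significance_matrix(result.records, result.alpha).rename_axis("target"),
        out / "matrix.tsv", index=True,
    )
    if heatmap:
        plot_significance_heatmap(result.records, out / "matrix.png", result.alpha)
    if dump_indices:
        tally = result.backgrounds[0].draw_tally
        _write_tsv(
            pd.DataFrame(sorted(tally.items()), columns=["gene_id", "times_drawn"]),
            out / "draw_tally.tsv",
        )
        for bg in result.backgrounds:
            _write_tsv(bg.samples, out / f"background_{bg.target}.tsv")
    _manifest(
        out,
        {"command": "enrich", "reps": reps, "seed": seed, "alpha": result.alpha,
         "correction": correction, "family_size": result.family_size,
         "strand": strand, "max_gap": max_gap, "n_experimental": result.n,
         "n_missing": len(result.missing), "pool_size": len(pset)},
        {"pool": Path(pool), "genes": Path(genes_path)}, t0,
    )
    n_sig = sum(1 for r in result.records if r.retained)
    click.echo(
        f"{result.dataset}: n={result.n} promoters vs pool of {len(pset)}; "
        f"{n_sig} significant target x parameter calls -> {out}"
    )


@cli.command()
@click.option("--pool", type=click.Path(), required=True)
@click.option("--motifs", type=click.Path(), default=None)
@click.option("--targets", "target_names", multiple=True, help="Motif names to test (default: all registry motifs).")
@click.option("--set-size", default=200, show_default=True)
@click.option("--alpha", default=0.01, show_default=True)
@click.option("--trials", default=1000, show_default=True)
@click.option("--reps", default=1000, show_default=True)
@click.option("--direction", type=click.Choice(["enriched", "depleted", "any"]), default="enriched", show_default=True)
@click.option("--seed", default=None, type=int)
@click.option("--out", "out_path", type=click.Path(), default="fpr.tsv", show_default=True)
def fpr(pool, motifs, target_names, set_size, alpha, trials, reps, direction, seed, out_path):
    """Estimate the false-positive error rate on random null sets."""
    registry = _load_registry_opt(motifs)
    pset = load_promoters(pool)
    targets = list(target_names) or list(registry.values())
    config = RandomizationConfig(n_reps=reps, seed=seed)
    table = false_positive_rate(
        pset, set_size, targets, alpha=alpha, trials=trials,
        config=config, registry=registry, direction=direction,
    )
    _write_tsv(table, Path(out_path))
    click.echo(f"false-positive rates for {len(table) // 4} targets -> {out_path}")


@cli.command()
@click.option("--pool-size", default=30000, show_default=True)
@click.option("--length", default=1000, show_default=True)
@click.option("--gc", default=0.5, show_default=True)
@click.option("--exp-size", default=200, show_default=True)
@click.option("--plant", "plants", multiple=True,
              help="MOTIF:q_bg:q_exp, e.g. RY:0.05:0.5 (repeatable; registry names).")
@click.option("--motifs", type=click.Path(), default=None)
@click.option("--seed", default=None, type=int)
@click.option("--out-dir", type=click.Path(), default="scenario", show_default=True)
def simulate(pool_size, length, gc, exp_size, plants, motifs, seed, out_dir):
    """Generate a synthetic pool with planted targets; write pool FASTA,
    experimental gene list and truth JSON."""
    registry = _load_registry_opt(motifs)
    plantings = []
    for spec in plants:
        try:
            name, q_bg, q_exp = spec.split(":")
            plantings.append(
                synthetic_data.Planting(registry[name], float(q_bg), float(q_exp))
            )
        except (ValueError, KeyError) as exc:
            raise click.UsageError(f"bad --plant spec {spec!r}: {exc}")
    config = synthetic_data.ScenarioConfig(
        pool_size=pool_size, promoter_length=length, gc_content=gc,
        experimental_size=exp_size, plantings=tuple(plantings), seed=seed,
    )
    pool, exp_ids, truth = synthetic_data.make_scenario(config, registry)
    synthetic_data.write_scenario(out_dir, pool, exp_ids, truth)
    click.echo(
        f"wrote pool of {len(pool)} promoters, {len(exp_ids)} experimental "
        f"IDs, {len(truth.instances)} planted instances -> {out_dir}"
    )


def run_cli(argv: Sequence[str]) -> int:
    """Run the CLI on an argument vector; returns a shell exit code
    (0 success, 1 data error, 2 usage error)."""
    try:
        cli.main(args=list(argv), standalone_mode=False)
        return 0
    except click.exceptions.Exit as exc:  # --help and friends
        return int(exc.exit_code)
    except click.UsageError as exc:
        click.echo(f"usage error: {exc.format_message()}", err=True)
        return 2
    except (OSError, ValueError, KeyError) as exc:
        click.echo(f"error: {exc}", err=True)
        return 1


def main() -> None:
    sys.exit(run_cli(sys.argv[1:]))
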