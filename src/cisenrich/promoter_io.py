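"""Promoter FASTA I/O and gene-list subsetting.

The genomic promoter pool is a FASTA file with one record per gene,
typically fixed-length upstream regions (e.g. the TAIR ``upstream_1000``
dumps: −1000..−1 relative to the annotated start, written 5'→3' on the
Watson strand). Coordinates inside the package are 0-based half-open on
the stored string.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "PromoterSet",
    "load_promoters",
    "write_promoters",
    "load_gene_list",
    "subset_by_genes",
]


@dataclass
class PromoterSet:
    """A named, ordered collection of gene-ID -> promoter sequence."""

    label: str
    records: dict[str, str]
    provenance: str = "synthetic"
    _ids: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for gid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for gene {gid!r}")
        self._ids = tuple(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self._ids

    def sequences(self) -> list[str]:
        return [self.records[g] for g in self._ids]

    def modal_length(self) -> int:
        lengths = Counter(len(s) for s in self.records.values())
        return lengths.most_common(1)[0][0]


_DEFAULT_ID_SPLIT = re.compile(r"[\s|]")


def _extract_id(description: str, id_regex: str | None) -> str:
    """Gene ID from a FASTA header: token before the first whitespace or
    ``|`` by default (covers TAIR and RAP styles), or the first group of
    an explicit regex override."""
    if id_regex is not None:
        m = re.search(id_regex, description)
        if not m:
            raise ValueError(
                f"id regex {id_regex!r} found no match in header {description!r}"
            )
        return m.group(1) if m.groups() else m.group(0)
    return _DEFAULT_ID_SPLIT.split(description, 1)[0]


def load_promoters(
    path: str | Path,
    label: str | None = None,
    id_regex: str | None = None,
    exclude_ids: Iterable[str] = (),
) -> PromoterSet:
    """Load a promoter pool from FASTA.

    Sequences are uppercased and U is normalised to T. Duplicate gene IDs
    are a hard error; an empty file is a hard error. Records whose length
    differs from the pool's modal length trigger a warning (short upstream
    regions are tolerated but worth knowing about).
    """
    path = Path(path)
    exclude = set(exclude_ids)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = _extract_id(rec.description, id_regex)
        if gid in exclude:
            continue
        if gid in records:
            raise ValueError(f"duplicate gene ID {gid!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for gene {gid!r} in {path}")
        records[gid] = seq
    if not records:
        raise ValueError(f"no FASTA records loaded from {path}")
    pool = PromoterSet(label or path.stem, records, provenance=str(path))
    modal = pool.modal_length()
    n_odd = sum(1 for s in records.values() if len(s) != modal)
    if n_odd:
        warnings.warn(
            f"{n_odd} of {len(records)} promoters in {path.name} deviate "
            f"from the modal length {modal}",
            stacklevel=2,
        )
    return pool


def write_promoters(pset: PromoterSet, path: str | Path) -> None:
    """Write a promoter set as FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        for gid, seq in pset.records.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def load_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and ``#`` comments skipped."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    if not ids:
        raise ValueError(f"no gene IDs in {path}")
    return ids


def subset_by_genes(
    pool: PromoterSet, gene_ids: Sequence[str], label: str | None = None
) -> tuple[PromoterSet, list[str]]:
    """Select an experimental promoter subset from the pool.

    Returns the subset (IDs in input order) and the list of requested IDs
    absent from the pool. Duplicate requests are collapsed with a warning;
    finding none of the IDs is a hard error.
    """
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    seen: dict[str, None] = {}
    dups = 0
    for gid in gene_ids:
        if gid in seen:
            dups += 1
        seen[gid] = None
    if dups:
        warnings.warn(f"{dups} duplicate gene IDs collapsed", stacklevel=2)
    found = {gid: pool.records[gid] for gid in seen if gid in pool}
    missing = [gid for gid in seen if gid not in pool]
    if not found:
        raise ValueError(
            f"none of the {len(seen)} requested gene IDs are in pool "
            f"{pool.label!r} (empty experimental set)"
        )
    subset = PromoterSet(
        label or f"{pool.label}:subset", found, provenance=pool.provenance
    )
    return subset, missing
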