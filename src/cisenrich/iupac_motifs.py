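"""IUPAC-degenerate DNA patterns and the default transcription-factor
binding-site registry.

A cis-element is represented as a fixed-length word over the IUPAC
nucleotide alphabet (``R`` = A/G, ``Y`` = C/T, ``B`` = C/G/T, ...).
Matching is plain word matching where each degenerate letter admits its
base class; there are no gaps or mismatches inside a single motif.

Sequence-side ambiguity codes (``N`` runs from masked or unsequenced
genomic stretches) never satisfy any pattern position, so masked regions
cannot inflate occurrence counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "IUPAC_CLASSES",
    "IUPAC_COMPLEMENT",
    "IUPACPattern",
    "matches_at",
    "reverse_complement",
    "load_registry",
    "default_registry",
    "write_registry",
]

#: Base classes of the IUPAC nucleotide alphabet (concrete bases only).
IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Complement map on the IUPAC alphabet (closed: complement of a class is
#: the class of complements).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class IUPACPattern:
    """A named degenerate DNA word, e.g. ``GRE = BACGTV``.

    Parameters
    ----------
    name:
        Short identifier, unique within a registry.
    word:
        Uppercase string over the IUPAC alphabet, length >= 3.
    """

    name: str
    word: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("pattern name must be non-empty")
        word = self.word.upper()
        object.__setattr__(self, "word", word)
        if len(word) < 3:
            raise ValueError(
                f"pattern {self.name!r}: word {word!r} shorter than 3"
            )
        bad = set(word) - set(IUPAC_CLASSES)
        if bad:
            raise ValueError(
                f"pattern {self.name!r}: illegal IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.word)

    def __str__(self) -> str:
        return f"{self.name}={self.word}"


def matches_at(pattern: IUPACPattern, sequence: str, offset: int) -> bool:
    """True iff *pattern* matches *sequence* at 0-based *offset*.

    The sequence is assumed uppercase (I/O layers normalise on load).
    A sequence character outside {A,C,G,T} matches no pattern position.
    """
    word = pattern.word
    if offset < 0 or offset > len(sequence) - len(word):
        raise IndexError(
            f"offset {offset} out of range for word of length {len(word)} "
            f"in sequence of length {len(sequence)}"
        )
    for i, code in enumerate(word):
        if sequence[offset + i] not in IUPAC_CLASSES[code]:
            return False
    return True


def reverse_complement(pattern: IUPACPattern) -> IUPACPattern:
    """The Crick word of *pattern*: IUPAC complement of the reversed word.

    The name is retained (both words denote the same cis-element);
    applying the operation twice returns the original pattern.
    """
    word = "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern.word))
    return IUPACPattern(pattern.name, word)


@lru_cache(maxsize=512)
def compile_word(word: str) -> re.Pattern[str]:
    """Compile an IUPAC word to a lookahead regex yielding overlapping
    match start positions over the concrete {A,C,G,T} alphabet."""
    parts = []
    for code in word:
        bases = "".join(sorted(IUPAC_CLASSES[code]))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?={''.join(parts)})")


# ---------------------------------------------------------------------------
# Registry I/O

def _check_registry(patterns: Iterable[IUPACPattern]) -> dict[str, IUPACPattern]:
    registry: dict[str, IUPACPattern] = {}
    for pat in patterns:
        if pat.name in registry:
            raise ValueError(f"duplicate motif name {pat.name!r} in registry")
        registry[pat.name] = pat
    if not registry:
        raise ValueError("empty motif registry")
    return registry


def load_registry(path: str | Path) -> dict[str, IUPACPattern]:
    """Read a motif registry from a plain TSV file (``name<TAB>word``,
    ``#`` comment lines allowed). Returns an ordered name -> pattern map."""
    patterns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'name<TAB>word', got {line!r}"
                )
            patterns.append(IUPACPattern(fields[0], fields[1]))
    return _check_registry(patterns)


def write_registry(registry: dict[str, IUPACPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pat in registry.values():
            fh.write(f"{pat.name}\t{pat.word}\n")


def default_registry() -> dict[str, IUPACPattern]:
    """The nine default TF-binding sites shipped with the package: the
    bZIP-related ZREs (GRE, TGA, AC), the B3-type sites (AUX1, AUX2, RY)
    and the MYB/MYC-related sites (MRE1, MRE2, MYC2)."""
    with resources.as_file(
        resources.files("cisenrich").joinpath("data/default_motifs.tsv")
    ) as path:
        return load_registry(path)
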