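"""Independent brute-force oracles for scanning.

Deliberately naive: per-offset set-membership window checks and full
tuple enumeration, written against their own copy of the IUPAC tables so
they share no code with the package's scanner.
"""

from itertools import product

BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def revcomp_word(word: str) -> str:
    return "".join(COMP[c] for c in reversed(word))


def window_matches(seq: str, word: str, off: int) -> bool:
    return all(seq[off + i] in BASES[c] for i, c in enumerate(word))


def brute_starts(seq: str, word: str, both_strands: bool = True) -> list[int]:
    """Deduplicated sorted start offsets of word (and optionally its
    reverse complement) over every window of seq."""
    words = {word, revcomp_word(word)} if both_strands else {word}
    out = set()
    for w in words:
        for off in range(len(seq) - len(w) + 1):
            if window_matches(seq, w, off):
                out.add(off)
    return sorted(out)


def brute_module_count(
    seq: str, member_words: list[str], max_gap: int, both_strands: bool = True
) -> int:
    """Number of ordered hit tuples: one hit per member, starts strictly
    ordered with non-overlap and a bounded gap between consecutive hits."""
    hit_lists = [
        [(s, s + len(w)) for s in brute_starts(seq, w, both_strands)]
        for w in member_words
    ]
    count = 0
    for combo in product(*hit_lists):
        ok = all(
            combo[k + 1][0] >= combo[k][1]
            and combo[k + 1][0] - combo[k][1] <= max_gap
            for k in range(len(combo) - 1)
        )
        count += ok
    return count


def iid_match_probability(word: str, base_probs: dict[str, float]) -> float:
    """Probability that one i.i.d. window matches word or its reverse
    complement (inclusion-exclusion over the two class products)."""

    def prob(w: str) -> float:
        p = 1.0
        for c in w:
            p *= sum(base_probs[b] for b in BASES[c])
        return p

    rc = revcomp_word(word)
    both = 1.0
    for c1, c2 in zip(word, rc):
        shared = set(BASES[c1]) & set(BASES[c2])
        both *= sum(base_probs[b] for b in shared)
    return prob(word) + prob(rc) - both
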