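"""Motif/module scanning semantics and the four dataset statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cisenrich import GRAUX_OLIGO
from cisenrich.iupac_motifs import IUPACPattern
from cisenrich.promoter_io import PromoterSet
from cisenrich.scanner import (
    ModuleSpec,
    count_occurrences,
    dataset_parameters,
    parameters_from_counts,
    scan_module,
    scan_motif,
)

import oracles
from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestGrauxExample:
    """The hand-checkable AtGH3.3-derived GRAUX fragment: one G-box
    related element upstream of two auxin response elements."""

    def test_single_motif_hits(self, registry):
        gre = scan_motif(GRAUX_OLIGO, registry["GRE"])
        aux2 = scan_motif(GRAUX_OLIGO, registry["AUX2"])
        assert [(h.start, h.end) for h in gre] == [(20, 26)]
        assert GRAUX_OLIGO[20:26] == "TACGTG"
        assert [(h.start, h.end) for h in aux2] == [(39, 45), (46, 52)]

    def test_module_instances(self, registry):
        fwd = scan_module(GRAUX_OLIGO, ModuleSpec.from_members(["GRE", "AUX2"]), registry)
        rev = scan_module(GRAUX_OLIGO, ModuleSpec.from_members(["AUX2", "GRE"]), registry)
        assert len(fwd) == 2 and len(rev) == 0
        for inst in fwd:
            starts = [h.start for h in inst.hits]
            assert starts == sorted(starts)

    def test_zero_gap_separated_hits_yield_no_instance(self, registry):
        spec = ModuleSpec("GRE-AUX2", ("GRE", "AUX2"), max_gap=0)
        assert scan_module(GRAUX_OLIGO, spec, registry) == []


def test_empty_sequence_and_short_sequence(registry):
    assert scan_motif("", registry["GRE"]) == []
    assert scan_motif("ACG", registry["RY"]) == []


def test_dyad_symmetric_span_counted_once(registry):
    # TACGTG matches BACGTV on both strands over the same span
    hits = scan_motif("TACGTG", registry["GRE"])
    assert len(hits) == 1 and hits[0].strand == "watson"


def test_crick_only_hit_strand_attribution(registry):
    # SRGACA (revcomp of TGTCYS) present, TGTCYS itself absent
    hits = scan_motif("AAGGGACAAA", registry["AUX2"])
    assert [h.strand for h in hits] == ["crick"]
    assert scan_motif("AAGGGACAAA", registry["AUX2"], "watson_only") == []


def test_overlapping_self_matches_enumerated():
    pat = IUPACPattern("x", "AAA")
    assert [h.start for h in scan_motif("AAAAA", pat, "watson_only")] == [0, 1, 2]


@pytest.mark.parametrize("seed", range(4))
def test_scan_motif_equals_brute_force(registry, seed):
    rng = np.random.default_rng(seed)
    for _ in range(40):
        seq = random_dna(rng, int(rng.integers(10, 300)))
        for pat in registry.values():
            got = [h.start for h in scan_motif(seq, pat)]
            assert got == oracles.brute_starts(seq, pat.word)
            got_w = [h.start for h in scan_motif(seq, pat, "watson_only")]
            assert got_w == oracles.brute_starts(seq, pat.word, both_strands=False)


def test_scan_module_equals_brute_force(registry):
    rng = np.random.default_rng(7)
    names = list(registry)
    for _ in range(60):
        seq = random_dna(rng, int(rng.integers(30, 300)))
        k = int(rng.integers(2, 4))
        members = [names[i] for i in rng.integers(0, len(names), size=k)]
        gap = int(rng.integers(0, 120))
        spec = ModuleSpec("m", tuple(members), gap)
        got = len(scan_module(seq, spec, registry))
        want = oracles.brute_module_count(seq, [registry[m].word for m in members], gap)
        assert got == want


@settings(max_examples=60, derandomize=True)
@given(seq=dna)
def test_motif_count_invariant_under_reverse_complement(registry, seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(seq))
    for pat in (registry["AUX2"], registry["MRE1"]):
        assert len(scan_motif(seq, pat)) == len(scan_motif(rc, pat))


@settings(max_examples=60, derandomize=True)
@given(seq=dna)
def test_module_mirror_property(registry, seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(seq))
    ab = ModuleSpec("ab", ("TGA", "MRE2"), 40)
    ba = ModuleSpec("ba", ("MRE2", "TGA"), 40)
    assert len(scan_module(seq, ab, registry)) == len(scan_module(rc, ba, registry))


def test_instance_count_monotone_in_max_gap(registry):
    rng = np.random.default_rng(13)
    for _ in range(20):
        seq = random_dna(rng, 250)
        counts = [
            len(scan_module(seq, ModuleSpec("m", ("MRE2", "MRE2"), g), registry))
            for g in (0, 5, 20, 100, 250)
        ]
        assert counts == sorted(counts)


def test_unknown_module_member_is_config_error(registry):
    spec = ModuleSpec("bad", ("GRE", "NOPE"))
    with pytest.raises(KeyError, match="NOPE"):
        scan_module("ACGT" * 20, spec, registry)


def test_count_matrix_agrees_with_per_sequence_scans(registry):
    rng = np.random.default_rng(3)
    pool = PromoterSet(
        "p", {f"g{i}": random_dna(rng, 200) for i in range(40)}
    )
    spec = ModuleSpec.from_members(["GRE", "AUX2"])
    counts = count_occurrences(pool, ["GRE", "AUX2", spec], registry)
    for gid, seq in pool.records.items():
        assert counts.loc[gid, "GRE"] == len(scan_motif(seq, registry["GRE"]))
        assert counts.loc[gid, "AUX2"] == len(scan_motif(seq, registry["AUX2"]))
        assert counts.loc[gid, "GRE-AUX2"] == len(scan_module(seq, spec, registry))


class TestDatasetParameters:
    def test_arithmetic_example(self):
        pv = parameters_from_counts(np.array([2, 0]))
        assert (pv.p1_promoters_with, pv.p2_mean_per_promoter, pv.p3_total, pv.p4_variance) == (1, 1.0, 2, 2.0)

    def test_all_zero(self):
        pv = parameters_from_counts(np.zeros(5, dtype=int))
        assert pv.as_array().tolist() == [0, 0.0, 0, 0.0]

    def test_single_promoter_variance_zero(self):
        assert parameters_from_counts(np.array([3])).p4_variance == 0.0

    def test_total_equals_mean_times_n(self, registry):
        rng = np.random.default_rng(5)
        pool = PromoterSet("p", {f"g{i}": random_dna(rng, 150) for i in range(17)})
        pv = dataset_parameters(pool, "MRE2", registry)
        assert pv.p3_total == round(pv.p2_mean_per_promoter * len(pool))
        assert pv.p1_promoters_with <= len(pool)

    def test_empty_set_rejected(self, registry):
        with pytest.raises(ValueError):
            parameters_from_counts(np.array([]))
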