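"""Occurrence lists, significance matrices, and the CLI."""

import json

import pytest

from cisenrich.reporting import (
    occurrence_frame,
    occurrence_list,
    run_cli,
    significance_matrix,
)
from cisenrich.stats import SignificanceRecord


def rec(target, param="I", p_corr=0.01, direction="enriched",
        gaussian_ok=True, dataset="ds"):
    return SignificanceRecord(
        target=target, parameter=param, observed=1.0, bg_mean=0.5, bg_sd=0.1,
        z=2.0 if direction == "enriched" else -2.0, p_raw=p_corr / 10,
        direction=direction, gaussian_ok=gaussian_ok,
        p_corrected=p_corr, retained=p_corr <= 0.05, dataset=dataset,
    )


class TestOccurrenceList:
    def test_sorted_by_promoter_presence(self):
        records = [rec("A"), rec("B"), rec("C")]
        counts = {"A": 134, "B": 123, "C": 93}
        entries = occurrence_list(records, counts, n=179)
        assert [e.target for e in entries] == ["A", "B", "C"]
        assert [e.rank for e in entries] == ["1", "2", "3"]

    def test_presence_floor_excludes_rare_targets(self):
        entries = occurrence_list([rec("A")], {"A": 4}, n=100, min_frac=0.05)
        assert entries == []
        entries = occurrence_list([rec("A")], {"A": 5}, n=100, min_frac=0.05)
        assert [e.target for e in entries] == ["A"]

    def test_nonsignificant_targets_never_listed(self):
        records = [rec("A"), rec("B", p_corr=0.2)]
        entries = occurrence_list(records, {"A": 50, "B": 60}, n=100)
        assert [e.target for e in entries] == ["A"]

    def test_parameter_two_only_flagged_with_asterisk(self):
        records = [
            rec("AUX2", param="II"),
            rec("AUX2", param="I", p_corr=0.9),
            rec("GRE", param="I"),
        ]
        entries = occurrence_list(records, {"AUX2": 181, "GRE": 172}, n=250)
        flags = {e.target: e.param2_flag for e in entries}
        assert flags == {"AUX2": True, "GRE": False}
        df = occurrence_frame(entries)
        assert df.loc[df["target"] == "AUX2", "rank"].item().endswith("*")

    def test_tied_counts_share_a_rank_span(self):
        records = [rec(t) for t in "ABCDE"]
        counts = {"A": 90, "B": 70, "C": 70, "D": 70, "E": 50}
        entries = occurrence_list(records, counts, n=200)
        ranks = {e.target: e.rank for e in entries}
        assert ranks == {"A": "1", "B": "2-4", "C": "2-4", "D": "2-4", "E": "5"}

    def test_modules_ranked_within_their_own_class(self):
        records = [rec("GRE"), rec("GRE-AUX2"), rec("GRE-AUX2-MRE2")]
        counts = {"GRE": 120, "GRE-AUX2": 40, "GRE-AUX2-MRE2": 22}
        entries = occurrence_list(records, counts, n=200)
        classes = {e.target: (e.combination, e.rank) for e in entries}
        assert classes == {
            "GRE": ("single", "1"),
            "GRE-AUX2": ("bipartite", "1"),
            "GRE-AUX2-MRE2": ("tripartite", "1"),
        }

    def test_output_is_byte_stable(self):
        records = [rec(t) for t in "BAC"]
        counts = {"A": 70, "B": 70, "C": 70}
        a = occurrence_frame(occurrence_list(records, counts, n=200)).to_csv()
        b = occurrence_frame(occurrence_list(list(reversed(records)), counts, n=200)).to_csv()
        assert a == b


class TestSignificanceMatrix:
    def test_nonsignificant_records_give_empty_cells(self):
        m = significance_matrix([rec("A", p_corr=0.5)])
        assert m.loc["A", "ds"] == ""

    def test_enriched_parameter_one_cell(self):
        m = significance_matrix([rec("A", p_corr=0.01)])
        assert m.loc["A", "ds"] == "+I**"

    def test_depletion_mirrors_enrichment_code(self):
        up = significance_matrix([rec("A")]).loc["A", "ds"]
        down = significance_matrix([rec("A", direction="depleted")]).loc["A", "ds"]
        assert up[0] == "+" and down[0] == "-" and up[1:] == down[1:]

    def test_parameter_two_elevated_when_one_not_gaussian(self):
        records = [
            rec("MRE2", param="I", p_corr=0.001, gaussian_ok=False),
            rec("MRE2", param="II", p_corr=0.04),
        ]
        m = significance_matrix(records)
        assert m.loc["MRE2", "ds"] == "+II*"

    def test_p_bins(self):
        assert significance_matrix([rec("A", p_corr=0.0005)]).loc["A", "ds"] == "+I***"
        assert significance_matrix([rec("A", p_corr=0.03)]).loc["A", "ds"] == "+I*"


class TestCli:
    def run_simulate(self, tmp_path, seed=1):
        out = tmp_path / "scenario"
        code = run_cli([
            "simulate", "--pool-size", "300", "--length", "300",
            "--exp-size", "40", "--plant", "RY:0.05:0.5",
            "--seed", str(seed), "--out-dir", str(out),
        ])
        assert code == 0
        return out

    def test_simulate_writes_scenario(self, tmp_path):
        out = self.run_simulate(tmp_path)
        assert (out / "pool.fa").exists()
        assert (out / "experimental.txt").exists()
        json.loads((out / "truth.json").read_text())

    def test_enrich_end_to_end(self, tmp_path):
        scenario = self.run_simulate(tmp_path)
        out = tmp_path / "results"
        code = run_cli([
            "enrich", "--pool", str(scenario / "pool.fa"),
            "--genes", str(scenario / "experimental.txt"),
            "--modules", "GRE-AUX2", "--reps", "300", "--seed", "7",
            "--dump-indices", "--out-dir", str(out),
        ])
        assert code == 0
        for name in ("records.tsv", "occurrence.tsv", "matrix.tsv",
                     "manifest.json", "draw_tally.tsv"):
            assert (out / name).exists(), name
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["parameters"]["seed"] == 7
        header = (out / "records.tsv").read_text().splitlines()[0]
        assert "p_corrected" in header

    def test_missing_pool_file_is_data_error(self, tmp_path):
        code = run_cli([
            "enrich", "--pool", str(tmp_path / "nope.fa"),
            "--genes", str(tmp_path / "nope.txt"),
        ])
        assert code == 1

    def test_unknown_flag_is_usage_error(self):
        assert run_cli(["enrich", "--frobnicate"]) == 2

    def test_unknown_module_member_is_usage_error(self, tmp_path):
        scenario = self.run_simulate(tmp_path)
        code = run_cli([
            "enrich", "--pool", str(scenario / "pool.fa"),
            "--genes", str(scenario / "experimental.txt"),
            "--modules", "GRE-NOPE",
        ])
        assert code == 2

    def test_scan_single_pool(self, tmp_path):
        scenario = self.run_simulate(tmp_path)
        out = tmp_path / "scan"
        code = run_cli([
            "scan", "--pool", str(scenario / "pool.fa"),
            "--modules", "GRE-AUX2", "--out-dir", str(out),
        ])
        assert code == 0
        counts_header = (out / "counts.tsv").read_text().splitlines()[0]
        assert "GRE-AUX2" in counts_header
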