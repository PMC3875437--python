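"""Variant-table and alignment I/O: parsing, validation, clone merging,
reference numbering, round-trips."""

import math
import textwrap

import pandas as pd
import pytest

import rheoscan as rs
from rheoscan.variants import (
    build_reference_alignment,
    contexts_to_frame,
    position_sort_key,
    read_report,
    write_report,
)

HEADER = "homolog,position,wt_aa,sub_aa,condition,mean_miller,sd_miller,n_reps"


def write_table(tmp_path, rows, name="vars.csv"):
    path = tmp_path / name
    path.write_text(HEADER + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path


class TestVariantTable:
    def test_basic_row_parses_into_measurement(self, tmp_path):
        path = write_table(tmp_path, ["LacI-11,62,K,A,minus,0.25,0.05,4"])
        df = rs.read_variant_table(path)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["condition"] == rs.MINUS
        assert row["position"] == "62"
        assert row["mean_miller"] == pytest.approx(0.25)

    def test_empty_data_section_gives_empty_frame(self, tmp_path):
        df = rs.read_variant_table(write_table(tmp_path, []))
        assert len(df) == 0

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("homolog,position,wt_aa,sub_aa,condition,mean_miller\n")
        with pytest.raises(rs.SchemaError, match="sd_miller"):
            rs.read_variant_table(path)

    def test_negative_activity_rejected_with_row_index(self, tmp_path):
        path = write_table(tmp_path, ["H,50,K,A,minus,-1,0.1,4"])
        with pytest.raises(rs.ValidationError, match="row 0"):
            rs.read_variant_table(path)

    def test_unknown_amino_acid_letter_rejected(self, tmp_path):
        path = write_table(tmp_path, ["H,50,K,B,minus,1,0.1,4"])
        with pytest.raises(rs.ValidationError, match="amino-acid"):
            rs.read_variant_table(path)

    def test_duplicate_clones_merge_to_geometric_mean(self, tmp_path):
        path = write_table(tmp_path, [
            "H,50,K,A,minus,1.0,0.1,4",
            "H,50,K,A,minus,1.8,0.2,4",
        ])
        warnings = []
        df = rs.read_variant_table(path, warnings=warnings)
        assert len(df) == 1
        assert df.iloc[0]["mean_miller"] == pytest.approx(math.sqrt(1.0 * 1.8), abs=5e-3)
        assert df.iloc[0]["mean_miller"] == pytest.approx(1.34, abs=5e-3)
        assert df.iloc[0]["n_reps"] == 8
        assert warnings == []  # within 2-fold: no flag

    def test_clones_beyond_twofold_flagged_but_merged(self, tmp_path):
        path = write_table(tmp_path, [
            "H,50,K,A,minus,1.0,0.1,4",
            "H,50,K,A,minus,2.5,0.2,4",
        ])
        warnings = []
        df = rs.read_variant_table(path, warnings=warnings)
        assert len(df) == 1
        assert len(warnings) == 1 and ">2-fold" in warnings[0]

    def test_excluded_flag_preserved(self, tmp_path):
        path = tmp_path / "vars.csv"
        path.write_text(HEADER + ",excluded\nH,50,K,A,minus,1,0.1,4,True\n")
        df = rs.read_variant_table(path)
        assert bool(df.iloc[0]["excluded"]) is True

    def test_round_trip_preserves_every_tuple(self, tmp_path, noisy_dataset):
        _, variants, _, _ = noisy_dataset
        out = tmp_path / "rt.tsv"
        variants.to_csv(out, sep="\t", index=False)
        back = rs.read_variant_table(out)
        key = ["homolog", "position", "sub_aa", "condition"]
        a = variants.sort_values(key).reset_index(drop=True)
        b = back.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a[b.columns], b, check_dtype=False)


class TestContexts:
    def test_round_trip(self, tmp_path, clean_dataset):
        _, _, _, contexts = clean_dataset
        path = tmp_path / "ctx.csv"
        contexts_to_frame(contexts).to_csv(path, index=False)
        back = rs.read_contexts(path)
        assert back == contexts

    def test_parent_row_value_used(self, tmp_path):
        path = tmp_path / "ctx.csv"
        path.write_text(
            "homolog,parent_miller,parent_sd,del_control,active_condition\n"
            "LacI-11,0.12,0.06,4000,minus\n"
        )
        ctx = rs.read_contexts(path)["LacI-11"]
        assert ctx.parent_activity == pytest.approx(0.12)
        assert ctx.active_condition == rs.MINUS

    def test_del_must_exceed_parent(self):
        with pytest.raises(rs.ValidationError):
            rs.HomologContext("H", parent_activity=10.0, parent_sd=1.0,
                              del_control=5.0)


class TestAlignment:
    def test_column_map_skips_reference_gaps(self):
        aln = build_reference_alignment(["r", "s"], ["M-KV", "MAKV"], "r",
                                        reference_offset=1)
        assert aln.column_map == {"1": 0, "2": 2, "3": 3}

    def test_ragged_alignment_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nMKV\n>b\nMK\n>c\nMKVL\n")
        with pytest.raises(rs.ValidationError, match="ragged"):
            rs.read_alignment(path, "a")

    def test_missing_reference_rejected(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">a\nMKV\n>b\nMKL\n")
        with pytest.raises(KeyError):
            rs.read_alignment(path, "zz")

    def test_known_gap_pattern_maps_by_hand(self, tmp_path):
        # reference: A-C-DE  -> offset 45: 45->0, 46->2, 47->4, 48->5
        seqs = [("ref", "A-C-DE")] + [(f"s{i}", "AXCXDE") for i in range(9)]
        path = tmp_path / "aln.fasta"
        path.write_text("".join(f">{i}\n{s}\n" for i, s in seqs))
        aln = rs.read_alignment(path, "ref", 45)
        assert aln.column_map == {"45": 0, "46": 2, "47": 4, "48": 5}

    def test_column_map_order_respected(self, synthetic_msa):
        _, aln, _ = synthetic_msa
        positions = sorted(aln.column_map, key=position_sort_key)
        cols = [aln.column_map[p] for p in positions]
        assert cols == sorted(cols)

    def test_insertion_labels_sort_after_integer(self):
        labels = ["62", "61a", "45", "61"]
        assert sorted(labels, key=position_sort_key) == ["45", "61", "61a", "62"]


class TestReports:
    def test_empty_table_round_trips_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["position", "code"])
        out = tmp_path / "empty.tsv"
        write_report(df, out)
        assert out.read_text().strip() == "position\tcode"

    def test_write_then_read_equality(self, tmp_path, noisy_dataset):
        _, variants, _, contexts = noisy_dataset
        behavior = rs.classify_dataset(variants, contexts)
        out = tmp_path / "behavior.tsv"
        write_report(behavior, out)
        back = read_report(out)
        pd.testing.assert_frame_equal(behavior, back, check_dtype=False,
                                      check_exact=False, atol=1e-6)

    def test_entropy_table_two_decimal_style(self, tmp_path):
        df = pd.DataFrame({"position": ["50", "51", "52"],
                           "H": [0.60, 1.92, 1.80]})
        out = tmp_path / "entropy.tsv"
        write_report(df, out, float_format="%.2f")
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 4
        assert lines[1].split("\t")[1] == "0.60"
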