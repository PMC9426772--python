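import numpy as np
import pytest

from circmilink.corpus_io import (
    AdjacencyMatrix,
    DuplicateIdError,
    FastaParseError,
    InteractionTable,
    SequenceRecord,
    UnknownIdError,
    build_adjacency,
    merge_interaction_sources,
    read_fasta,
    read_pairs,
    write_fasta,
    write_pairs,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = _write(tmp_path, "a.fa", ">c1\nACGU\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "c1"
        assert recs[0].sequence == "ACGU"

    def test_wrapped_lines_joined_and_uppercased(self, tmp_path):
        p = _write(tmp_path, "a.fa", ">c1\nac\ngu\n")
        assert read_fasta(p)[0].sequence == "ACGU"

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert read_fasta(_write(tmp_path, "e.fa", "")) == []

    def test_headerless_first_line_names_line_number(self, tmp_path):
        p = _write(tmp_path, "bad.fa", "ACGT\n>c1\nACGT\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = _write(tmp_path, "dup.fa", ">c1\nAC\n>c1\nGT\n")
        with pytest.raises(DuplicateIdError):
            read_fasta(p)

    def test_round_trip(self, tmp_path):
        recs = [
            SequenceRecord("c1", "circRNA", "ACGU" * 40),
            SequenceRecord("c2", "circRNA", "GGCC"),
        ]
        out = tmp_path / "rt.fa"
        write_fasta(recs, out)
        back = read_fasta(out)
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in recs
        ]


class TestSequenceRecord:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"id": "", "molecule_class": "miRNA", "sequence": "A"},
            {"id": "x", "molecule_class": "tRNA", "sequence": "A"},
            {"id": "x", "molecule_class": "miRNA", "sequence": ""},
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SequenceRecord(**kwargs)


class TestMerge:
    def test_union_removes_duplicates(self):
        t1 = InteractionTable.from_pairs([("c1", "m1")], source="a")
        t2 = InteractionTable.from_pairs(
            [("c1", "m1"), ("c2", "m2")], source="b"
        )
        merged = merge_interaction_sources([t1, t2])
        assert len(merged) == 2
        assert merged.provenance[("c1", "m1")] == {"a", "b"}

    def test_case_fold_normalization_collapses_pairs(self):
        t1 = InteractionTable.from_pairs([("C1", "m1")], source="a")
        t2 = InteractionTable.from_pairs([(" c1", "M1 ")], source="b")
        assert len(merge_interaction_sources([t1, t2])) == 1

    def test_disjoint_tables_sum(self):
        t1 = InteractionTable.from_pairs([("c1", "m1"), ("c2", "m1")])
        t2 = InteractionTable.from_pairs(
            [("c3", "m2"), ("c4", "m2"), ("c5", "m3")]
        )
        assert len(merge_interaction_sources([t1, t2])) == 5

    def test_empty_input(self):
        assert len(merge_interaction_sources([])) == 0


class TestPairsIO:
    def test_header_autodetect_and_round_trip(self, tmp_path):
        table = InteractionTable.from_pairs(
            [("c1", "m1"), ("c2", "m2")], source="db1"
        )
        p = tmp_path / "pairs.tsv"
        write_pairs(table, p)
        back = read_pairs(p)
        assert set(back.pairs) == set(table.pairs)

    def test_headerless_file(self, tmp_path):
        p = _write(tmp_path, "p.tsv", "c1\tm1\nc2\tm2\n")
        assert len(read_pairs(p)) == 2


class TestBuildAdjacency:
    def test_single_pair_placement(self):
        table = InteractionTable.from_pairs([("c1", "m1")])
        adj = build_adjacency(table, ["c1", "c2"], ["m1", "m2"])
        assert adj.P.tolist() == [[1, 0], [0, 0]]

    def test_empty_table_all_zero(self):
        adj = build_adjacency(InteractionTable(), ["c1"], ["m1"])
        assert adj.P.sum() == 0

    def test_full_table_all_ones(self):
        pairs = [(c, m) for c in ("c1", "c2") for m in ("m1", "m2")]
        adj = build_adjacency(
            InteractionTable.from_pairs(pairs), ["c1", "c2"], ["m1", "m2"]
        )
        assert adj.P.sum() == 4

    def test_unknown_id_error(self):
        table = InteractionTable.from_pairs([("c9", "m1")])
        with pytest.raises(UnknownIdError):
            build_adjacency(table, ["c1"], ["m1"])

    def test_row_permutation_consistency(self):
        pairs = [("c1", "m1"), ("c2", "m2"), ("c3", "m1")]
        table = InteractionTable.from_pairs(pairs)
        a = build_adjacency(table, ["c1", "c2", "c3"], ["m1", "m2"])
        b = build_adjacency(table, ["c3", "c1", "c2"], ["m1", "m2"])
        assert np.array_equal(a.P[[2, 0, 1]], b.P)

    def test_sum_equals_unique_pairs(self):
        pairs = [("c1", "m1"), ("c1", "m2"), ("c2", "m2")]
        adj = build_adjacency(InteractionTable.from_pairs(pairs))
        assert adj.P.sum() == len(set(pairs))

    def test_entries_validated(self):
        with pytest.raises(ValueError):
            AdjacencyMatrix(np.array([[2]]), ["c1"], ["m1"])
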