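import numpy as np
import pandas as pd
import pytest

from hemenet.io_formats import FormatError, GenomeEntry, GenomeSet, ProteinRecord
from hemenet.orthology import (
    Orthogroup,
    assignment_stats,
    concatenate_supermatrix,
    infer_orthogroups_rbh,
    map_markers_to_ogs,
    marker_prevalence_and_copies,
    og_sharing_stats,
    parse_orthogroups,
    presence_matrix,
    single_copy_core,
)
from oracles import sharing_oracle, single_copy_oracle


def write_og_table(tmp_path, text):
    p = tmp_path / "Orthogroups.tsv"
    p.write_text(text)
    return p


class TestParseOrthogroups:
    def test_member_lists_parsed(self, tmp_path):
        p = write_og_table(tmp_path, "Orthogroup\tA\tB\tC\nOG0000001\tp1, p2\t\tp3\n")
        ogs = parse_orthogroups(p)
        assert len(ogs) == 1
        assert ogs[0].members == {"A": ["p1", "p2"], "C": ["p3"]}

    def test_empty_orthogroup_rejected(self, tmp_path):
        p = write_og_table(tmp_path, "Orthogroup\tA\tB\nOG0000001\t\t\n")
        with pytest.raises(FormatError, match="empty orthogroup"):
            parse_orthogroups(p)

    def test_protein_in_two_ogs_rejected(self, tmp_path):
        p = write_og_table(
            tmp_path, "Orthogroup\tA\nOG0000001\tp1\nOG0000002\tp1\n"
        )
        with pytest.raises(FormatError, match="p1"):
            parse_orthogroups(p)

    def test_missing_corner_header_rejected(self, tmp_path):
        p = write_og_table(tmp_path, "OGID\tA\nOG1\tp1\n")
        with pytest.raises(FormatError, match="Orthogroup"):
            parse_orthogroups(p)

    def test_unassigned_fraction(self):
        gs = GenomeSet(
            [
                GenomeEntry(
                    "A",
                    proteins=[ProteinRecord(f"p{i}", "A", "MKLV") for i in range(4)],
                )
            ]
        )
        ogs = [Orthogroup("OG1", {"A": ["p0", "p1", "p2"]})]
        stats = assignment_stats(ogs, gs)
        assert stats["n_assigned"] == 3
        assert stats["n_unassigned"] == 1
        assert stats["pct_assigned"] == pytest.approx(75.0)


def random_og_tables(n_tables, rng):
    """Random orthogroup tables over small genome/family universes."""
    for _ in range(n_tables):
        n_genomes = int(rng.integers(2, 6))
        genomes = [f"G{i}" for i in range(n_genomes)]
        families = {g: f"F{int(rng.integers(0, 3))}" for g in genomes}
        ogs = []
        pid = 0
        for k in range(int(rng.integers(1, 15))):
            members = {}
            for g in genomes:
                c = int(rng.integers(0, 4))
                if c:
                    members[g] = [f"p{pid + i}" for i in range(c)]
                    pid += c
            if members:
                ogs.append(Orthogroup(f"OG{k}", members))
        if ogs:
            yield ogs, genomes, families


class TestCoreAndSharing:
    def test_single_copy_selection(self):
        ogs = [
            Orthogroup("OG1", {"A": ["p1"], "B": ["p2"]}),
            Orthogroup("OG2", {"A": ["p3", "p4"], "B": ["p5"]}),
            Orthogroup("OG3", {"A": ["p6"]}),
        ]
        assert single_copy_core(ogs, ["A", "B"]) == ["OG1"]

    def test_single_copy_and_sharing_match_brute_force(self):
        rng = np.random.default_rng(42)
        n = 0
        for ogs, genomes, families in random_og_tables(120, rng):
            assert single_copy_core(ogs, genomes) == single_copy_oracle(ogs, genomes)
            assert og_sharing_stats(ogs, families) == sharing_oracle(ogs, families)
            n += 1
        assert n >= 100

    def test_sharing_examples(self):
        fam = {"A": "F1", "B": "F1", "C": "F2"}
        ogs = [
            Orthogroup("u", {"A": ["p1"], "B": ["p2"], "C": ["p3"]}),  # universal
            Orthogroup("s", {"A": ["p4"]}),  # species-specific
            Orthogroup("fx", {"A": ["p5"], "B": ["p6"]}),  # family-exclusive
            Orthogroup("px", {"B": ["p7"], "C": ["p8"]}),  # spans the pair
        ]
        stats = og_sharing_stats(ogs, fam)
        assert stats["universal"] == 1
        assert stats["species_specific"] == 1
        assert stats["family_exclusive"] == {"F1": 1, "F2": 0}
        # both the universal OG and "px" span exactly the two families
        assert stats["family_pair_exclusive"] == {("F1", "F2"): 2}


class TestSupermatrix:
    def test_lengths_and_partitions(self):
        alignments = {
            "OG2": {"A": "MKLVQW", "B": "MKLVQW"},
            "OG1": {"A": "MKCV", "B": "MKCV"},
        }
        sm, parts = concatenate_supermatrix(alignments)
        assert len(sm["A"]) == 10
        assert parts.to_dict("records") == [
            {"og_id": "OG1", "start": 1, "end": 4},
            {"og_id": "OG2", "start": 5, "end": 10},
        ]

    def test_single_alignment_identity(self):
        sm, parts = concatenate_supermatrix({"OG1": {"A": "MKCV"}})
        assert sm == {"A": "MKCV"}

    def test_input_order_irrelevant(self):
        a = {"OG1": {"A": "MK"}, "OG2": {"A": "CV"}}
        b = {"OG2": {"A": "CV"}, "OG1": {"A": "MK"}}
        sm_a, parts_a = concatenate_supermatrix(a)
        sm_b, parts_b = concatenate_supermatrix(b)
        assert sm_a == sm_b
        assert parts_a.equals(parts_b)

    def test_missing_genome_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            concatenate_supermatrix({"OG1": {"A": "MK", "B": "MK"}, "OG2": {"A": "CV"}})


class TestPresenceAndPrevalence:
    def test_copy_numbers(self):
        ogs = [Orthogroup("OG7", {"A": ["p1", "p2"], "B": ["p3"]})]
        mat = presence_matrix(ogs, {"ppcA": "OG7"}, ["A", "B", "C"])
        assert mat.loc["A", "ppcA"] == 2
        assert mat.loc["B", "ppcA"] == 1
        assert mat.loc["C", "ppcA"] == 0

    def test_prevalence_and_mean_copies(self):
        mat = pd.DataFrame(
            {"m": [1, 2, 1, 0], "z": [0, 0, 0, 0]}, index=["A", "B", "C", "D"]
        )
        fam = {g: "F" for g in mat.index}
        out = marker_prevalence_and_copies(mat, fam).set_index("marker_id")
        assert out.loc["m", "prevalence_pct"] == pytest.approx(75.0)
        assert out.loc["m", "mean_copies"] == pytest.approx(1.0)
        assert out.loc["z", "prevalence_pct"] == 0.0
        assert out.loc["z", "mean_copies"] == 0.0


def _two_genome_set(seq_a, seq_b):
    return GenomeSet(
        [
            GenomeEntry("A", proteins=[ProteinRecord("pa", "A", seq_a)]),
            GenomeEntry("B", proteins=[ProteinRecord("pb", "B", seq_b)]),
        ]
    )


SEQ = "MKVLCAACHGGTRPLWEELVMKVLDERTNAPQRSILVMKVLCAACHGGTRPLWEELV"


class TestRBHInference:
    def test_identical_proteins_form_one_og(self):
        gs = _two_genome_set(SEQ, SEQ)
        ogs = infer_orthogroups_rbh(gs)
        assert len(ogs) == 1
        assert sorted(ogs[0].protein_ids()) == ["pa", "pb"]

    def test_unrelated_proteins_stay_unassigned(self):
        gs = _two_genome_set(SEQ, "PPPPGGGGPPPPGGGGPPPPGGGGPPPPGGGG")
        assert infer_orthogroups_rbh(gs) == []

    def test_inferred_families_match_planted(self, study, inferred_ogs):
        """Sequence-only clustering must re-derive the planted gene families
        (singleton families excepted: they have no partner to link to)."""
        _, _, truth = study
        planted = {}
        for pid, og in truth.true_og.items():
            planted.setdefault(og, set()).add(pid)
        expected = {frozenset(v) for v in planted.values() if len(v) > 1}
        inferred = {frozenset(og.protein_ids()) for og in inferred_ogs}
        assert inferred == expected


class TestMarkerMapping:
    def test_membership_rule_and_threshold(self):
        gs = _two_genome_set(SEQ, SEQ)
        ogs = infer_orthogroups_rbh(gs)
        markers = pd.DataFrame(
            [
                {
                    "marker_id": "direct",
                    "reference_protein_id": "pa",
                    "source_model": "G. sulfurreducens PCA",
                    "category": "other",
                },
                {
                    "marker_id": "by_seq",
                    "reference_protein_id": "REF_x",
                    "source_model": "S. oneidensis MR-1",
                    "category": "other",
                },
                {
                    "marker_id": "too_far",
                    "reference_protein_id": "REF_y",
                    "source_model": "S. oneidensis MR-1",
                    "category": "other",
                },
            ]
        )
        seqs = {"REF_x": SEQ[:50], "REF_y": "WWWWHHHHWWWWHHHHWWWWHHHHWWWWHHHH"}
        mapping = map_markers_to_ogs(markers, ogs, gs, seqs)
        og_id = ogs[0].og_id
        assert mapping["direct"] == og_id
        assert mapping["by_seq"] == og_id
        assert mapping["too_far"] is None
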