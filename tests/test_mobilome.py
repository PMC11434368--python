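import numpy as np
import pandas as pd
import pytest

from hemenet.io_formats import GenomeEntry, GenomeSet
from hemenet.mobilome import (
    ELEMENT_METRICS,
    build_mobilome_profiles,
    family_mobilome_summary,
    filter_is_hits,
)
from oracles import is_filter_oracle


def is_table(rows):
    return pd.DataFrame(rows, columns=["genome_id", "is_name", "family", "aln_length", "evalue"])


class TestFilterISHits:
    @pytest.mark.parametrize(
        "aln_length,evalue,kept",
        [
            (700, 1e-9, False),  # boundary: strictly over 700 required
            (701, 1e-7, True),
            (701, 1e-6, True),  # e-value boundary is inclusive
            (701, 2e-6, False),
            (5000, 1e-30, True),
        ],
    )
    def test_boundaries(self, aln_length, evalue, kept):
        df = is_table([{"genome_id": "G1", "is_name": "IS1", "family": "IS3",
                        "aln_length": aln_length, "evalue": evalue}])
        filtered, counts = filter_is_hits(df)
        assert (len(filtered) == 1) is kept
        assert counts.get("G1", 0) == (1 if kept else 0)

    def test_negative_length_rejected_with_warning(self, caplog):
        df = is_table([{"genome_id": "G1", "is_name": "IS1", "family": "IS3",
                        "aln_length": -5, "evalue": 1e-9}])
        with caplog.at_level("WARNING", logger="hemenet"):
            filtered, counts = filter_is_hits(df)
        assert len(filtered) == 0
        assert "negative" in caplog.text

    def test_empty_table_all_zero(self):
        filtered, counts = filter_is_hits(is_table([]))
        assert len(filtered) == 0
        assert counts.empty

    def test_matches_row_scan_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            rows = [
                {
                    "genome_id": f"G{int(rng.integers(0, 4))}",
                    "is_name": "IS",
                    "family": "ISfam",
                    "aln_length": int(rng.integers(400, 1200)),
                    "evalue": float(10.0 ** -rng.uniform(0, 12)),
                }
                for _ in range(int(rng.integers(0, 30)))
            ]
            _, counts = filter_is_hits(is_table(rows))
            assert counts.to_dict() == is_filter_oracle(rows)


def _genome_set():
    return GenomeSet(
        [
            GenomeEntry("G1", family="F1", subclade="I", genome_length_bp=4_000_000),
            GenomeEntry("G2", family="F1", subclade="II", genome_length_bp=2_000_000),
        ]
    )


def _tables():
    prophages = pd.DataFrame(
        [
            *({"genome_id": "G1", "region_id": f"r{i}", "completeness": c}
              for i, c in enumerate(["intact"] * 2 + ["questionable"] + ["incomplete"] * 5)),
        ]
    )
    ices = pd.DataFrame(
        [
            {"genome_id": "G1", "system_type": "typeF"},
            {"genome_id": "G1", "system_type": "typeF"},  # duplicate row, one type
            {"genome_id": "G1", "system_type": "typeT"},
        ]
    )
    return {"prophages": prophages, "ices": ices}


class TestBuildProfiles:
    def test_totals_density_and_missing_genome_zeros(self):
        profiles = build_mobilome_profiles(_tables(), _genome_set())
        g1 = profiles.loc["G1"]
        assert g1["prophages_total"] == 8
        assert g1["prophages_intact"] == 2
        assert g1["prophage_density"] == pytest.approx(2.0)  # 8 / 4 Mbp
        assert g1["ice_types"] == 2  # distinct system types
        g2 = profiles.loc["G2"]
        assert g2["prophages_total"] == 0
        assert g2["crispr_arrays"] == 0

    def test_intact_only_density_mode(self):
        profiles = build_mobilome_profiles(_tables(), _genome_set(), density_mode="intact")
        assert profiles.loc["G1", "prophage_density"] == pytest.approx(0.5)

    def test_unknown_genome_in_table_rejected(self):
        tables = _tables()
        tables["crispr"] = pd.DataFrame([{"genome_id": "GX", "array_id": "a1"}])
        with pytest.raises(ValueError, match="GX"):
            build_mobilome_profiles(tables, _genome_set())

    def test_unknown_genome_length_rejected(self):
        gs = GenomeSet([GenomeEntry("G1", family="F1")])
        with pytest.raises(ValueError, match="genome_length_bp"):
            build_mobilome_profiles({}, gs)


class TestFamilySummary:
    def test_prevalence_and_mean(self):
        profiles = pd.DataFrame(
            {
                "prophages_total": [0, 0, 0, 0],
                "crispr_arrays": [0, 0, 0, 0],
                "integrons_complete": [0, 0, 0, 0],
                "is_count": [0, 0, 2, 5],
                "ice_types": [0, 0, 0, 0],
                "prophage_density": [0.0, 0.0, 0.0, 0.0],
            },
            index=["G1", "G2", "G3", "G4"],
        )
        fam = {g: "F" for g in profiles.index}
        out = family_mobilome_summary(profiles, fam).set_index("group")
        assert out.loc["F", "prevalence_is_count"] == pytest.approx(0.5)
        assert out.loc["F", "mean_is_count"] == pytest.approx(1.75)
        assert out.loc["F", "prevalence_prophages_total"] == 0.0

    def test_pooling_two_disjoint_sets_is_genome_weighted(self):
        """Summaries are linear folds: pooling split summaries with genome
        weights equals summarizing the concatenation."""
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame(
            {
                c: rng.integers(0, 5, size=6)
                for c in ["prophages_total", "crispr_arrays", "integrons_complete",
                          "is_count", "ice_types"]
            },
            index=[f"G{i}" for i in range(6)],
        ).assign(prophage_density=rng.uniform(0, 2, size=6))
        fam = {g: "F" for g in profiles.index}
        whole = family_mobilome_summary(profiles, fam).set_index("group")
        a = family_mobilome_summary(profiles.iloc[:2], fam).set_index("group")
        b = family_mobilome_summary(profiles.iloc[2:], fam).set_index("group")
        for metric in ELEMENT_METRICS:
            pooled = (2 * a.loc["F", f"mean_{metric}"] + 4 * b.loc["F", f"mean_{metric}"]) / 6
            assert whole.loc["F", f"mean_{metric}"] == pytest.approx(pooled)

    def test_summary_equals_truth_on_synthetic_study(self, study, genome_set):
        study_dir, _, truth = study
        from hemenet.io_formats import read_table
        from hemenet.mobilome import ELEMENT_TABLES

        tables = {
            name: read_table(study_dir / "mobilome" / f"{name}.tsv", name)
            for name in ELEMENT_TABLES
        }
        profiles = build_mobilome_profiles(tables, genome_set)
        for col in truth.true_mobilome.columns:
            assert (
                profiles[col].sort_index() == truth.true_mobilome[col].sort_index()
            ).all(), col
        summary = family_mobilome_summary(profiles, truth.family_map).set_index("group")
        for fam in set(truth.family_map.values()):
            gids = [g for g, f in truth.family_map.items() if f == fam]
            expected = truth.true_mobilome.loc[gids, "prophages_total"].mean()
            assert summary.loc[fam, "mean_prophages_total"] == pytest.approx(expected)
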