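import numpy as np
import pandas as pd
import pytest
from scipy.linalg import subspace_angles
from sklearn.decomposition import PCA as SkPCA

from hemenet.genome_stats import (
    FEATURE_COLUMNS,
    assemble_feature_table,
    genome_size_gc,
    qc_filter,
    run_pca,
)
from hemenet.heme_scan import HemeAnnotation
from hemenet.io_formats import GenomeEntry, GenomeSet, ProteinRecord
from hemenet.synthetic import generate_low_rank_features


def checkm(rows):
    return pd.DataFrame(rows, columns=["genome_id", "completeness", "contamination"])


class TestQCFilter:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (98.0, 1.0, False),  # completeness must be strictly > 98
            (99.5, 4.99, True),
            (99.5, 5.0, False),  # contamination must be strictly < 5
            (98.01, 0.0, True),
        ],
    )
    def test_boundaries(self, completeness, contamination, kept):
        table = checkm([{"genome_id": "G1", "completeness": completeness,
                         "contamination": contamination}])
        kept_ids, dropped = qc_filter(table)
        assert (kept_ids == ["G1"]) is kept
        assert (len(dropped) == 0) is kept

    def test_matches_row_scan_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            rows = [
                {
                    "genome_id": f"G{i}",
                    "completeness": float(rng.uniform(95, 100)),
                    "contamination": float(rng.uniform(0, 8)),
                }
                for i in range(int(rng.integers(1, 10)))
            ]
            kept_ids, dropped = qc_filter(checkm(rows))
            expected = [
                r["genome_id"]
                for r in rows
                if r["completeness"] > 98.0 and r["contamination"] < 5.0
            ]
            assert kept_ids == expected
            assert len(kept_ids) + len(dropped) == len(rows)

    def test_missing_values_rejected(self):
        table = checkm([{"genome_id": "G1", "completeness": np.nan, "contamination": 1.0}])
        with pytest.raises(ValueError, match="missing"):
            qc_filter(table)


class TestGenomeSizeGC:
    @pytest.mark.parametrize(
        "seq,length,gc",
        [("GGCC", 4, 1.0), ("ATAT", 4, 0.0), ("ATGCN", 5, 0.5)],
    )
    def test_examples(self, seq, length, gc):
        got = genome_size_gc([("c1", "", seq)])
        assert got == (length, pytest.approx(gc))

    def test_multiple_contigs_summed(self):
        got = genome_size_gc([("c1", "", "GGCC"), ("c2", "", "ATAT")])
        assert got == (8, pytest.approx(0.5))

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            genome_size_gc([("c1", "", "NNNN")])


def _feature_inputs():
    gs = GenomeSet(
        [
            GenomeEntry(
                "G1",
                family="F",
                genome_length_bp=4_000_000,
                gc_fraction=0.6,
                proteins=[ProteinRecord("p1", "G1", "MK")],
            )
        ]
    )
    presence = pd.DataFrame(
        {"cbc1": [2], "cbc2": [0], "cbc3": [3], "ppcA": [4], "ribA": [1]}, index=["G1"]
    )
    markers = pd.DataFrame(
        {
            "marker_id": ["cbc1", "cbc2", "cbc3", "ppcA", "ribA"],
            "reference_protein_id": ["r1", "r2", "r3", "r4", "r5"],
            "source_model": ["G. sulfurreducens PCA"] * 5,
            "category": [
                "cytochrome bc complex",
                "cytochrome bc complex",
                "cytochrome bc complex",
                "periplasmic",
                "riboflavin biosynthesis",
            ],
        }
    )
    annotations = [HemeAnnotation(f"h{i}", "G1", 1, 0) for i in range(56)]
    profiles = pd.DataFrame(
        {
            "prophages_total": [3],
            "crispr_arrays": [2],
            "integrons_complete": [1],
            "is_count": [4],
            "ice_types": [2],
            "prophage_density": [0.75],
        },
        index=["G1"],
    )
    return gs, presence, markers, annotations, profiles


class TestAssembleFeatureTable:
    def test_sums_and_density(self):
        gs, presence, markers, annotations, profiles = _feature_inputs()
        table = assemble_feature_table(gs, presence, markers, annotations, profiles)
        row = table.loc["G1"]
        assert list(table.columns) == FEATURE_COLUMNS
        assert row["cbc_copies_sum"] == 5.0  # 2 + 0 + 3
        assert row["total_cyt_per_mbp"] == pytest.approx(14.0)  # 56 / 4 Mbp
        assert row["ppcA_copies"] == 4.0
        assert row["rib_copies_sum"] == 1.0
        assert row["ompJ_copies"] == 0.0  # marker absent from the matrix
        assert row["gc_percent"] == pytest.approx(60.0)

    def test_missing_genome_named_in_error(self):
        gs, presence, markers, annotations, profiles = _feature_inputs()
        with pytest.raises(ValueError, match="G1"):
            assemble_feature_table(
                gs, presence, markers, annotations, profiles.drop(index="G1")
            )


class TestRunPCA:
    def test_two_perfectly_correlated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        result = run_pca(df)
        assert result.variance_explained[0] == pytest.approx(100.0)

    def test_variance_sums_to_100_and_reconstructs(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((40, 13)), columns=FEATURE_COLUMNS)
        result = run_pca(df)
        assert result.variance_explained.sum() == pytest.approx(100.0, abs=1e-9)
        assert all(a >= b - 1e-12 for a, b in zip(result.variance_explained,
                                                  result.variance_explained[1:]))
        Z = (df - df.mean()) / df.std(ddof=1)
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        assert np.max(np.abs(recon - Z.to_numpy())) < 1e-8
        # component scores are mutually orthogonal
        S = result.scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_row_permutation_only_permutes_scores(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.standard_normal((20, 5)),
            columns=list("abcde"),
            index=[f"G{i}" for i in range(20)],
        )
        perm = rng.permutation(20)
        r1 = run_pca(df)
        r2 = run_pca(df.iloc[perm])
        assert np.allclose(r1.loadings.to_numpy(), r2.loadings.to_numpy())
        assert np.allclose(r1.variance_explained, r2.variance_explained)
        assert np.allclose(
            r1.scores.loc[df.index.to_numpy()[perm]].to_numpy(), r2.scores.to_numpy()
        )

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((50, 8)))
        result = run_pca(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        sk = SkPCA().fit(Z.to_numpy())
        assert np.allclose(
            result.variance_explained / 100.0, sk.explained_variance_ratio_, atol=1e-10
        )
        assert np.allclose(
            np.abs(result.loadings.to_numpy().T), np.abs(sk.components_), atol=1e-8
        )

    def test_recovers_planted_factor_subspace(self):
        # covariance PCA: the generator plants the factors on the raw scale
        df, W = generate_low_rank_features(n_genomes=60, n_latent=2, noise_sd=0.05, seed=4)
        result = run_pca(df, standardize=False)
        angles = subspace_angles(result.loadings.to_numpy()[:, :2], W)
        assert np.degrees(angles).max() < 5.0

    def test_constant_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.standard_normal(10), "b": np.ones(10),
                           "c": rng.standard_normal(10)})
        with caplog.at_level("WARNING", logger="hemenet"):
            result = run_pca(df)
        assert result.dropped_columns == ["b"]
        assert list(result.loadings.index) == ["a", "c"]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            run_pca(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_sign_convention(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((25, 4)))
        L = run_pca(df).loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0
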