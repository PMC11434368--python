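"""End-to-end orchestration: QC -> orthogroups -> heme scan -> marker profile
-> similarity network -> mobilome -> feature table -> PCA.

Each stage writes its TSVs and is recorded in a JSON manifest (stage name,
parameters, sha256 of every output), so two runs with the same inputs,
config and seed produce identical manifests.  All stage randomness derives
from the single config seed via stable per-stage hashing, so adding or
reordering stages cannot silently shift another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import genome_stats, heme_scan, mobilome, orthology, ssn
from .io_formats import (
    build_genome_set,
    logger,
    read_fasta,
    read_table,
    write_graph,
)

DEFAULT_THRESHOLDS = {
    "evalue_max": 1e-40,
    "min_identity": 0.30,
    "min_coverage": 0.70,
    "resolution": 1.0,
    "qc_min_completeness": 98.0,
    "qc_max_contamination": 5.0,
    "is_length_min": 700,
    "is_evalue_max": 1e-6,
}

DEFAULT_POLICIES = {
    "motif_policy": "nonoverlap_greedy",
    "coverage_mode": "shorter",
    "standardize": True,
    "density_mode": "total",
    "cytochrome_scope": "all",
}

STAGES = ("qc", "orthogroups", "scan_hemes", "profile", "ssn", "mobilome", "features", "pca")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def run_all(config: Mapping, out_dir: str | Path) -> dict:
    """Run every stage on the inputs named in ``config`` and return the manifest.

    Config keys: ``inputs`` (proteome_dir, genome_dir, orthogroups,
    localization, markers, marker_fasta, mobilome_dir, checkm, metadata),
    ``thresholds``/``policies`` overriding the defaults above, and ``seed``.
    Any stage failure aborts with the stage name and cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = dict(config.get("inputs", {}))
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    policies = {**DEFAULT_POLICIES, **config.get("policies", {})}
    seed = int(config.get("seed", 0))

    for key in ("proteome_dir", "checkm", "metadata"):
        if key not in inputs or not Path(inputs[key]).exists():
            raise FileNotFoundError(f"missing required input path: {key} = {inputs.get(key)}")

    manifest: dict = {"seed": seed, "stages": []}

    def record(stage: str, params: Mapping, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "parameters": {k: params[k] for k in sorted(params)},
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            }
        )

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- qc -------------------------------------------------------------------
    def stage_qc():
        checkm = read_table(inputs["checkm"], "checkm")
        kept, dropped = genome_stats.qc_filter(
            checkm,
            thresholds["qc_min_completeness"],
            thresholds["qc_max_contamination"],
        )
        p1 = _write_tsv(pd.DataFrame({"genome_id": kept}), out / "qc_kept.tsv")
        p2 = _write_tsv(dropped, out / "qc_dropped.tsv")
        record(
            "qc",
            {
                "min_completeness": thresholds["qc_min_completeness"],
                "max_contamination": thresholds["qc_max_contamination"],
            },
            [p1, p2],
        )
        return kept

    kept = run_stage("qc", stage_qc)

    # -- genome set -------------------------------------------------------------
    metadata = read_table(inputs["metadata"], "metadata")
    proteome_dir = Path(inputs["proteome_dir"])
    proteomes = {p.stem: p for p in sorted(proteome_dir.glob("*.faa")) if p.stem in set(kept)}
    genome_paths = None
    if inputs.get("genome_dir"):
        genome_paths = {
            p.stem: p for p in sorted(Path(inputs["genome_dir"]).glob("*.fna")) if p.stem in set(kept)
        }
    genome_set = build_genome_set(proteomes, metadata, genome_paths)
    logger.info("genome set: %d genomes, %d proteins", len(genome_set),
                sum(1 for _ in genome_set.iter_proteins()))

    # -- orthogroups -------------------------------------------------------------
    def stage_orthogroups():
        if inputs.get("orthogroups"):
            ogs = orthology.parse_orthogroups(inputs["orthogroups"])
            source = "table"
        else:
            ogs = orthology.infer_orthogroups_rbh(
                genome_set, thresholds["min_identity"], thresholds["min_coverage"]
            )
            source = "rbh"
        stats = orthology.assignment_stats(ogs, genome_set)
        fam_map = genome_set.family_map()
        sharing = orthology.og_sharing_stats(ogs, fam_map)
        payload = {
            "assignment": stats,
            "sharing": {
                "universal": sharing["universal"],
                "species_specific": sharing["species_specific"],
                "family_exclusive": sharing["family_exclusive"],
                "family_pair_exclusive": {
                    " & ".join(k): v for k, v in sharing["family_pair_exclusive"].items()
                },
            },
            "single_copy_core": orthology.single_copy_core(ogs, genome_set.genome_ids),
        }
        p = out / "orthogroup_stats.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True))
        record("orthogroups", {"source": source}, [p])
        return ogs

    ogs = run_stage("orthogroups", stage_orthogroups)

    # -- heme scan ----------------------------------------------------------------
    def stage_scan():
        loc = read_table(inputs["localization"], "localization") if inputs.get("localization") else None
        annotations = heme_scan.annotate_proteome(genome_set, loc, policies["motif_policy"])
        p1 = _write_tsv(heme_scan.annotations_frame(annotations), out / "heme_annotations.tsv")
        p2 = _write_tsv(
            heme_scan.family_heme_summary(annotations, genome_set), out / "heme_family_summary.tsv"
        )
        p3 = _write_tsv(
            heme_scan.hits_frame(genome_set, policies["motif_policy"]), out / "heme_hits.tsv"
        )
        record("scan_hemes", {"policy": policies["motif_policy"]}, [p1, p2, p3])
        return annotations

    annotations = run_stage("scan_hemes", stage_scan)

    # -- marker profile --------------------------------------------------------------
    def stage_profile():
        markers = read_table(inputs["markers"], "markers")
        marker_seqs = None
        if inputs.get("marker_fasta"):
            marker_seqs = {
                rid: seq for rid, _, seq in read_fasta(inputs["marker_fasta"], "protein")
            }
        mapping = orthology.map_markers_to_ogs(
            markers, ogs, genome_set, marker_seqs,
            thresholds["min_identity"], thresholds["min_coverage"],
        )
        matrix = orthology.presence_matrix(ogs, mapping, genome_set.genome_ids)
        prevalence = orthology.marker_prevalence_and_copies(matrix, genome_set.family_map())
        p1 = _write_tsv(matrix.rename_axis("genome_id"), out / "marker_copy_matrix.tsv", index=True)
        p2 = _write_tsv(prevalence, out / "marker_prevalence.tsv")
        record("profile", {"n_markers": len(markers)}, [p1, p2])
        return markers, matrix

    markers, matrix = run_stage("profile", stage_profile)

    # -- SSN ----------------------------------------------------------------------------
    def stage_ssn():
        selected = ssn.select_network_sequences(ogs, annotations)
        seqs = {p.protein_id: p.sequence for p in genome_set.iter_proteins() if p.protein_id in set(selected)}
        fam_map = genome_set.family_map()
        og_of = {pid: og.og_id for og in ogs for pid in og.protein_ids()}
        genome_of = {p.protein_id: p.genome_id for p in genome_set.iter_proteins()}
        attrs = {
            pid: {
                "genome_id": genome_of[pid],
                "family": fam_map.get(genome_of[pid], ""),
                "og_id": og_of.get(pid, ""),
            }
            for pid in seqs
        }
        graph = ssn.build_ssn(
            seqs,
            attrs,
            evalue_max=thresholds["evalue_max"],
            min_identity=thresholds["min_identity"],
            min_coverage=thresholds["min_coverage"],
            coverage_mode=policies["coverage_mode"],
        )
        ssn.partition_ssn(graph, thresholds["resolution"], derive_seed(seed, "ssn"))
        totals, per_comm = ssn.community_summary(graph)
        p1 = out / "ssn.graphml"
        write_graph(graph, p1, "graphml")
        p2 = out / "ssn_edges.tsv"
        write_graph(graph, p2, "edge_tsv")
        p3 = _write_tsv(per_comm, out / "ssn_communities.tsv")
        p4 = out / "ssn_summary.json"
        p4.write_text(json.dumps(totals, indent=2, sort_keys=True))
        record(
            "ssn",
            {
                "evalue_max": thresholds["evalue_max"],
                "min_identity": thresholds["min_identity"],
                "min_coverage": thresholds["min_coverage"],
                "resolution": thresholds["resolution"],
                "seed": derive_seed(seed, "ssn"),
            },
            [p1, p2, p3, p4],
        )
        return graph

    graph = run_stage("ssn", stage_ssn)

    # -- mobilome --------------------------------------------------------------------------
    def stage_mobilome():
        tables = {}
        mob_dir = inputs.get("mobilome_dir")
        if mob_dir:
            for name in mobilome.ELEMENT_TABLES:
                path = Path(mob_dir) / f"{name}.tsv"
                if path.exists():
                    tables[name] = read_table(path, name)
        profiles = mobilome.build_mobilome_profiles(
            tables, genome_set, policies["density_mode"]
        )
        summary = mobilome.family_mobilome_summary(
            profiles, genome_set.family_map(), genome_set.subclade_map()
        )
        p1 = _write_tsv(profiles, out / "mobilome_profiles.tsv", index=True)
        p2 = _write_tsv(summary, out / "mobilome_summary.tsv")
        record("mobilome", {"density_mode": policies["density_mode"]}, [p1, p2])
        return profiles

    profiles = run_stage("mobilome", stage_mobilome)

    # -- features + PCA ----------------------------------------------------------------------
    def stage_features():
        table = genome_stats.assemble_feature_table(
            genome_set, matrix, markers, annotations, profiles,
            policies["cytochrome_scope"],
        )
        p = _write_tsv(table, out / "features.tsv", index=True)
        record("features", {"cytochrome_scope": policies["cytochrome_scope"]}, [p])
        return table

    features = run_stage("features", stage_features)

    def stage_pca():
        result = genome_stats.run_pca(features, standardize=policies["standardize"])
        p1 = _write_tsv(result.loadings.rename_axis("variable"), out / "pca_loadings.tsv", index=True)
        p2 = _write_tsv(result.scores.rename_axis("genome_id"), out / "pca_scores.tsv", index=True)
        var = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(result.variance_explained))],
                "variance_explained_pct": result.variance_explained,
            }
        )
        p3 = _write_tsv(var, out / "pca_variance.tsv")
        record("pca", {"standardize": policies["standardize"]}, [p1, p2, p3])
        return result

    run_stage("pca", stage_pca)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def study_config(study_dir: str | Path, seed: int = 0, **overrides) -> dict:
    """Pipeline config pointing at a directory laid out by ``generate_study``."""
    study = Path(study_dir)
    cfg = {
        "seed": seed,
        "inputs": {
            "proteome_dir": str(study / "proteomes"),
            "genome_dir": str(study / "genomes"),
            "orthogroups": str(study / "orthogroups.tsv"),
            "localization": str(study / "localization.tsv"),
            "markers": str(study / "markers.tsv"),
            "marker_fasta": str(study / "markers.faa"),
            "mobilome_dir": str(study / "mobilome"),
            "checkm": str(study / "checkm.tsv"),
            "metadata": str(study / "metadata.tsv"),
        },
    }
    cfg.update(overrides)
    return cfg
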