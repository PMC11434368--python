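"""Session-scoped fixtures: one synthetic study shared by the whole suite.

The expensive artifacts (the study itself, the inferred orthogroups, the
similarity network, one full pipeline run) are computed once per session.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from hemenet import pipeline
from hemenet.heme_scan import annotate_proteome
from hemenet.io_formats import build_genome_set, read_fasta, read_table
from hemenet.orthology import infer_orthogroups_rbh, parse_orthogroups
from hemenet.ssn import build_ssn, partition_ssn, select_network_sequences
from hemenet.synthetic import SynthConfig, generate_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """(study_dir, paths, truth) for the default synthetic study."""
    out = tmp_path_factory.mktemp("study")
    paths, truth = generate_study(SynthConfig(seed=STUDY_SEED), out)
    return out, paths, truth


@pytest.fixture(scope="session")
def genome_set(study):
    study_dir, _, _ = study
    metadata = read_table(study_dir / "metadata.tsv", "metadata")
    proteomes = {p.stem: p for p in sorted((study_dir / "proteomes").glob("*.faa"))}
    genomes = {p.stem: p for p in sorted((study_dir / "genomes").glob("*.fna"))}
    return build_genome_set(proteomes, metadata, genomes)


@pytest.fixture(scope="session")
def annotations(study, genome_set):
    study_dir, _, _ = study
    loc = read_table(study_dir / "localization.tsv", "localization")
    return annotate_proteome(genome_set, loc)


@pytest.fixture(scope="session")
def parsed_ogs(study):
    study_dir, _, _ = study
    return parse_orthogroups(study_dir / "orthogroups.tsv")


@pytest.fixture(scope="session")
def inferred_ogs(genome_set):
    """Orthogroups inferred from sequences alone (slow: all-vs-all alignment)."""
    return infer_orthogroups_rbh(genome_set)


@pytest.fixture(scope="session")
def marker_inputs(study):
    study_dir, _, _ = study
    markers = read_table(study_dir / "markers.tsv", "markers")
    marker_seqs = {r: s for r, _, s in read_fasta(study_dir / "markers.faa")}
    return markers, marker_seqs


@pytest.fixture(scope="session")
def ssn_graph(genome_set, parsed_ogs, annotations):
    selected = set(select_network_sequences(parsed_ogs, annotations))
    seqs = {p.protein_id: p.sequence for p in genome_set.iter_proteins() if p.protein_id in selected}
    fam = genome_set.family_map()
    genome_of = {p.protein_id: p.genome_id for p in genome_set.iter_proteins()}
    attrs = {pid: {"family": fam[genome_of[pid]], "genome_id": genome_of[pid]} for pid in seqs}
    graph = build_ssn(seqs, attrs)
    return partition_ssn(graph, resolution=1.0, seed=0)


@pytest.fixture(scope="session")
def pipeline_run(study, tmp_path_factory):
    study_dir, _, _ = study
    out = tmp_path_factory.mktemp("pipeline_out")
    manifest = pipeline.run_all(pipeline.study_config(study_dir, seed=7), out)
    return out, manifest
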