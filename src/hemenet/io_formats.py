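"""Readers and writers for every external format the pipeline touches.

All tabular inputs are TSV with a header row; a single schema registry
(:data:`SCHEMAS`) defines required and optional columns per table kind so
that parsing errors surface at the boundary rather than deep in a stage.
Genome ids are the join key everywhere; family/subclade labels live only in
the metadata table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("hemenet")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
NUCLEOTIDES = set("ACGT")

#: PSORTb subcellular localization sites for Gram-negative bacteria, plus the
#: "unknown" bucket used when the predictor abstains or the protein is absent
#: from the localization table.
LOCALIZATION_CATEGORIES = frozenset(
    {
        "cytoplasmic",
        "cytoplasmic membrane",
        "periplasmic",
        "outer membrane",
        "extracellular",
        "unknown",
    }
)

INTEGRON_KINDS = frozenset({"complete", "In0", "CALIN"})
PROPHAGE_COMPLETENESS = frozenset({"intact", "questionable", "incomplete"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence tied to its source genome."""

    protein_id: str
    genome_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id or any(c.isspace() for c in self.protein_id):
            raise ValueError(f"invalid protein_id {self.protein_id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.protein_id}")


@dataclass
class GenomeEntry:
    """A genome with its taxonomy labels and proteome."""

    genome_id: str
    family: str = ""
    subclade: str = ""
    isolation_source: str = ""
    proteins: list[ProteinRecord] = field(default_factory=list)
    genome_length_bp: int = 0
    gc_fraction: float | None = None


@dataclass
class GenomeSet:
    """The universe every pipeline stage indexes into."""

    genomes: list[GenomeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate genome ids: {dup}")
        for g in self.genomes:
            for p in g.proteins:
                if p.genome_id != g.genome_id:
                    raise ValueError(
                        f"protein {p.protein_id} claims genome {p.genome_id} "
                        f"but is attached to {g.genome_id}"
                    )

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def family_map(self) -> dict[str, str]:
        return {g.genome_id: g.family for g in self.genomes}

    def subclade_map(self) -> dict[str, str]:
        return {g.genome_id: g.subclade for g in self.genomes}

    def protein_index(self) -> dict[str, ProteinRecord]:
        idx: dict[str, ProteinRecord] = {}
        for g in self.genomes:
            for p in g.proteins:
                if p.protein_id in idx:
                    raise ValueError(f"duplicate protein id {p.protein_id}")
                idx[p.protein_id] = p
        return idx

    def iter_proteins(self) -> Iterable[ProteinRecord]:
        for g in self.genomes:
            yield from g.proteins

    def __len__(self) -> int:
        return len(self.genomes)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _normalize_sequence(seq: str, alphabet: str) -> tuple[str, int]:
    seq = seq.upper()
    if alphabet == "protein":
        allowed, repl = PROTEIN_ALPHABET, "X"
    elif alphabet == "nucleotide":
        allowed, repl = NUCLEOTIDES, "N"
        allowed = allowed | {"N"}
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    out = []
    replaced = 0
    for c in seq:
        if c in allowed:
            out.append(c)
        else:
            out.append(repl)
            replaced += 1
    return "".join(out), replaced


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[tuple[str, str, str]]:
    """Parse a FASTA file into ``(id, description, sequence)`` tuples.

    Sequences are upper-cased and normalized: for the protein alphabet any
    character outside the 20 amino acids + X becomes X; for nucleotide,
    anything outside ACGT becomes N.  Replacement counts are logged.  Record
    order is preserved.  Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    total_replaced = 0
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal total_replaced
        if header is None:
            return
        parts = header.split(None, 1)
        rid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if rid in seen:
            raise FormatError(f"duplicate id {rid}")
        seq, replaced = _normalize_sequence("".join(chunks), alphabet)
        total_replaced += replaced
        seen.add(rid)
        records.append((rid, desc, seq))

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"empty FASTA header in {path}")
                chunks = []
            elif line.strip():
                if header is None:
                    raise FormatError(f"sequence data before first header in {path}")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FormatError(f"empty FASTA file: {path}")
    if total_replaced:
        logger.warning("%s: replaced %d out-of-alphabet characters", path, total_replaced)
    return records


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, desc, seq in records:
            head = f">{rid} {desc}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV schema registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    optional: Mapping[str, object] = field(default_factory=dict)
    numeric: tuple[str, ...] = ()


SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in [
        TableSchema("localization", ("protein_id", "category")),
        TableSchema(
            "markers",
            ("marker_id", "reference_protein_id", "source_model", "category"),
        ),
        TableSchema(
            "checkm",
            ("genome_id", "completeness", "contamination"),
            numeric=("completeness", "contamination"),
        ),
        TableSchema(
            "metadata",
            ("genome_id", "family"),
            optional={"subclade": "", "isolation_source": ""},
        ),
        TableSchema("features", ("genome_id",)),
        TableSchema("prophages", ("genome_id", "region_id", "completeness")),
        TableSchema("crispr", ("genome_id", "array_id")),
        TableSchema("integrons", ("genome_id", "element_id", "kind")),
        TableSchema(
            "is_hits",
            ("genome_id", "is_name", "family", "aln_length", "evalue"),
            numeric=("aln_length", "evalue"),
        ),
        TableSchema("ices", ("genome_id", "system_type")),
        # orthogroups is a dialect, not a fixed column set; read_table only
        # checks the corner header, parsing lives in hemenet.orthology.
        TableSchema("orthogroups", ("Orthogroup",)),
    ]
}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read a TSV against a named schema from :data:`SCHEMAS`.

    Missing optional columns are filled with the schema default; a missing
    required column is a :class:`FormatError` naming the column and schema.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in schema.required:
        if col not in df.columns:
            raise FormatError(
                f"missing required column {col!r} for schema {schema_name!r} in {path}"
            )
    for col, default in schema.optional.items():
        if col not in df.columns:
            df[col] = default
    for col in schema.numeric:
        df[col] = pd.to_numeric(df[col], errors="raise")
    if schema_name == "localization":
        bad = sorted(set(df["category"]) - LOCALIZATION_CATEGORIES)
        if bad:
            raise FormatError(
                f"invalid localization categories {bad}; "
                f"allowed: {sorted(LOCALIZATION_CATEGORIES)}"
            )
    if schema_name == "integrons":
        bad = sorted(set(df["kind"]) - INTEGRON_KINDS)
        if bad:
            raise FormatError(f"invalid integron kinds {bad}")
    if schema_name == "prophages":
        bad = sorted(set(df["completeness"]) - PROPHAGE_COMPLETENESS)
        if bad:
            raise FormatError(f"invalid prophage completeness values {bad}")
    logger.info("read %d rows from %s (schema %s)", len(df), path, schema_name)
    return df


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

EDGE_TSV_COLUMNS = ("source", "target", "score", "evalue", "identity", "coverage", "weight")


def write_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a similarity network as GraphML or an edge-list TSV.

    GraphML preserves isolated nodes and node attributes and round-trips
    through :func:`read_graph`; the edge TSV carries the fixed column set
    ``(source, target, score, evalue, identity, coverage, weight)`` for
    spreadsheet/Gephi-style use.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for n, attrs in graph.nodes(data=True):
            g.add_node(n, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, attrs in graph.edges(data=True):
            g.add_edge(u, v, **{k: w for k, w in attrs.items() if w is not None})
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        rows = []
        for u, v, attrs in sorted(graph.edges(data=True)):
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "score": attrs.get("score", 0),
                    "evalue": attrs.get("evalue", float("nan")),
                    "identity": attrs.get("identity", float("nan")),
                    "coverage": attrs.get("coverage", float("nan")),
                    "weight": attrs.get("weight", 1.0),
                }
            )
        pd.DataFrame(rows, columns=list(EDGE_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(
                row.source,
                row.target,
                score=row.score,
                evalue=row.evalue,
                identity=row.identity,
                coverage=row.coverage,
                weight=row.weight,
            )
        return g
    raise ValueError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------------------
# genome-set assembly, config, logging
# ---------------------------------------------------------------------------


def build_genome_set(
    proteome_paths: Mapping[str, str | Path],
    metadata: pd.DataFrame | None = None,
    genome_paths: Mapping[str, str | Path] | None = None,
) -> GenomeSet:
    """Assemble a :class:`GenomeSet` from per-genome proteome FASTA files.

    ``metadata`` follows the ``metadata`` schema; genomes absent from it keep
    empty labels.  ``genome_paths`` optionally supplies nucleotide FASTAs from
    which genome length and GC content are computed.
    """
    from .genome_stats import genome_size_gc  # local import to avoid a cycle

    meta: dict[str, dict[str, str]] = {}
    if metadata is not None:
        for row in metadata.itertuples(index=False):
            meta[row.genome_id] = {
                "family": row.family,
                "subclade": getattr(row, "subclade", ""),
                "isolation_source": getattr(row, "isolation_source", ""),
            }
    genomes = []
    for gid in sorted(proteome_paths):
        recs = read_fasta(proteome_paths[gid], alphabet="protein")
        proteins = [ProteinRecord(rid, gid, seq, desc) for rid, desc, seq in recs]
        entry = GenomeEntry(genome_id=gid, proteins=proteins, **meta.get(gid, {}))
        if genome_paths and gid in genome_paths:
            entry.genome_length_bp, entry.gc_fraction = genome_size_gc(genome_paths[gid])
        genomes.append(entry)
    return GenomeSet(genomes=genomes)


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )
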