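"""CXXCH / CXXXCH heme-binding motif detection and the per-family census.

The covalent attachment site of a c-type heme is the CXXCH (occasionally
CXXXCH) motif, whose two cysteines form thioether bonds to the heme vinyl
groups and whose histidine is the proximal iron ligand.  A protein carrying
three or more such motifs is treated as a multi-heme cytochrome, the
operational proxy for extracellular-electron-transfer capability.

Two scan policies are provided because scripted regex alternations consume
matched text: ``nonoverlap_greedy`` (default) walks left to right, tries the
shorter pattern first and never lets a residue serve two motifs;
``all_matches`` enumerates every satisfying window, overlaps allowed.
Pattern wildcards accept any residue including the unknown X, but the three
anchors (C, C, H) must be literal — they define the ligation chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import GenomeSet, LOCALIZATION_CATEGORIES, logger

PATTERNS = {"CXXCH": (0, 3, 4), "CXXXCH": (0, 4, 5)}  # anchor offsets (C, C, H)
PATTERN_LENGTH = {"CXXCH": 5, "CXXXCH": 6}
POLICIES = ("nonoverlap_greedy", "all_matches")

HEME_CLASSES = ("none", "mono", "bi", "multi")


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    start: int
    pattern: str


@dataclass(frozen=True)
class HemeAnnotation:
    protein_id: str
    genome_id: str
    n_cxxch: int
    n_cxxxch: int
    localization: str = "unknown"

    @property
    def n_total(self) -> int:
        return self.n_cxxch + self.n_cxxxch

    @property
    def heme_class(self) -> str:
        n = self.n_total
        if n == 0:
            return "none"
        if n == 1:
            return "mono"
        if n == 2:
            return "bi"
        return "multi"

    @property
    def both_motifs(self) -> bool:
        return self.n_cxxch >= 1 and self.n_cxxxch >= 1

    @property
    def motif_type(self) -> str:
        """Mutually exclusive motif-type category: CXXCH-only / CXXXCH-only / both / none."""
        if self.both_motifs:
            return "both"
        if self.n_cxxch:
            return "CXXCH-only"
        if self.n_cxxxch:
            return "CXXXCH-only"
        return "none"


def _window_matches(seq: str, i: int, pattern: str) -> bool:
    c1, c2, h = PATTERNS[pattern]
    if i + PATTERN_LENGTH[pattern] > len(seq):
        return False
    return seq[i + c1] == "C" and seq[i + c2] == "C" and seq[i + h] == "H"


def scan_heme_motifs(
    sequence: str, policy: str = "nonoverlap_greedy", protein_id: str = ""
) -> list[MotifHit]:
    """Scan one normalized protein sequence for heme-binding motifs.

    Returns hits ordered by start position.  An empty sequence yields an
    empty list.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    hits: list[MotifHit] = []
    n = len(sequence)
    if policy == "nonoverlap_greedy":
        i = 0
        while i <= n - 5:
            if _window_matches(sequence, i, "CXXCH"):
                hits.append(MotifHit(protein_id, i, "CXXCH"))
                i += 5
            elif _window_matches(sequence, i, "CXXXCH"):
                hits.append(MotifHit(protein_id, i, "CXXXCH"))
                i += 6
            else:
                i += 1
    else:
        for i in range(n):
            for pattern in ("CXXCH", "CXXXCH"):
                if _window_matches(sequence, i, pattern):
                    hits.append(MotifHit(protein_id, i, pattern))
    return hits


def annotate_proteome(
    genome_set: GenomeSet,
    localization: pd.DataFrame | Mapping[str, str] | None = None,
    policy: str = "nonoverlap_greedy",
) -> list[HemeAnnotation]:
    """Scan every protein of a genome set and attach localization labels.

    The localization table may be partial: proteins absent from it get
    "unknown".  Rows referencing unknown protein ids are ignored with a
    warning.
    """
    loc_map: dict[str, str] = {}
    if localization is not None:
        if isinstance(localization, pd.DataFrame):
            items = zip(localization["protein_id"], localization["category"])
        else:
            items = localization.items()
        loc_map = dict(items)
    known = {p.protein_id for p in genome_set.iter_proteins()}
    stray = set(loc_map) - known
    if stray:
        logger.warning(
            "localization table references %d unknown protein ids (ignored)", len(stray)
        )
    annotations = []
    for protein in genome_set.iter_proteins():
        hits = scan_heme_motifs(protein.sequence, policy=policy, protein_id=protein.protein_id)
        n5 = sum(1 for h in hits if h.pattern == "CXXCH")
        n6 = len(hits) - n5
        category = loc_map.get(protein.protein_id, "unknown")
        if category not in LOCALIZATION_CATEGORIES:
            raise ValueError(f"invalid localization category {category!r}")
        annotations.append(
            HemeAnnotation(protein.protein_id, protein.genome_id, n5, n6, category)
        )
    return annotations


def annotations_frame(annotations: Iterable[HemeAnnotation]) -> pd.DataFrame:
    """Flatten annotations into the TSV layout used by the CLI."""
    rows = [
        {
            "protein_id": a.protein_id,
            "genome_id": a.genome_id,
            "n_cxxch": a.n_cxxch,
            "n_cxxxch": a.n_cxxxch,
            "n_total": a.n_total,
            "heme_class": a.heme_class,
            "both_motifs": a.both_motifs,
            "localization": a.localization,
        }
        for a in annotations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "genome_id",
            "n_cxxch",
            "n_cxxxch",
            "n_total",
            "heme_class",
            "both_motifs",
            "localization",
        ],
    )


def family_heme_summary(
    annotations: Iterable[HemeAnnotation], genome_set: GenomeSet
) -> pd.DataFrame:
    """Per-family heme census.

    One row per family with: mean heme-containing proteins per genome;
    percentage of motif-bearing proteins that are CXXCH-only, CXXXCH-only or
    carry both motif types; counts by heme class; mean
    extracellular-predicted multi-heme proteins per genome; and the
    percentage of multi-heme proteins predicted extracellular.  Families with
    zero genomes are excluded with a warning (they cannot arise from a
    well-formed GenomeSet but can from an inconsistent family map).
    """
    fam_map = genome_set.family_map()
    fam_genomes: dict[str, int] = {}
    for gid, fam in fam_map.items():
        fam_genomes[fam] = fam_genomes.get(fam, 0) + 1

    stats: dict[str, dict[str, float]] = {
        fam: {
            "n_genomes": n,
            "heme_proteins": 0,
            "cxxch_only": 0,
            "cxxxch_only": 0,
            "both": 0,
            "mono": 0,
            "bi": 0,
            "multi": 0,
            "multi_extracellular": 0,
            "extracellular_multi_per_genome": 0.0,
        }
        for fam, n in fam_genomes.items()
    }
    for a in annotations:
        fam = fam_map.get(a.genome_id)
        if fam is None:
            raise ValueError(f"annotation genome {a.genome_id} not in genome set")
        s = stats[fam]
        if a.n_total == 0:
            continue
        s["heme_proteins"] += 1
        key = {"CXXCH-only": "cxxch_only", "CXXXCH-only": "cxxxch_only", "both": "both"}[
            a.motif_type
        ]
        s[key] += 1
        s[a.heme_class] += 1
        if a.heme_class == "multi" and a.localization == "extracellular":
            s["multi_extracellular"] += 1

    rows = []
    for fam in sorted(stats):
        s = stats[fam]
        n_gen = s["n_genomes"]
        if n_gen == 0:
            logger.warning("family %s has zero genomes; excluded from summary", fam)
            continue
        hp = s["heme_proteins"]
        rows.append(
            {
                "family": fam,
                "n_genomes": int(n_gen),
                "heme_proteins_total": int(hp),
                "mean_heme_proteins_per_genome": hp / n_gen,
                "pct_cxxch_only": 100.0 * s["cxxch_only"] / hp if hp else 0.0,
                "pct_cxxxch_only": 100.0 * s["cxxxch_only"] / hp if hp else 0.0,
                "pct_both_motifs": 100.0 * s["both"] / hp if hp else 0.0,
                "n_mono": int(s["mono"]),
                "n_bi": int(s["bi"]),
                "n_multi": int(s["multi"]),
                "mean_multi_per_genome": s["multi"] / n_gen,
                "mean_extracellular_multi_per_genome": s["multi_extracellular"] / n_gen,
                "pct_multi_extracellular": (
                    100.0 * s["multi_extracellular"] / s["multi"] if s["multi"] else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


def hits_frame(genome_set: GenomeSet, policy: str = "nonoverlap_greedy") -> pd.DataFrame:
    rows = []
    for protein in genome_set.iter_proteins():
        for h in scan_heme_motifs(protein.sequence, policy=policy, protein_id=protein.protein_id):
            rows.append({"protein_id": h.protein_id, "start": h.start, "pattern": h.pattern})
    return pd.DataFrame(rows, columns=["protein_id", "start", "pattern"])
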