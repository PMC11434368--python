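"""Mobile-genetic-element census aggregation.

Detection itself is external (PHASTER-style prophage regions, CRISPR arrays,
IntegronFinder element kinds, ISFinder blastn hits, CONJScan conjugation
systems); this module consumes normalized per-element TSVs, applies the
published filters, and aggregates per genome / family / subclade.

Filters: IS hits are kept only with alignment length strictly over 700 bp
and E-value <= 1e-6.  Prophage density = prophages per Mbp of genome; by
default all completeness categories count (a knob restricts it to intact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io_formats import GenomeSet, INTEGRON_KINDS, PROPHAGE_COMPLETENESS, logger

IS_MIN_LENGTH = 700  # strict ">"
IS_EVALUE_MAX = 1e-6

ELEMENT_TABLES = ("prophages", "crispr", "integrons", "is_hits", "ices")

PROFILE_COLUMNS = [
    "prophages_intact",
    "prophages_questionable",
    "prophages_incomplete",
    "prophages_total",
    "crispr_arrays",
    "integrons_complete",
    "integrons_In0",
    "integrons_CALIN",
    "is_count",
    "ice_types",
    "prophage_density",
]


@dataclass(frozen=True)
class MobilomeProfile:
    genome_id: str
    prophages_intact: int = 0
    prophages_questionable: int = 0
    prophages_incomplete: int = 0
    crispr_arrays: int = 0
    integrons_complete: int = 0
    integrons_In0: int = 0
    integrons_CALIN: int = 0
    is_count: int = 0
    ice_types: int = 0
    genome_length_bp: int = 0
    density_mode: str = "total"

    @property
    def prophages_total(self) -> int:
        return self.prophages_intact + self.prophages_questionable + self.prophages_incomplete

    @property
    def prophage_density(self) -> float:
        if self.genome_length_bp <= 0:
            raise ValueError(f"genome_length_bp unknown for {self.genome_id}")
        count = self.prophages_total if self.density_mode == "total" else self.prophages_intact
        return count / (self.genome_length_bp / 1e6)


def filter_is_hits(
    hits: pd.DataFrame,
    min_length: int = IS_MIN_LENGTH,
    evalue_max: float = IS_EVALUE_MAX,
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the IS filters; returns (retained rows, per-genome counts).

    A hit survives iff ``aln_length > min_length`` (strict) and
    ``evalue <= evalue_max``.  Rows with negative lengths are rejected with
    a warning before filtering.
    """
    hits = hits.copy()
    neg = hits["aln_length"] < 0
    if neg.any():
        logger.warning("rejecting %d IS rows with negative alignment length", int(neg.sum()))
        hits = hits[~neg]
    kept = hits[(hits["aln_length"] > min_length) & (hits["evalue"] <= evalue_max)]
    counts = kept.groupby("genome_id").size()
    return kept.reset_index(drop=True), counts


def build_mobilome_profiles(
    tables: Mapping[str, pd.DataFrame],
    genome_set: GenomeSet,
    density_mode: str = "total",
) -> pd.DataFrame:
    """One profile row per genome of the set, indexed by genome_id.

    ``tables`` maps element-table names (:data:`ELEMENT_TABLES`) to frames
    in their normalized schemas; a missing table or missing genome yields
    zeros with a warning, but a genome present in a table and absent from
    the genome set is an error.
    """
    if density_mode not in ("total", "intact"):
        raise ValueError(f"unknown density mode {density_mode!r}")
    known = set(genome_set.genome_ids)
    for name, df in tables.items():
        stray = set(df["genome_id"]) - known
        if stray:
            raise ValueError(f"{name} table references unknown genomes: {sorted(stray)}")

    rows = []
    for g in genome_set.genomes:
        gid = g.genome_id
        vals = {c: 0 for c in PROFILE_COLUMNS[:-1]}
        if "prophages" in tables:
            sub = tables["prophages"].query("genome_id == @gid")
            for cat in PROPHAGE_COMPLETENESS:
                vals[f"prophages_{cat}"] = int((sub["completeness"] == cat).sum())
        if "crispr" in tables:
            vals["crispr_arrays"] = int((tables["crispr"]["genome_id"] == gid).sum())
        if "integrons" in tables:
            sub = tables["integrons"].query("genome_id == @gid")
            for kind in INTEGRON_KINDS:
                vals[f"integrons_{kind}"] = int((sub["kind"] == kind).sum())
        if "is_hits" in tables:
            _, counts = filter_is_hits(tables["is_hits"])
            vals["is_count"] = int(counts.get(gid, 0))
        if "ices" in tables:
            sub = tables["ices"].query("genome_id == @gid")
            vals["ice_types"] = int(sub["system_type"].nunique())
        vals["prophages_total"] = (
            vals["prophages_intact"] + vals["prophages_questionable"] + vals["prophages_incomplete"]
        )
        if g.genome_length_bp <= 0:
            raise ValueError(f"genome_length_bp unknown for {gid}; cannot compute density")
        count = vals["prophages_total"] if density_mode == "total" else vals["prophages_intact"]
        vals["prophage_density"] = count / (g.genome_length_bp / 1e6)
        rows.append({"genome_id": gid, **vals})
    missing = [
        g.genome_id
        for g in genome_set.genomes
        for name in ELEMENT_TABLES
        if name in tables and g.genome_id not in set(tables[name]["genome_id"])
    ]
    if missing:
        logger.warning("genomes absent from some element tables (zeros used): %s", sorted(set(missing)))
    return pd.DataFrame(rows).set_index("genome_id")[PROFILE_COLUMNS]


ELEMENT_METRICS = [
    "prophages_total",
    "crispr_arrays",
    "integrons_complete",
    "is_count",
    "ice_types",
]


def family_mobilome_summary(
    profiles: pd.DataFrame,
    family_map: Mapping[str, str],
    subclade_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mean count per strain, prevalence, and mean prophage density per group.

    Groups are families and, when a subclade map is given, (family, subclade)
    pairs; the ``level`` column distinguishes the two.
    """

    def summarize(label_level: str, label: str, gids: list[str]) -> dict:
        sub = profiles.loc[gids]
        row: dict = {"level": label_level, "group": label, "n_genomes": len(gids)}
        for metric in ELEMENT_METRICS:
            row[f"mean_{metric}"] = float(sub[metric].mean())
            row[f"prevalence_{metric}"] = float((sub[metric] >= 1).mean())
        row["mean_prophage_density"] = float(sub["prophage_density"].mean())
        return row

    fams: dict[str, list[str]] = {}
    for gid in profiles.index:
        fams.setdefault(family_map[gid], []).append(gid)
    rows = [summarize("family", fam, gids) for fam, gids in sorted(fams.items())]
    if subclade_map is not None:
        subs: dict[tuple[str, str], list[str]] = {}
        for gid in profiles.index:
            subs.setdefault((family_map[gid], subclade_map.get(gid, "")), []).append(gid)
        rows += [
            summarize("subclade", f"{fam}/{sc}", gids)
            for (fam, sc), gids in sorted(subs.items())
        ]
    return pd.DataFrame(rows)
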