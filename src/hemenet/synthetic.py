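"""Seeded generator of a complete toy comparative-genomics study.

Emits every input the pipeline consumes — per-genome proteomes and genome
FASTAs, an orthogroup table, a localization table, an EET-marker database,
mobilome element tables, CheckM-style QC and metadata — together with truth
tables, so every stage can be checked against planted ground truth without
any downloads.

Design in brief: each *gene family* has a random ancestor protein
(150-450 aa); per-genome copies diverge from it by uniform point
substitutions so that two copies of one family share a target pairwise
identity, while different families are unrelated random sequences.  Heme
motifs are planted at family-level non-overlapping slots (wildcards never C
or H, inter-slot gap >= 6) and every *accidental* motif arising from the
random background is scrubbed by breaking an anchor residue outside any
planted slot, so the realized motif census equals the planted one and is
re-verified by an internal brute-force scan before being recorded as truth.
Gene families follow fixed presence archetypes (universal single-copy,
universal multi-copy, designated cytochrome families with boosted motif
rates and surface localization, family-exclusive, two-family, and
genome-specific) so the sharing statistics have nontrivial expected values.
Nucleotide genomes are length/GC-controlled filler: no stage maps proteins
to coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_stats import FEATURE_COLUMNS
from .io_formats import write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_CH = [a for a in AA20 if a not in "CH"]

FAMILY_NAMES = ["Desulfovibrionaceae", "Geobacteraceae", "Shewanellaceae"]
FAMILY_GC = [0.60, 0.55, 0.46]
ISOLATION_SOURCES = ["marine sediment", "freshwater sediment", "soil", "engineered system"]
ICE_SYSTEM_TYPES = ["typeF", "typeT", "typeB", "typeG", "typeFATA"]

#: named markers -> (source organism, functional category); the cytochrome-ish
#: ones are attached to the designated cytochrome gene families.
NAMED_MARKERS = {
    "ompJ": ("G. sulfurreducens PCA", "outer-membrane cytochrome/protein"),
    "omcA": ("S. oneidensis MR-1", "outer-membrane cytochrome/protein"),
    "mtrA": ("S. oneidensis MR-1", "porin-cytochrome complex"),
    "cbcA": ("G. sulfurreducens PCA", "cytochrome bc complex"),
    "cbcB": ("G. sulfurreducens PCA", "cytochrome bc complex"),
    "ppcA": ("G. sulfurreducens PCA", "periplasmic"),
    "cymA": ("S. oneidensis MR-1", "other"),
    "ribB": ("S. oneidensis MR-1", "riboflavin biosynthesis"),
    "ribE": ("S. oneidensis MR-1", "riboflavin biosynthesis"),
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic toy study (all seeded)."""

    seed: int = 0
    n_families: int = 3
    genomes_per_family: int = 4
    n_gene_families: int = 30
    single_copy_fraction: float = 0.4
    within_family_identity: float = 0.85  # target pairwise identity inside a gene family
    between_family_identity: float = 0.25  # upper bound on background identity
    marker_fraction: float = 0.3
    heme_motif_rate: float = 1.0  # Poisson mean, background proteins
    cytochrome_heme_rate: float | None = None  # default: 5x the background rate
    n_cytochrome_families: int = 5
    genome_length_mean_mbp: float = 1.5
    mobilome_rates: dict = field(
        default_factory=lambda: {
            "prophages": 3.0,
            "crispr": 2.0,
            "integrons": 1.0,
            "is_hits": 6.0,
            "ices": 2.0,
        }
    )
    pca_latent_factors: int = 2
    localization_coverage: float = 0.9  # fraction of background proteins with a row
    orphan_genes_per_genome: int = 3  # singleton genes outside every orthogroup

    def validate(self) -> None:
        if not 0 < self.within_family_identity <= 1:
            raise ValueError("within_family_identity must be in (0, 1]")
        if not 0 <= self.between_family_identity < self.within_family_identity:
            raise ValueError(
                "between_family_identity must be in [0, within_family_identity)"
            )
        if any(r < 0 for r in self.mobilome_rates.values()) or self.heme_motif_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_families < 1 or self.genomes_per_family < 1 or self.n_gene_families < 1:
            raise ValueError("counts must be >= 1")

    @property
    def cyt_rate(self) -> float:
        return (
            self.cytochrome_heme_rate
            if self.cytochrome_heme_rate is not None
            else 5.0 * self.heme_motif_rate
        )


@dataclass
class TruthTables:
    true_og: dict[str, str]  # protein -> gene-family og id
    true_motif_counts: pd.DataFrame  # protein_id, n_cxxch, n_cxxxch
    true_localization: dict[str, str]  # effective downstream label
    true_marker_copies: pd.DataFrame  # genomes x markers
    true_communities: dict[str, str]  # SSN node -> gene-family id
    true_mobilome: pd.DataFrame  # genomes x element counts (post-filter)
    marker_families: dict[str, str]  # marker_id -> og id
    family_map: dict[str, str]
    subclade_map: dict[str, str]


# ---------------------------------------------------------------------------
# motif machinery (kept independent of hemenet.heme_scan on purpose: the
# generator's own brute-force walk is the oracle the scanner is tested against)
# ---------------------------------------------------------------------------


def _window_hits(seq: str) -> list[tuple[int, str]]:
    hits = []
    for i in range(len(seq)):
        if i + 5 <= len(seq) and seq[i] == "C" and seq[i + 3] == "C" and seq[i + 4] == "H":
            hits.append((i, "CXXCH"))
        if i + 6 <= len(seq) and seq[i] == "C" and seq[i + 4] == "C" and seq[i + 5] == "H":
            hits.append((i, "CXXXCH"))
    return hits


def _greedy_counts(seq: str) -> tuple[int, int]:
    n5 = n6 = 0
    i = 0
    n = len(seq)
    while i <= n - 5:
        if seq[i] == "C" and seq[i + 3] == "C" and seq[i + 4] == "H":
            n5 += 1
            i += 5
        elif i + 6 <= n and seq[i] == "C" and seq[i + 4] == "C" and seq[i + 5] == "H":
            n6 += 1
            i += 6
        else:
            i += 1
    return n5, n6


def _scrub_accidental_motifs(
    seq: list[str], planted: list[tuple[int, int]], rng: np.random.Generator
) -> None:
    """Break every motif window not inside a planted slot, in place.

    Anchors of a stray window cannot all lie inside one planted slot (slots
    are >= 6 apart and their wildcards exclude C/H), so one anchor is always
    free to mutate.
    """
    def inside(pos: int) -> bool:
        return any(s <= pos < e for s, e in planted)

    for _ in range(10):
        s = "".join(seq)
        # a hit is planted iff its exact window [i, i+len) equals a slot
        stray = [
            (i, pat)
            for i, pat in _window_hits(s)
            if (i, i + (5 if pat == "CXXCH" else 6)) not in planted
        ]
        if not stray:
            return
        for i, pat in stray:
            anchors = (i, i + 3, i + 4) if pat == "CXXCH" else (i, i + 4, i + 5)
            for a in anchors:
                if not inside(a):
                    seq[a] = AA_NO_CH[int(rng.integers(len(AA_NO_CH)))]
                    break
    raise RuntimeError("could not scrub accidental motifs")  # pragma: no cover


# ---------------------------------------------------------------------------
# planted partition graphs
# ---------------------------------------------------------------------------


def generate_planted_partition_graph(
    n_blocks: int, block_size: int, p_in: float, p_out: float, seed: int = 0
):
    """Unit-weight Bernoulli block graph plus its true block assignment."""
    import networkx as nx

    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    truth = {i: i // block_size for i in range(n)}
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if truth[i] == truth[j] else p_out
            if rng.random() < p:
                g.add_edge(i, j, weight=1.0)
    return g, truth


def generate_low_rank_features(
    n_genomes: int = 40,
    n_latent: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """A 13-variable feature table with known low-rank structure.

    ``X = F W^T + eps`` with F (n x k) standard normal and W (13 x k) a
    random orthonormal basis; returns the table and W for subspace-recovery
    checks.
    """
    rng = np.random.default_rng(seed)
    W, _ = np.linalg.qr(rng.standard_normal((len(FEATURE_COLUMNS), n_latent)))
    F = rng.standard_normal((n_genomes, n_latent))
    X = F @ W.T + noise_sd * rng.standard_normal((n_genomes, len(FEATURE_COLUMNS)))
    df = pd.DataFrame(
        X, index=[f"G{i:03d}" for i in range(n_genomes)], columns=FEATURE_COLUMNS
    )
    return df, W


# ---------------------------------------------------------------------------
# the study generator
# ---------------------------------------------------------------------------


def _derive_copy(ancestor: str, sub_fraction: float, rng: np.random.Generator) -> list[str]:
    seq = list(ancestor)
    n_sub = int(round(sub_fraction * len(seq)))
    if n_sub:
        positions = rng.choice(len(seq), size=n_sub, replace=False)
        for p in positions:
            choices = [a for a in AA20 if a != seq[p]]
            seq[p] = choices[int(rng.integers(len(choices)))]
    return seq


def _plant_slots(
    seq: list[str], slots: list[tuple[int, str]], n_use: int
) -> list[tuple[int, int]]:
    intervals = []
    for start, window in slots[:n_use]:
        seq[start : start + len(window)] = list(window)
        intervals.append((start, start + len(window)))
    return intervals


def generate_study(config: SynthConfig, out_dir: str | Path) -> tuple[dict[str, Path], TruthTables]:
    """Write the full toy study under ``out_dir`` and return (paths, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    for sub in ("proteomes", "genomes", "mobilome", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    # --- genomes and metadata -------------------------------------------------
    families = [
        FAMILY_NAMES[i] if i < len(FAMILY_NAMES) else f"Family{i + 1}"
        for i in range(config.n_families)
    ]
    genome_ids, family_map, subclade_map, meta_rows = [], {}, {}, []
    for fi, fam in enumerate(families):
        for k in range(config.genomes_per_family):
            gid = f"G{fi * config.genomes_per_family + k + 1:02d}"
            genome_ids.append(gid)
            family_map[gid] = fam
            subclade_map[gid] = "I" if k < (config.genomes_per_family + 1) // 2 else "II"
            meta_rows.append(
                {
                    "genome_id": gid,
                    "family": fam,
                    "subclade": subclade_map[gid],
                    "isolation_source": ISOLATION_SOURCES[
                        int(rng.integers(len(ISOLATION_SOURCES)))
                    ],
                }
            )

    # --- gene-family archetypes ----------------------------------------------
    n = config.n_gene_families
    n_single = int(round(config.single_copy_fraction * n))
    n_cyt = min(config.n_cytochrome_families, max(0, n - n_single))
    kinds = ["single"] * n_single + ["cyt"] * n_cyt
    pattern = ["multi", "fam_excl", "pair_excl", "species"]
    kinds += [pattern[i % 4] for i in range(n - len(kinds))]
    og_ids = [f"OG{i:07d}" for i in range(n)]

    fam_genomes = {
        fam: [g for g in genome_ids if family_map[g] == fam] for fam in families
    }
    fam_pairs = [
        (families[i], families[j])
        for i in range(len(families))
        for j in range(i + 1, len(families))
    ] or [(families[0], families[0])]

    copies: dict[int, dict[str, int]] = {}  # gene family -> genome -> copy number
    fx_i = px_i = sp_i = 0
    for i, kind in enumerate(kinds):
        if kind == "single":
            copies[i] = {g: 1 for g in genome_ids}
        elif kind in ("cyt", "multi"):
            copies[i] = {g: int(rng.integers(1, 4)) for g in genome_ids}
        elif kind == "fam_excl":
            fam = families[fx_i % len(families)]
            fx_i += 1
            copies[i] = {g: 1 for g in fam_genomes[fam]}
        elif kind == "pair_excl":
            fa, fb = fam_pairs[px_i % len(fam_pairs)]
            px_i += 1
            copies[i] = {g: 1 for g in dict.fromkeys(fam_genomes[fa] + fam_genomes[fb])}
        else:  # species-specific
            g = genome_ids[sp_i % len(genome_ids)]
            sp_i += 1
            copies[i] = {g: 1}

    # --- ancestors and motif slots -------------------------------------------
    ancestors: list[str] = []
    slots_per_family: list[list[tuple[int, str]]] = []
    for i in range(n):
        length = int(rng.integers(150, 451))
        ancestors.append("".join(AA20[j] for j in rng.integers(0, 20, size=length)))
        # non-overlapping slots with >= 6 residue gaps; wildcards never C/H
        slot_list: list[tuple[int, str]] = []
        pos = int(rng.integers(0, 12))
        while pos < length - 6 and len(slot_list) < 12:
            if rng.random() < 0.85:
                window = (
                    "C"
                    + "".join(AA_NO_CH[j] for j in rng.integers(len(AA_NO_CH), size=2))
                    + "CH"
                )
            else:
                window = (
                    "C"
                    + "".join(AA_NO_CH[j] for j in rng.integers(len(AA_NO_CH), size=3))
                    + "CH"
                )
            slot_list.append((pos, window))
            pos += len(window) + 6 + int(rng.integers(0, 20))
        slots_per_family.append(slot_list)

    cyt_indices = [i for i, k in enumerate(kinds) if k == "cyt"]
    surface_loc = {
        i: ("extracellular" if j % 2 == 0 else "outer membrane")
        for j, i in enumerate(cyt_indices)
    }

    # --- markers ---------------------------------------------------------------
    n_markers = max(len(NAMED_MARKERS), int(round(config.marker_fraction * n)))
    # multi-copy universal families first so copy-number marker columns vary
    universal_noncyt = [i for i, k in enumerate(kinds) if k == "multi"] + [
        i for i, k in enumerate(kinds) if k == "single"
    ]
    marker_assignment: dict[str, int] = {}
    it_cyt = iter(cyt_indices)
    it_uni = iter(universal_noncyt)
    for name in ("ompJ", "omcA", "mtrA", "cbcA", "cbcB"):
        idx = next(it_cyt, None)
        if idx is None:
            idx = next(it_uni, None)
        if idx is not None:
            marker_assignment[name] = idx
    for name in ("ppcA", "cymA", "ribB", "ribE"):
        idx = next(it_uni, None)
        if idx is not None:
            marker_assignment[name] = idx
    extra_pool = [
        i for i in range(n) if i not in set(marker_assignment.values())
    ]
    for j in range(n_markers - len(marker_assignment)):
        if j >= len(extra_pool):
            break
        marker_assignment[f"mk{j + 1:02d}"] = extra_pool[j]

    # --- per-protein emission ---------------------------------------------------
    sub_fraction = (1.0 - config.within_family_identity) / 2.0
    proteomes: dict[str, list[tuple[str, str, str]]] = {g: [] for g in genome_ids}
    true_og: dict[str, str] = {}
    motif_rows = []
    true_loc: dict[str, str] = {}
    loc_rows = []
    true_comm: dict[str, str] = {}

    for i in range(n):
        rate = config.cyt_rate if kinds[i] == "cyt" else config.heme_motif_rate
        slots = slots_per_family[i]
        for gid in genome_ids:
            for c in range(copies[i].get(gid, 0)):
                pid = f"{gid}_g{i:03d}_{c + 1}"
                seq = _derive_copy(ancestors[i], sub_fraction, rng)
                n_use = min(int(rng.poisson(rate)), len(slots))
                planted = _plant_slots(seq, slots, n_use)
                _scrub_accidental_motifs(seq, planted, rng)
                s = "".join(seq)
                n5, n6 = _greedy_counts(s)
                motif_rows.append({"protein_id": pid, "n_cxxch": n5, "n_cxxxch": n6})
                true_og[pid] = og_ids[i]
                if kinds[i] == "cyt":
                    category = surface_loc[i]
                    loc_rows.append({"protein_id": pid, "category": category})
                    true_loc[pid] = category
                    true_comm[pid] = og_ids[i]
                else:
                    category = ["cytoplasmic", "cytoplasmic membrane", "periplasmic", "unknown"][
                        int(rng.integers(4))
                    ]
                    if rng.random() < config.localization_coverage:
                        loc_rows.append({"protein_id": pid, "category": category})
                        true_loc[pid] = category
                    else:
                        true_loc[pid] = "unknown"
                proteomes[gid].append((pid, f"gene family {og_ids[i]}", s))

    # orphan genes: present in the proteome, absent from every orthogroup,
    # mirroring the unassigned-gene fraction of a real orthology run
    for gid in genome_ids:
        for j in range(config.orphan_genes_per_genome):
            pid = f"{gid}_orphan_{j + 1}"
            length = int(rng.integers(150, 451))
            seq = [AA20[k] for k in rng.integers(0, 20, size=length)]
            _scrub_accidental_motifs(seq, [], rng)
            s = "".join(seq)
            n5, n6 = _greedy_counts(s)
            motif_rows.append({"protein_id": pid, "n_cxxch": n5, "n_cxxxch": n6})
            category = ["cytoplasmic", "cytoplasmic membrane", "periplasmic", "unknown"][
                int(rng.integers(4))
            ]
            if rng.random() < config.localization_coverage:
                loc_rows.append({"protein_id": pid, "category": category})
                true_loc[pid] = category
            else:
                true_loc[pid] = "unknown"
            proteomes[gid].append((pid, "orphan gene", s))

    paths: dict[str, Path] = {}
    for gid in genome_ids:
        p = out / "proteomes" / f"{gid}.faa"
        write_fasta(proteomes[gid], p)
        paths[f"proteome:{gid}"] = p

    # --- genome FASTA -----------------------------------------------------------
    for fi, fam in enumerate(families):
        gc = FAMILY_GC[fi % len(FAMILY_GC)]
        for gid in fam_genomes[fam]:
            length = int(config.genome_length_mean_mbp * 1e6 * rng.uniform(0.85, 1.15))
            g_gc = min(0.9, max(0.1, gc + rng.uniform(-0.02, 0.02)))
            probs = [(1 - g_gc) / 2, g_gc / 2, g_gc / 2, (1 - g_gc) / 2]
            bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
            seq = bases.tobytes().decode()
            p = out / "genomes" / f"{gid}.fna"
            write_fasta([(f"{gid}_contig1", "synthetic genome filler", seq)], p)
            paths[f"genome:{gid}"] = p

    # --- orthogroups TSV (truth-derived) ---------------------------------------
    og_rows = []
    for i in range(n):
        row = {"Orthogroup": og_ids[i]}
        for gid in genome_ids:
            pids = [f"{gid}_g{i:03d}_{c + 1}" for c in range(copies[i].get(gid, 0))]
            row[gid] = ", ".join(pids)
        og_rows.append(row)
    og_df = pd.DataFrame(og_rows, columns=["Orthogroup", *genome_ids])
    paths["orthogroups"] = out / "orthogroups.tsv"
    og_df.to_csv(paths["orthogroups"], sep="\t", index=False)

    paths["localization"] = out / "localization.tsv"
    pd.DataFrame(loc_rows, columns=["protein_id", "category"]).to_csv(
        paths["localization"], sep="\t", index=False
    )

    # --- marker database --------------------------------------------------------
    marker_rows, marker_fasta = [], []
    for name in sorted(marker_assignment):
        idx = marker_assignment[name]
        source, category = NAMED_MARKERS.get(name, ("G. sulfurreducens PCA", "other"))
        ref_id = f"REF_{name}"
        ref_seq = list(ancestors[idx])
        rate = config.cyt_rate if kinds[idx] == "cyt" else config.heme_motif_rate
        n_use = min(int(rng.poisson(rate)), len(slots_per_family[idx]))
        planted = _plant_slots(ref_seq, slots_per_family[idx], n_use)
        _scrub_accidental_motifs(ref_seq, planted, rng)
        marker_rows.append(
            {
                "marker_id": name,
                "reference_protein_id": ref_id,
                "source_model": source,
                "category": category,
            }
        )
        marker_fasta.append((ref_id, f"reference for {name}", "".join(ref_seq)))
    paths["markers"] = out / "markers.tsv"
    pd.DataFrame(
        marker_rows, columns=["marker_id", "reference_protein_id", "source_model", "category"]
    ).to_csv(paths["markers"], sep="\t", index=False)
    paths["marker_fasta"] = out / "markers.faa"
    write_fasta(marker_fasta, paths["marker_fasta"])

    # --- mobilome tables ---------------------------------------------------------
    rates = config.mobilome_rates
    pro_rows, cri_rows, int_rows, is_rows, ice_rows = [], [], [], [], []
    mob_truth = []
    for gid in genome_ids:
        t = {"genome_id": gid}
        n_pro = int(rng.poisson(rates.get("prophages", 0.0)))
        cats = rng.choice(
            ["intact", "questionable", "incomplete"], size=n_pro, p=[0.18, 0.09, 0.73]
        )
        for j, cat in enumerate(cats):
            pro_rows.append(
                {"genome_id": gid, "region_id": f"{gid}_ph{j + 1}", "completeness": cat}
            )
        t["prophages_intact"] = int((cats == "intact").sum())
        t["prophages_questionable"] = int((cats == "questionable").sum())
        t["prophages_incomplete"] = int((cats == "incomplete").sum())
        t["prophages_total"] = n_pro

        n_cri = int(rng.poisson(rates.get("crispr", 0.0)))
        for j in range(n_cri):
            cri_rows.append({"genome_id": gid, "array_id": f"{gid}_cr{j + 1}"})
        t["crispr_arrays"] = n_cri

        n_int = int(rng.poisson(rates.get("integrons", 0.0)))
        kinds_drawn = rng.choice(["complete", "In0", "CALIN"], size=n_int, p=[0.45, 0.3, 0.25])
        for j, kind in enumerate(kinds_drawn):
            int_rows.append(
                {"genome_id": gid, "element_id": f"{gid}_in{j + 1}", "kind": kind}
            )
        for kind in ("complete", "In0", "CALIN"):
            t[f"integrons_{kind}"] = int((kinds_drawn == kind).sum())

        n_is = int(rng.poisson(rates.get("is_hits", 0.0)))
        kept = 0
        for j in range(n_is):
            aln_length = int(rng.integers(400, 1800))
            evalue = 10.0 ** (-rng.uniform(2.0, 40.0))
            is_rows.append(
                {
                    "genome_id": gid,
                    "is_name": f"IS{int(rng.integers(1, 90))}",
                    "family": f"IS{int(rng.integers(1, 30))}fam",
                    "aln_length": aln_length,
                    "evalue": evalue,
                }
            )
            if aln_length > 700 and evalue <= 1e-6:
                kept += 1
        t["is_count"] = kept

        n_ice = min(int(rng.poisson(rates.get("ices", 0.0))), len(ICE_SYSTEM_TYPES))
        types = list(rng.choice(ICE_SYSTEM_TYPES, size=n_ice, replace=False))
        for st in types:
            ice_rows.append({"genome_id": gid, "system_type": st})
            if rng.random() < 0.2:  # duplicate rows must not inflate the type count
                ice_rows.append({"genome_id": gid, "system_type": st})
        t["ice_types"] = n_ice
        mob_truth.append(t)

    for name, rows, cols in [
        ("prophages", pro_rows, ["genome_id", "region_id", "completeness"]),
        ("crispr", cri_rows, ["genome_id", "array_id"]),
        ("integrons", int_rows, ["genome_id", "element_id", "kind"]),
        ("is_hits", is_rows, ["genome_id", "is_name", "family", "aln_length", "evalue"]),
        ("ices", ice_rows, ["genome_id", "system_type"]),
    ]:
        paths[name] = out / "mobilome" / f"{name}.tsv"
        pd.DataFrame(rows, columns=cols).to_csv(paths[name], sep="\t", index=False)

    # --- QC and metadata ---------------------------------------------------------
    checkm_rows = [
        {
            "genome_id": gid,
            "completeness": round(float(rng.uniform(98.3, 100.0)), 2),
            "contamination": round(float(rng.uniform(0.0, 4.0)), 2),
        }
        for gid in genome_ids
    ]
    paths["checkm"] = out / "checkm.tsv"
    pd.DataFrame(checkm_rows).to_csv(paths["checkm"], sep="\t", index=False)
    paths["metadata"] = out / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], sep="\t", index=False)

    # --- truth tables --------------------------------------------------------------
    motif_df = pd.DataFrame(motif_rows, columns=["protein_id", "n_cxxch", "n_cxxxch"])
    marker_copy_df = pd.DataFrame(
        {
            name: [copies[marker_assignment[name]].get(g, 0) for g in genome_ids]
            for name in sorted(marker_assignment)
        },
        index=genome_ids,
    )
    mob_df = pd.DataFrame(mob_truth).set_index("genome_id")
    truth = TruthTables(
        true_og=true_og,
        true_motif_counts=motif_df,
        true_localization=true_loc,
        true_marker_copies=marker_copy_df,
        true_communities=true_comm,
        true_mobilome=mob_df,
        marker_families={m: og_ids[i] for m, i in marker_assignment.items()},
        family_map=family_map,
        subclade_map=subclade_map,
    )
    truth_dir = out / "truth"
    motif_df.to_csv(truth_dir / "motif_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"protein_id": p, "og_id": o} for p, o in sorted(true_og.items())]
    ).to_csv(truth_dir / "og.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"protein_id": p, "category": c} for p, c in sorted(true_loc.items())]
    ).to_csv(truth_dir / "localization.tsv", sep="\t", index=False)
    marker_copy_df.rename_axis("genome_id").to_csv(truth_dir / "marker_copies.tsv", sep="\t")
    pd.DataFrame(
        [{"protein_id": p, "block": b} for p, b in sorted(true_comm.items())]
    ).to_csv(truth_dir / "communities.tsv", sep="\t", index=False)
    mob_df.to_csv(truth_dir / "mobilome.tsv", sep="\t")
    return paths, truth
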