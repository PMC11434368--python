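"""Independent brute-force oracles used across the test suite.

Each oracle re-derives the expected answer from first principles (window
enumeration, quadratic DP, exhaustive partition search, plain row scans)
without touching the implementation paths it checks.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

# ---------------------------------------------------------------------------
# heme motif scanning
# ---------------------------------------------------------------------------


def _is_cxxch(seq: str, i: int) -> bool:
    return i + 5 <= len(seq) and seq[i] == "C" and seq[i + 3] == "C" and seq[i + 4] == "H"


def _is_cxxxch(seq: str, i: int) -> bool:
    return i + 6 <= len(seq) and seq[i] == "C" and seq[i + 4] == "C" and seq[i + 5] == "H"


def all_matches_oracle(seq: str) -> list[tuple[int, str]]:
    """Every window satisfying either pattern, overlaps allowed."""
    out = []
    for i in range(len(seq)):
        if _is_cxxch(seq, i):
            out.append((i, "CXXCH"))
        if _is_cxxxch(seq, i):
            out.append((i, "CXXXCH"))
    return out


def greedy_oracle(seq: str) -> list[tuple[int, str]]:
    """Left-to-right walk, CXXCH before CXXXCH, matched windows consumed."""
    out = []
    i = 0
    while i < len(seq):
        if _is_cxxch(seq, i):
            out.append((i, "CXXCH"))
            i += 5
        elif _is_cxxxch(seq, i):
            out.append((i, "CXXXCH"))
            i += 6
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Smith-Waterman with affine gaps (quadratic Gotoh DP)
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal local alignment score; a gap of length L costs open + L*extend."""
    neg = float("-inf")
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            sub = H[i - 1][j - 1] + _BLOSUM62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# modularity / partitions
# ---------------------------------------------------------------------------


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many; keep inputs tiny)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1 :]
        yield [[head]] + part


def best_partition_oracle(graph, resolution: float = 1.0):
    """Exhaustive maximum-modularity partition via networkx's modularity."""
    import networkx as nx

    nodes = sorted(graph.nodes)
    best_q, best_p = -math.inf, None
    for part in set_partitions(nodes):
        q = nx.community.modularity(
            graph, [set(block) for block in part], weight="weight", resolution=resolution
        )
        if q > best_q:
            best_q, best_p = q, part
    return best_p, best_q


# ---------------------------------------------------------------------------
# orthogroup statistics (plain recounts)
# ---------------------------------------------------------------------------


def single_copy_oracle(orthogroups, genome_ids) -> list[str]:
    out = []
    for og in orthogroups:
        ok = True
        for g in genome_ids:
            if len(og.members.get(g, [])) != 1:
                ok = False
        if ok:
            out.append(og.og_id)
    return sorted(out)


def sharing_oracle(orthogroups, family_map, min_exclusive_genomes: int = 2) -> dict:
    genomes = set(family_map)
    fams = sorted(set(family_map.values()))
    res = {
        "universal": 0,
        "species_specific": 0,
        "family_exclusive": {f: 0 for f in fams},
        "family_pair_exclusive": {
            (a, b): 0 for i, a in enumerate(fams) for b in fams[i + 1 :]
        },
    }
    for og in orthogroups:
        gset = {g for g, pids in og.members.items() if pids}
        if all(g in gset for g in genomes):
            res["universal"] += 1
        if len(gset) == 1:
            res["species_specific"] += 1
        f = sorted({family_map[g] for g in gset})
        if len(f) == 1 and len(gset) >= min_exclusive_genomes:
            res["family_exclusive"][f[0]] += 1
        if len(f) == 2:
            res["family_pair_exclusive"][(f[0], f[1])] += 1
    return res


def is_filter_oracle(rows: list[dict], min_length: int = 700, evalue_max: float = 1e-6) -> dict:
    counts: dict[str, int] = {}
    for r in rows:
        if r["aln_length"] < 0:
            continue
        if r["aln_length"] > min_length and r["evalue"] <= evalue_max:
            counts[r["genome_id"]] = counts.get(r["genome_id"], 0) + 1
    return counts
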