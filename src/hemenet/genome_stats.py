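"""Genome QC, size/GC statistics, the 13-variable feature table and its PCA.

The feature table mixes units (Mbp, %, raw counts), so the default PCA is
on the correlation matrix: columns are z-scored (ddof = 1) and the
eigendecomposition of the resulting covariance — which equals the
correlation matrix — gives loadings, scores and percent variance explained.
``standardize=False`` preserves the covariance-PCA alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .heme_scan import HemeAnnotation
from .io_formats import GenomeSet, logger, read_fasta

FEATURE_COLUMNS = [
    "genome_size_mbp",
    "gc_percent",
    "prophages",
    "total_cyt_per_mbp",
    "integrons_complete",
    "crispr_arrays",
    "is_count",
    "ice_types",
    "ppcA_copies",
    "ompJ_copies",
    "cbc_copies_sum",
    "cymA_copies",
    "rib_copies_sum",
]


def qc_filter(checkm: pd.DataFrame, min_completeness: float = 98.0, max_contamination: float = 5.0):
    """CheckM-style QC: keep iff completeness > 98 and contamination < 5 (both strict).

    Returns ``(kept_ids, dropped)`` where dropped is a frame with a
    ``reason`` column.  Duplicate or missing-value rows are errors.
    """
    if checkm["genome_id"].duplicated().any():
        raise ValueError("duplicate genome rows in CheckM table")
    if checkm[["completeness", "contamination"]].isna().any().any():
        raise ValueError("missing completeness/contamination values")
    kept, dropped = [], []
    for row in checkm.itertuples(index=False):
        reasons = []
        if not row.completeness > min_completeness:
            reasons.append(f"completeness {row.completeness} <= {min_completeness}")
        if not row.contamination < max_contamination:
            reasons.append(f"contamination {row.contamination} >= {max_contamination}")
        if reasons:
            dropped.append({"genome_id": row.genome_id, "reason": "; ".join(reasons)})
        else:
            kept.append(row.genome_id)
    return kept, pd.DataFrame(dropped, columns=["genome_id", "reason"])


def genome_size_gc(source: str | Path | Iterable[tuple[str, str, str]]) -> tuple[int, float]:
    """Total length (all contigs, Ns included) and GC fraction of a genome.

    GC = (G+C) / (A+C+G+T); ambiguous bases are excluded from the
    denominator.  A genome with zero unambiguous bases has no defined GC and
    raises.
    """
    if isinstance(source, (str, Path)):
        records = read_fasta(source, alphabet="nucleotide")
    else:
        records = list(source)
    length = 0
    gc = 0
    acgt = 0
    for _, _, seq in records:
        length += len(seq)
        g = seq.count("G")
        c = seq.count("C")
        gc += g + c
        acgt += g + c + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined: zero unambiguous bases")
    return length, gc / acgt


def assemble_feature_table(
    genome_set: GenomeSet,
    presence: pd.DataFrame,
    markers: pd.DataFrame,
    annotations: Iterable[HemeAnnotation],
    mobilome_profiles: pd.DataFrame,
    cytochrome_scope: str = "all",
) -> pd.DataFrame:
    """Build the fixed 13-column feature table, one row per genome.

    ``total_cyt_per_mbp`` counts proteins with >= 1 heme motif (or only
    multi-heme proteins under ``cytochrome_scope='multi'``) per Mbp.
    ``cbc_copies_sum`` / ``rib_copies_sum`` sum copy numbers over all markers
    of the cytochrome-bc-complex / riboflavin-biosynthesis categories;
    ``ppcA_copies``, ``ompJ_copies`` and ``cymA_copies`` are single-marker
    columns (zero when the marker is absent from the presence matrix).  A
    genome missing from any source is an error naming it.
    """
    if cytochrome_scope not in ("all", "multi"):
        raise ValueError(f"unknown cytochrome scope {cytochrome_scope!r}")
    cat_of = dict(zip(markers["marker_id"], markers["category"]))
    cbc_markers = [m for m in presence.columns if cat_of.get(m) == "cytochrome bc complex"]
    rib_markers = [m for m in presence.columns if cat_of.get(m) == "riboflavin biosynthesis"]

    heme_count: dict[str, int] = {}
    for a in annotations:
        if a.n_total == 0:
            continue
        if cytochrome_scope == "multi" and a.heme_class != "multi":
            continue
        heme_count[a.genome_id] = heme_count.get(a.genome_id, 0) + 1

    rows = []
    for g in genome_set.genomes:
        gid = g.genome_id
        if gid not in presence.index:
            raise ValueError(f"genome {gid} missing from presence matrix")
        if gid not in mobilome_profiles.index:
            raise ValueError(f"genome {gid} missing from mobilome profiles")
        if g.genome_length_bp <= 0 or g.gc_fraction is None:
            raise ValueError(f"genome {gid} lacks length/GC statistics")
        size_mbp = g.genome_length_bp / 1e6
        prow = presence.loc[gid]
        mrow = mobilome_profiles.loc[gid]

        def marker_copies(name: str) -> float:
            return float(prow[name]) if name in presence.columns else 0.0

        rows.append(
            {
                "genome_id": gid,
                "genome_size_mbp": size_mbp,
                "gc_percent": 100.0 * g.gc_fraction,
                "prophages": float(mrow["prophages_total"]),
                "total_cyt_per_mbp": heme_count.get(gid, 0) / size_mbp,
                "integrons_complete": float(mrow["integrons_complete"]),
                "crispr_arrays": float(mrow["crispr_arrays"]),
                "is_count": float(mrow["is_count"]),
                "ice_types": float(mrow["ice_types"]),
                "ppcA_copies": marker_copies("ppcA"),
                "ompJ_copies": marker_copies("ompJ"),
                "cbc_copies_sum": float(prow[cbc_markers].sum()) if cbc_markers else 0.0,
                "cymA_copies": marker_copies("cymA"),
                "rib_copies_sum": float(prow[rib_markers].sum()) if rib_markers else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("genome_id")[FEATURE_COLUMNS]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # genomes x components
    variance_explained: np.ndarray  # percent per component, sums to 100
    dropped_columns: list[str]


def run_pca(features: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA by eigendecomposition of the (correlation) covariance matrix.

    Columns are centred and, when ``standardize``, scaled to unit variance
    (ddof = 1); constant columns are dropped with a warning in that case.
    Each loading vector is oriented so its largest-magnitude entry is
    positive; components are sorted by decreasing eigenvalue and
    ``variance_explained`` is 100 * lambda_k / sum(lambda).  Requires >= 3
    rows.
    """
    if len(features) < 3:
        raise ValueError("PCA requires at least 3 genomes")
    X = features.astype(float)
    dropped: list[str] = []
    if standardize:
        sd = X.std(ddof=1)
        constant = sd[sd == 0].index.tolist()
        if constant:
            logger.warning("dropping constant columns before standardized PCA: %s", constant)
            dropped = constant
            X = X.drop(columns=constant)
            sd = sd.drop(constant)
        Z = (X - X.mean()) / sd
    else:
        Z = X - X.mean()
    cov = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] *= -1
    comp_names = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=X.columns, columns=comp_names)
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=X.index, columns=comp_names)
    total = eigval.sum()
    variance = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    return PCAResult(loadings, scores, variance, dropped)
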