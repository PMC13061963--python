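"""Hierarchical clustering of reads on composition/transition/autocorrelation features.

Each read is summarized by a fixed-width feature row mirroring the three
per-read heatmap tracks used to characterize synthesis pools: 4 base
fractions, the flattened 4x4 transition matrix (undefined rows imputed as
uniform 0.25), and the autocorrelation values r(1..max_lag). Feature columns
are standardized across reads and reads are grouped by agglomerative
clustering (Euclidean distance, Ward linkage). The largest ``n_top``
clusters are reported in size order and labelled with the panel motif that
passes in the majority of member reads, or "random" when none does.

Pools are conventionally clustered separately for reads shorter and longer
than 250 nt, after seeded subsampling, via :func:`cluster_pool_by_length`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .motifs import MotifPanel, canonical_rotation, classify_read
from .reads import ReadPool
from .seqstats import autocorrelation_profile, base_composition, transition_matrix

__all__ = [
    "FeatureTable",
    "ClusterResult",
    "featurize_reads",
    "hierarchical_top_clusters",
    "label_clusters",
    "cluster_pool_by_length",
]


@dataclass
class FeatureTable:
    values: np.ndarray  # n_reads x (4 + 16 + max_lag), standardized
    read_ids: list[str]
    max_lag: int

    def __len__(self) -> int:
        return len(self.read_ids)


@dataclass
class ClusterResult:
    assignment: dict[str, int]  # read id -> cluster id (0-based, size-ordered)
    top_clusters: list[list[str]]  # member ids of the n_top largest clusters
    labels: dict[int, str] | None = None  # cluster id -> motif or "random"

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.top_clusters]


def featurize_reads(pool: ReadPool, max_lag: int = 24) -> FeatureTable:
    """One standardized feature row per read: composition | transitions | r(1..max_lag).

    Every read must be longer than ``max_lag``; offenders are listed in the
    error. Each column is z-scored across reads; zero-variance columns are
    left at 0 so constant features carry no weight.
    """
    short = [r.id for r in pool if len(r) <= max_lag]
    if short:
        raise ValueError(f"reads shorter than max_lag+1={max_lag + 1}: {short[:10]}")
    rows, ids = [], []
    for r in pool:
        comp = base_composition(r.sequence).fractions
        trans = transition_matrix(r.sequence).probabilities.copy()
        trans[np.isnan(trans)] = 0.25  # undefined rows -> uniform
        auto = autocorrelation_profile(r.sequence, max_lag).r[1:]
        rows.append(np.concatenate([comp, trans.ravel(), auto]))
        ids.append(r.id)
    X = np.asarray(rows)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf  # zero-variance columns stay at 0
    return FeatureTable((X - mu) / sd, ids, max_lag)


def hierarchical_top_clusters(features: FeatureTable, n_top: int = 7) -> ClusterResult:
    """Ward-linkage agglomerative clustering cut into ``n_top`` groups.

    Cluster ids are reassigned in decreasing size order (0 = largest); ties
    in size break toward the lower original index, so results are
    deterministic for a given input order.
    """
    n = len(features)
    if n < n_top:
        raise ValueError(f"need at least n_top={n_top} reads, got {n}")
    if n == 1:
        raw = np.array([1])
    else:
        Z = linkage(features.values, method="ward", metric="euclidean")
        raw = fcluster(Z, t=n_top, criterion="maxclust")
    order = sorted(
        np.unique(raw), key=lambda c: (-int(np.sum(raw == c)), int(np.min(np.where(raw == c)[0])))
    )
    remap = {c: i for i, c in enumerate(order)}
    assignment = {rid: remap[c] for rid, c in zip(features.read_ids, raw)}
    top: list[list[str]] = [[] for _ in range(len(order))]
    for rid, c in assignment.items():
        top[c].append(rid)
    return ClusterResult(assignment, top[:n_top])


def label_clusters(pool: ReadPool, result: ClusterResult, panel: MotifPanel | None = None) -> ClusterResult:
    """Label each top cluster with its majority motif, or "random".

    The label is the panel motif passing its copy threshold in the largest
    fraction of member reads, provided that fraction is >= 0.5; ties break to
    the lexicographically smaller canonical rotation.
    """
    panel = panel or MotifPanel()
    by_id = {r.id: r for r in pool}
    labels: dict[int, str] = {}
    for cid, members in enumerate(result.top_clusters):
        counts: dict[str, int] = {m: 0 for m in panel.motifs}
        for rid in members:
            for m in classify_read(by_id[rid].sequence, panel):
                counts[m] += 1
        top_count = max(counts.values())
        tied = [m for m in counts if counts[m] == top_count]
        # ties break to the lexicographically smaller canonical rotation
        best = min(tied, key=lambda m: (canonical_rotation(m), m))
        frac = counts[best] / len(members) if members else 0.0
        labels[cid] = best if frac >= 0.5 else "random"
    result.labels = labels
    return result


def cluster_pool_by_length(
    pool: ReadPool,
    panel: MotifPanel | None = None,
    split_length: int = 250,
    subsample: int = 500,
    n_top: int = 7,
    max_lag: int = 24,
    seed: int | None = None,
) -> dict[str, ClusterResult | None]:
    """Cluster reads <split_length and >=split_length separately.

    Each length class is subsampled (seeded, without replacement) to at most
    ``subsample`` reads before featurization. Classes with fewer than
    ``n_top`` usable reads return None.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, ClusterResult | None] = {}
    for name, pred in (
        ("short", lambda r: len(r) < split_length),
        ("long", lambda r: len(r) >= split_length),
    ):
        reads = [r for r in pool if pred(r) and len(r) > max_lag]
        if len(reads) > subsample:
            idx = rng.choice(len(reads), size=subsample, replace=False)
            reads = [reads[i] for i in sorted(idx)]
        if len(reads) < n_top:
            out[name] = None
            continue
        feats = featurize_reads(ReadPool(reads), max_lag=max_lag)
        result = hierarchical_top_clusters(feats, n_top=min(n_top, len(reads)))
        out[name] = label_clusters(ReadPool(reads), result, panel)
    return out


def assignments_frame(results: dict[str, ClusterResult | None]) -> pd.DataFrame:
    """Flatten per-length-class cluster assignments to a tidy table."""
    rows = []
    for length_class, res in results.items():
        if res is None:
            continue
        for rid, cid in res.assignment.items():
            label = res.labels.get(cid, "") if res.labels else ""
            rows.append(
                {"read_id": rid, "length_class": length_class, "cluster": cid, "label": label}
            )
    return pd.DataFrame(rows)
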