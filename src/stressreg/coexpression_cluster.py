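"""Co-expression clustering, cross-dataset consensus, and enrichment.

Each kept dataset's genes are partitioned into k groups (default 16) by
k-means on their expression profiles; the genes sharing the query gene's
cluster form that dataset's co-cluster set; genes co-clustering with the
query in at least ``min_support`` datasets form the consensus set, which is
tested for gene-set enrichment with a one-sided hypergeometric tail and
Benjamini-Hochberg correction.

K-means (Lloyd's algorithm with k-means++ seeding, Euclidean distance,
restarts, empty-cluster repair) is implemented here so that clustering is
deterministic given a seed and free of library version drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterAssignment",
    "ConsensusSet",
    "GeneSetCollection",
    "kmeans_cluster",
    "cluster_dataset",
    "cocluster_set",
    "consensus_genes",
    "hypergeom_enrich",
    "read_gmt",
]


@dataclass
class ClusterAssignment:
    dataset_id: str
    k: int
    gene_ids: list[str]
    labels: np.ndarray
    inertia: float
    seed: int
    n_iter: int
    inertia_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.gene_ids):
            raise ValueError("labels length must equal clustered-gene count")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.k:
            raise ValueError("cluster index out of range")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[i] = x[rng.integers(n)]
        else:
            centers[i] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((x - centers[i]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    x: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    k = centers.shape[0]
    history: list[float] = []
    labels = np.zeros(len(x), dtype=int)
    inertia = np.inf
    for it in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # repair empty clusters with the point farthest from its center
        for c in range(k):
            if not (labels == c).any():
                far = int(d2[np.arange(len(x)), labels].argmax())
                labels[far] = c
                d2[far, :] = np.inf
                d2[far, c] = 0.0
        new_inertia = float(d2[np.arange(len(x)), labels].sum())
        history.append(new_inertia)
        for c in range(k):
            centers[c] = x[labels == c].mean(axis=0)
        if np.isfinite(inertia) and inertia - new_inertia <= tol * max(inertia, 1e-12):
            inertia = new_inertia
            return labels, centers, inertia, it, history
        inertia = new_inertia
    return labels, centers, inertia, max_iter, history


def kmeans_cluster(
    matrix: np.ndarray,
    k: int = 16,
    seed: int = 1,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
    dataset_id: str = "",
    gene_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts.

    Deterministic given ``seed``; raises if the input has non-finite values
    or fewer distinct rows than k.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("matrix must be 2-D with >= 1 condition")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in clustering input")
    if len(np.unique(x, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers = _kmeanspp_init(x, k, rng)
        labels, _, inertia, n_iter, history = _lloyd(x, centers, max_iter, tol)
        if best is None or inertia < best[1]:
            best = (labels, inertia, n_iter, history)
    labels, inertia, n_iter, history = best
    if gene_ids is None:
        gene_ids = [str(i) for i in range(len(x))]
    return ClusterAssignment(
        dataset_id=dataset_id, k=k, gene_ids=list(gene_ids), labels=labels,
        inertia=inertia, seed=seed, n_iter=n_iter, inertia_history=history,
    )


def cluster_dataset(
    dataset,
    k: int = 16,
    seed: int = 1,
    max_missing_frac: float = 0.5,
    **kmeans_kwargs,
) -> ClusterAssignment:
    """Cluster an ExpressionDataset's genes on replicate-averaged values.

    Genes missing in more than ``max_missing_frac`` of conditions are
    dropped; remaining missing entries are imputed with the gene's row
    mean.  No standardization is applied.
    """
    vals = np.where(dataset.missing, np.nan, dataset.values)
    frac_missing = np.isnan(vals).mean(axis=1)
    keep = frac_missing <= max_missing_frac
    vals = vals[keep]
    genes = [g for g, kp in zip(dataset.gene_ids, keep) if kp]
    row_mean = np.nanmean(vals, axis=1)
    vals = np.where(np.isnan(vals), row_mean[:, None], vals)
    return kmeans_cluster(
        vals, k=k, seed=seed, dataset_id=dataset.dataset_id,
        gene_ids=genes, **kmeans_kwargs,
    )


def cocluster_set(assignment: ClusterAssignment, query_gene: str) -> set[str]:
    """Genes sharing the query's cluster, query excluded."""
    try:
        qi = assignment.gene_ids.index(query_gene)
    except ValueError:
        raise ValueError(
            f"query gene {query_gene!r} was not clustered "
            f"(dataset {assignment.dataset_id!r})"
        ) from None
    label = assignment.labels[qi]
    return {
        g for g, l in zip(assignment.gene_ids, assignment.labels)
        if l == label and g != query_gene
    }


@dataclass
class ConsensusSet:
    support: dict[str, int]
    min_support: int
    members: set[str]


def consensus_genes(sets: list[set[str]], min_support: int = 4) -> ConsensusSet:
    """Genes co-clustering with the query in >= min_support datasets."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not sets:
        raise ValueError("need at least one co-cluster set")
    support: dict[str, int] = {}
    for s in sets:
        for g in s:
            support[g] = support.get(g, 0) + 1
    members = {g for g, n in support.items() if n >= min_support}
    return ConsensusSet(support=support, min_support=min_support, members=members)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): term_id -> (description, genes)."""

    terms: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene list")


def read_gmt(path: str | Path) -> GeneSetCollection:
    terms: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: need term, description, genes")
        term, desc = fields[0], fields[1]
        genes = list(dict.fromkeys(g.strip().upper() for g in fields[2:] if g.strip()))
        if not genes:
            raise ValueError(f"{path}: line {lineno}: term {term!r} has no genes")
        terms[term] = (desc, genes)
    return GeneSetCollection(terms=terms)


def hypergeom_enrich(
    genes: set[str], background: set[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment with BH correction.

    Per term with K annotated genes in a background of N, drawing n query
    genes with overlap k: p = P(X >= k), X ~ Hypergeom(N, K, n).  Terms
    with no overlap are reported with p = 1.  Rows sorted by p ascending.
    """
    if not background:
        raise ValueError("empty background")
    if not genes:
        raise ValueError("empty query gene set")
    if not genes <= background:
        raise ValueError("query genes must be a subset of the background")
    n_bg = len(background)
    n_query = len(genes)
    rows = []
    for term, (desc, term_genes) in collection.terms.items():
        in_bg = set(term_genes) & background
        kk = len(in_bg & genes)
        pop_k = len(in_bg)
        p = float(hypergeom.sf(kk - 1, n_bg, pop_k, n_query)) if kk > 0 else 1.0
        rows.append((term, desc, n_bg, pop_k, n_query, kk, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term_id", "description", "N", "K", "n", "k", "p"]
    )
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    return df
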