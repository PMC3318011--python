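"""Comparative analyses on a corrected virtual array.

Covers the cell-identity analyses run once platforms are integrated and
batch-corrected: principal component analysis, agglomerative clustering with
unrooted-tree (newick) export, gene-signature subsetting, per-gene
Mann-Whitney group comparison, and the transcript-level marker positivity
caller (array-wide Q3 + 1.5×IQR threshold over per-gene medians).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import scipy.cluster.hierarchy
import scipy.spatial.distance
import dendropy
from sklearn.decomposition import PCA

from .integration import VirtualArray

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "ClusterTree",
    "MarkerCallTable",
    "run_pca",
    "hierarchical_cluster",
    "subset_signature",
    "mann_whitney_compare",
    "call_marker_positivity",
    "interpolated_quartiles",
]


# --------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    """PCA of samples on gene-centered expression.

    ``scores``: sample × component; ``loadings``: gene × component;
    ``explained_variance_fraction``: per-component fraction of total
    centered variance (non-increasing, sums to ≤ 1).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray


def run_pca(v: VirtualArray, n_components: int = 3) -> PcaResult:
    """PCA on gene-centered data with a deterministic sign convention.

    Samples are observations, genes features; each gene is centered across
    samples.  For every component the sign is chosen so that the
    largest-magnitude gene loading is positive.
    """
    if v.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    if n_components > min(v.n_genes, v.n_samples):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes={v.n_genes}, samples={v.n_samples})"
        )
    X = v.values.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=v.samples, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=v.genes, columns=comp_names),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


# --------------------------------------------------------------------------
# hierarchical clustering with unrooted-tree export


@dataclass
class ClusterTree:
    """Unrooted sample tree from agglomerative clustering.

    ``tree`` is a dendropy tree whose leaves are sample ids; ``merges``
    records the agglomeration order as (left leafset, right leafset, height)
    triples for auditing against oracles.
    """

    tree: dendropy.Tree
    merges: list[tuple[frozenset, frozenset, float]] = field(default_factory=list)

    @property
    def leaf_names(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, src: str) -> "ClusterTree":
        tree = dendropy.Tree.get(data=src, schema="newick")
        return cls(tree=tree)

    def has_split(self, labels: Sequence[str]) -> bool:
        """True if some edge of the unrooted tree separates ``labels`` from the rest.

        Used to check that a group of samples forms a pure subtree.
        """
        want = frozenset(labels)
        all_leaves = frozenset(self.leaf_names)
        if not want <= all_leaves:
            raise ValueError("labels are not all leaves of the tree")
        if len(want) in (1, len(all_leaves)):
            return True
        for edge in self.tree.preorder_edge_iter():
            head = edge.head_node
            if head is None:
                continue
            below = frozenset(lf.taxon.label for lf in head.leaf_iter())
            if below == want or (all_leaves - below) == want:
                return True
        return False


def hierarchical_cluster(
    v: VirtualArray,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of samples, exported as an unrooted tree.

    ``distance`` is ``correlation`` (1 − Pearson r between sample profiles)
    or ``euclidean``; ``linkage`` is ``average`` or ``complete``.  The rooted
    dendrogram is converted to an unrooted tree by suppressing the root
    (merging its two child edges), the convention for unrooted cluster-tree
    displays.
    """
    if v.n_samples < 3:
        raise ValueError("hierarchical clustering requires at least three samples")
    if distance not in ("correlation", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    X = v.values.to_numpy(dtype=float).T  # samples x genes
    if distance == "correlation":
        sds = X.std(axis=1)
        if np.any(sds == 0):
            bad = [v.samples[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(
                f"correlation distance undefined for constant sample(s): {bad}"
            )
    condensed = scipy.spatial.distance.pdist(X, metric=distance)
    Z = scipy.cluster.hierarchy.linkage(condensed, method=linkage)
    return _linkage_to_tree(Z, v.samples)


def _linkage_to_tree(Z: np.ndarray, sample_ids: Sequence[str]) -> ClusterTree:
    n = len(sample_ids)
    taxa = dendropy.TaxonNamespace([str(s) for s in sample_ids])
    nodes: dict[int, dendropy.Node] = {}
    heights: dict[int, float] = {}
    leafsets: dict[int, frozenset] = {}
    for i, s in enumerate(sample_ids):
        nd = dendropy.Node(taxon=taxa.get_taxon(str(s)))
        nodes[i] = nd
        heights[i] = 0.0
        leafsets[i] = frozenset([str(s)])
    merges = []
    for k, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        parent = dendropy.Node()
        for child in (a, b):
            nodes[child].edge.length = max(float(h) - heights[child], 0.0)
            parent.add_child(nodes[child])
        idx = n + k
        nodes[idx] = parent
        heights[idx] = float(h)
        leafsets[idx] = leafsets[a] | leafsets[b]
        merges.append((leafsets[a], leafsets[b], float(h)))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[n + len(Z) - 1]
    tree.is_rooted = False
    # suppress the root bifurcation so the tree is genuinely unrooted
    tree.collapse_basal_bifurcation()
    return ClusterTree(tree=tree, merges=merges)


# --------------------------------------------------------------------------
# signature subsetting


def subset_signature(
    v: VirtualArray, signature: Sequence[str]
) -> tuple[VirtualArray, dict]:
    """Restrict the array to signature genes present in it.

    Returns the subset plus a retrieval report (queried / retrieved / missing
    counts and the missing symbols).  Duplicate symbols in the signature are
    de-duplicated with a warning; retrieving zero genes is an error.
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    seen: list[str] = []
    dupes = 0
    for g in signature:
        if g in seen:
            dupes += 1
        else:
            seen.append(g)
    if dupes:
        logger.warning("signature contains %d duplicate symbol(s); de-duplicated", dupes)
    present = [g for g in seen if g in v.values.index]
    missing = [g for g in seen if g not in v.values.index]
    if not present:
        raise ValueError("none of the signature genes are present in the virtual array")
    report = {
        "queried": len(seen),
        "retrieved": len(present),
        "missing": len(missing),
        "missing_symbols": missing,
    }
    return v.subset_genes(present), report


# --------------------------------------------------------------------------
# Mann-Whitney group comparison


def _exact_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group assignments.

    Enumerates every way of choosing which pooled observations form the
    first group, computing U from midranks, so ties are handled exactly.
    The two-sided p-value is the null probability of a U at least as far
    from its mean n1·n2/2 as the observed one.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    combos = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    p = float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-9))
    return float(u_obs), p


def mann_whitney_compare(
    v: VirtualArray,
    group_key: str = "cell_type",
    critical_p: float = 0.01,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney U test between two sample groups.

    For group sizes both ≤ ``exact_max_n`` the exact null distribution of U
    is obtained by full enumeration (tie-exact); otherwise the normal
    approximation with tie correction is used.  A gene is significant when
    p < ``critical_p`` (default 0.01).

    Returns a DataFrame indexed by gene with columns ``U`` (first group's
    statistic), ``p``, ``significant``, and the two group medians.
    """
    groups = v.metadata[group_key].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"mann_whitney_compare requires exactly 2 groups, got {levels}")
    g1 = v.values.loc[:, groups[groups == levels[0]].index].to_numpy(dtype=float)
    g2 = v.values.loc[:, groups[groups == levels[1]].index].to_numpy(dtype=float)
    n1, n2 = g1.shape[1], g2.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least two samples")

    exact = max(n1, n2) <= exact_max_n
    U = np.empty(v.n_genes)
    P = np.empty(v.n_genes)
    if exact:
        for i in range(v.n_genes):
            U[i], P[i] = _exact_mwu(g1[i], g2[i])
    else:
        res = scipy.stats.mannwhitneyu(g1, g2, axis=1, alternative="two-sided",
                                       method="asymptotic")
        U[:] = res.statistic
        P[:] = res.pvalue
    out = pd.DataFrame(
        {
            "U": U,
            "p": P,
            "significant": P < critical_p,
            f"median_{levels[0]}": np.median(g1, axis=1),
            f"median_{levels[1]}": np.median(g2, axis=1),
        },
        index=v.values.index,
    )
    out.attrs["groups"] = levels
    out.attrs["exact"] = exact
    out.attrs["critical_p"] = critical_p
    return out


# --------------------------------------------------------------------------
# marker positivity calling


def interpolated_quartiles(values: np.ndarray) -> tuple[float, float]:
    """Q1 and Q3 by linear interpolation of order statistics (position 1+(n−1)p)."""
    q1, q3 = np.percentile(np.asarray(values, dtype=float), [25, 75],
                           method="linear")
    return float(q1), float(q3)


@dataclass
class MarkerCallTable:
    """Per-gene positivity calls against an array-wide outlier threshold.

    ``table`` has columns ``median_level`` and ``call`` ('+'/'−');
    ``threshold`` is the array-wide scalar Q3 + 1.5×IQR over per-gene
    medians; ``missing`` lists requested genes absent from the array.
    """

    table: pd.DataFrame
    threshold: float
    missing: list[str] = field(default_factory=list)

    @property
    def positive_genes(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "+"])

    @property
    def n_positive(self) -> int:
        return int((self.table["call"] == "+").sum())


def call_marker_positivity(
    v: VirtualArray,
    genes_of_interest: Optional[Sequence[str]] = None,
) -> MarkerCallTable:
    """Call genes transcriptionally positive or negative.

    A gene's level is its median across the array's samples.  The threshold
    is computed array-wide from the distribution of *all* per-gene medians:
    Q3 + 1.5×IQR with quartiles by linear interpolation.  A gene is positive
    iff its median exceeds the threshold (strict).  Requested genes absent
    from the array are reported in ``missing`` rather than called.
    """
    if v.n_genes == 0 or v.n_samples == 0:
        raise ValueError("cannot call positivity on an empty array")
    medians = v.values.median(axis=1)
    q1, q3 = interpolated_quartiles(medians.to_numpy())
    threshold = q3 + 1.5 * (q3 - q1)
    if genes_of_interest is None:
        wanted = list(v.values.index)
        missing: list[str] = []
    else:
        wanted = [g for g in genes_of_interest if g in v.values.index]
        missing = [g for g in genes_of_interest if g not in v.values.index]
        if missing:
            logger.warning("positivity: %d requested gene(s) absent from array: %s",
                           len(missing), ",".join(missing))
    med = medians.loc[wanted]
    table = pd.DataFrame(
        {
            "median_level": med,
            "call": np.where(med > threshold, "+", "−"),
        },
        index=pd.Index(wanted, name="gene"),
    )
    return MarkerCallTable(table=table, threshold=float(threshold), missing=missing)
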