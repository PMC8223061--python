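"""qPCR delta-Ct classification by hierarchical clustering with bootstrap support.

For a small clinical cohort assayed by qPCR on a reduced gene panel, samples
are classified without refitting any supervised model: cycle thresholds are
normalized to a reference gene (dCt = Ct(gene) - Ct(reference); lower dCt =
higher relative expression), samples are clustered agglomeratively on
Euclidean distances between dCt profiles under the Ward criterion in its
"ward.D2" convention (squared distances inside the objective, merge heights
reported on the distance scale), and cluster stability is quantified by an
ordinary bootstrap over genes: each replicate resamples the gene rows with
replacement, reclusters, and a node's support is the fraction of replicates
in which its exact leaf set reappears as a cluster (a bootstrap proportion,
BP — not the approximately-unbiased multiscale variant). Unknown samples
inherit the majority class of the smallest enclosing cluster that contains
at least one labeled sample; exact ties are reported as unresolved, never
guessed.

The agglomeration is written out explicitly (Lance-Williams recurrence on
squared Euclidean distances) so the merge order is fully pinned down: ties
are broken by the lexicographically smallest pair of cluster indices, which
makes dendrograms reproducible bit-for-bit across platforms. With a handful
of genes the bootstrap is low-resolution; reports label support values "BP"
and record the number of genes resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import CtTable, SubgroupLabels

__all__ = [
    "DctMatrix",
    "DendrogramWithSupport",
    "compute_dct",
    "hierarchical_cluster",
    "bootstrap_support",
    "assign_unknowns",
    "to_newick",
]


@dataclass
class DctMatrix:
    """Reference-normalized qPCR expression: dct(g, s) = Ct(g,s) - Ct(ref,s)."""

    data: pd.DataFrame  # genes x samples, reference gene excluded

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DendrogramWithSupport:
    """Sample dendrogram in scipy linkage convention plus bootstrap support.

    ``merges[i] = (a, b)`` merges clusters ``a`` and ``b`` (ids < n are
    leaves in ``sample_ids`` order; id ``n + i`` is the cluster created by
    merge ``i``) at height ``heights[i]``. ``support`` maps internal node id
    to its bootstrap proportion once :func:`bootstrap_support` has run.
    """

    sample_ids: list[str]
    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) float, non-decreasing
    support: dict[int, float] | None = None
    nboot: int | None = None
    seed: int | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Leaf-name set of every node (leaves and internal)."""
        n = self.n_leaves
        sets: dict[int, frozenset[str]] = {
            i: frozenset([s]) for i, s in enumerate(self.sample_ids)
        }
        for i, (a, b) in enumerate(self.merges):
            sets[n + i] = sets[int(a)] | sets[int(b)]
        return sets

    def clusters(self) -> set[frozenset[str]]:
        """The set of internal-node leaf sets (used for bootstrap matching)."""
        n = self.n_leaves
        return {ls for node, ls in self.leaf_sets().items() if node >= n}


def compute_dct(ct: CtTable) -> DctMatrix:
    """Subtract the reference gene's Ct per sample and drop its row."""
    ref = ct.data.loc[ct.reference_gene]
    dct = ct.data.drop(index=ct.reference_gene).subtract(ref, axis=1)
    if dct.isna().to_numpy().any():
        g, s = np.argwhere(dct.isna().to_numpy())[0]
        raise ValueError(
            f"missing Ct at gene {dct.index[g]!r}, sample {dct.columns[s]!r}; "
            "resolve undetermined wells at read time"
        )
    if dct.shape[0] == 0:
        raise ValueError("Ct table contains only the reference gene")
    return DctMatrix(dct)


def _ward_agglomerate(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ward.D2 agglomeration of row vectors with a pinned tie rule.

    Lance-Williams recurrence on squared Euclidean distances:

        d2(k, i+j) = ((n_i + n_k) d2(k,i) + (n_j + n_k) d2(k,j)
                      - n_k d2(i,j)) / (n_i + n_j + n_k)

    Merge heights are sqrt(d2) (the distance scale; two singletons merge at
    their Euclidean distance). At each step the pair with minimal d2 is
    merged; exact ties go to the lexicographically smallest (id_a, id_b).
    """
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    diff = x[:, None, :] - x[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    pos = {i: i for i in range(n)}  # cluster id -> row in d2 workspace
    merges = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1, dtype=float)
    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for ii, a in enumerate(ids):
            for b in ids[ii + 1:]:
                d = d2[pos[a], pos[b]]
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d_ab, a, b = best
        merges[step] = (a, b)
        heights[step] = np.sqrt(max(d_ab, 0.0))
        new_id = n + step
        na, nb = active[a], active[b]
        ra, rb = pos[a], pos[b]
        # update distances from every other cluster to the merged one, in place
        for c in ids:
            if c in (a, b):
                continue
            nc = active[c]
            rc = pos[c]
            d2[ra, rc] = d2[rc, ra] = (
                (na + nc) * d2[rc, ra] + (nb + nc) * d2[rc, rb] - nc * d_ab
            ) / (na + nb + nc)
        del active[a], active[b], pos[a], pos[b]
        active[new_id] = na + nb
        pos[new_id] = ra
    return merges, heights


def hierarchical_cluster(d: DctMatrix) -> DendrogramWithSupport:
    """Cluster samples on Euclidean dCt distances with Ward.D2 linkage."""
    x = d.data.to_numpy().T  # samples x genes
    merges, heights = _ward_agglomerate(x)
    return DendrogramWithSupport(
        sample_ids=list(d.sample_ids), merges=merges, heights=heights
    )


def bootstrap_support(
    d: DctMatrix, nboot: int = 1000, seed: int = 0
) -> DendrogramWithSupport:
    """Attach gene-resampling bootstrap proportions to the dendrogram.

    Each of ``nboot`` replicates draws genes (rows) with replacement,
    reclusters the samples, and every internal node of the reference tree
    scores a hit when its exact leaf set appears among the replicate's
    clusters. The root is the all-sample cluster of every replicate, so its
    support is 1 by construction.
    """
    if nboot < 1:
        raise ValueError("nboot must be >= 1")
    n_genes = d.data.shape[0]
    if n_genes < 2:
        raise ValueError("bootstrap over genes needs at least 2 genes")
    reference = hierarchical_cluster(d)
    n = reference.n_leaves
    node_sets = {
        node: ls for node, ls in reference.leaf_sets().items() if node >= n
    }
    hits = {node: 0 for node in node_sets}
    rng = np.random.default_rng(seed)
    values = d.data.to_numpy()
    for _ in range(nboot):
        rows = rng.integers(0, n_genes, size=n_genes)
        rep = DctMatrix(
            pd.DataFrame(values[rows], columns=d.sample_ids)
        )
        rep_clusters = hierarchical_cluster(rep).clusters()
        for node, ls in node_sets.items():
            if ls in rep_clusters:
                hits[node] += 1
    support = {node: hits[node] / nboot for node in node_sets}
    return replace(reference, support=support, nboot=nboot, seed=seed)


def assign_unknowns(
    dend: DendrogramWithSupport,
    known: SubgroupLabels,
    unknown: Sequence[str],
) -> dict[str, dict[str, object]]:
    """Assign each unknown sample the majority class of its smallest
    enclosing cluster that contains at least one labeled sample.

    Returns ``{sample: {"assigned": class or None, "confidence": bootstrap
    support of the deciding cluster (None if support was not computed),
    "resolved": bool, "cluster_size": int}}``. A tied majority is reported
    as unresolved (``assigned=None``).
    """
    overlap = set(known.assignments) & set(unknown)
    if overlap:
        raise ValueError(f"samples both known and unknown: {sorted(overlap)}")
    in_tree = set(dend.sample_ids)
    missing = [s for s in unknown if s not in in_tree]
    if missing:
        raise KeyError(f"unknown sample(s) absent from the dendrogram: {missing}")
    for cls in known.classes:
        if not any(s in in_tree for s in known.samples_of(cls)):
            raise ValueError(f"class {cls!r} has no labeled sample in the tree")

    n = dend.n_leaves
    leaf_sets = dend.leaf_sets()
    # internal nodes in merge order are already sorted small-to-large height;
    # for each unknown walk the node list from the first (lowest) enclosing node up
    internal = [(n + i, leaf_sets[n + i]) for i in range(len(dend.merges))]
    results: dict[str, dict[str, object]] = {}
    for s in unknown:
        decided = None
        for node, ls in internal:  # heights non-decreasing => smallest first
            if s not in ls:
                continue
            labeled = [known.assignments[t] for t in ls if t in known.assignments]
            if not labeled:
                continue
            counts = pd.Series(labeled).value_counts()
            top = counts[counts == counts.max()]
            assigned = top.index[0] if len(top) == 1 else None
            conf = dend.support.get(node) if dend.support is not None else None
            decided = {
                "assigned": assigned,
                "confidence": float(conf) if conf is not None else None,
                "resolved": assigned is not None,
                "cluster_size": len(ls),
            }
            break
        if decided is None:  # no labeled sample anywhere (cannot happen if known non-empty)
            decided = {
                "assigned": None,
                "confidence": None,
                "resolved": False,
                "cluster_size": 0,
            }
        results[s] = decided
    return results


def to_newick(dend: DendrogramWithSupport) -> str:
    """Serialize the dendrogram as newick; internal node labels carry the
    bootstrap proportion (when computed) and branch lengths derive from
    merge heights."""
    n = dend.n_leaves
    heights = {n + i: float(h) for i, h in enumerate(dend.heights)}
    for i in range(n):
        heights[i] = 0.0

    def node_str(node: int, parent_height: float) -> str:
        length = max(parent_height - heights[node], 0.0)
        if node < n:
            return f"{dend.sample_ids[node]}:{length:.6g}"
        i = node - n
        a, b = (int(v) for v in dend.merges[i])
        inner = ",".join(node_str(c, heights[node]) for c in (a, b))
        label = ""
        if dend.support is not None and node in dend.support:
            label = f"{dend.support[node]:.3f}"
        return f"({inner}){label}:{length:.6g}"

    root = n + len(dend.merges) - 1
    a, b = (int(v) for v in dend.merges[-1])
    inner = ",".join(node_str(c, heights[root]) for c in (a, b))
    label = f"{dend.support[root]:.3f}" if dend.support else ""
    return f"({inner}){label};"
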