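"""Genomic annotations -> sparse connectivity masks.

Every "visible" layer in this package is defined by a :class:`ConnectivityMask`:
a binary incidence structure between named input units and named output units.
This module derives those masks from the two kinds of prior knowledge the
networks use:

* CpG -> gene annotation by nearest transcription start site (TSS), the
  methylation gene layer;
* a three-level pathway hierarchy (local -> mid -> global), the pathway layers,
  with skip connections to the output for genes that carry no pathway
  annotation so that every gene keeps a route to the prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CpGSite",
    "GeneRegion",
    "CpGGeneMap",
    "PathwayHierarchy",
    "ConnectivityMask",
    "AnnotationSet",
    "map_cpgs_to_genes",
    "intersect_gene_sets",
    "build_gene_mask",
    "build_pathway_masks",
]


@dataclass(frozen=True)
class CpGSite:
    """A methylation site: 1-based genomic position of the interrogated CpG."""

    cpg_id: str
    chrom: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"CpG {self.cpg_id!r}: position must be >= 1 (1-based), got {self.position}"
            )


@dataclass(frozen=True)
class GeneRegion:
    """A gene anchored at its TSS; strand is kept for provenance only."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(
                f"gene {self.gene_id!r}: tss must be >= 1 (1-based), got {self.tss}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")


@dataclass
class CpGGeneMap:
    """One-to-one assignment of CpGs to their nearest gene.

    ``pairs`` maps cpg_id -> gene_id and ``distance`` maps cpg_id -> |pos - tss|
    in base pairs. ``dropped`` lists CpGs on chromosomes without any gene.
    """

    pairs: dict[str, str]
    distance: dict[str, int]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.pairs) != set(self.distance):
            raise ValueError("pairs and distance must cover the same CpGs")
        for c, d in self.distance.items():
            if d < 0:
                raise ValueError(f"negative distance for CpG {c!r}")

    def genes(self) -> set[str]:
        return set(self.pairs.values())


@dataclass
class PathwayHierarchy:
    """Three-level pathway forest: gene -> local -> mid -> global.

    ``membership`` maps gene_id to the set of local pathways it belongs to (a
    gene may belong to zero, one or many); ``parent`` maps every local pathway
    to its mid-level parent and every mid-level pathway to its global parent.
    """

    membership: dict[str, set[str]]
    parent: dict[str, str]
    levels: tuple[str, ...] = ("local", "mid", "global")

    def __post_init__(self) -> None:
        locals_ = self.local_ids()
        mids = self.mid_ids()
        for lp in locals_:
            if lp not in self.parent:
                raise ValueError(f"local pathway {lp!r} has no mid-level parent")
        for m in mids:
            if m not in self.parent:
                raise ValueError(f"mid pathway {m!r} has no global-level parent")
            if m in locals_:
                raise ValueError(f"pathway {m!r} appears at both local and mid level")

    def local_ids(self) -> list[str]:
        return sorted({p for ps in self.membership.values() for p in ps})

    def mid_ids(self) -> list[str]:
        return sorted({self.parent[p] for p in self.local_ids()})

    def global_ids(self) -> list[str]:
        return sorted({self.parent[m] for m in self.mid_ids()})


@dataclass
class ConnectivityMask:
    """Sparse binary incidence matrix between named units of one layer.

    ``edges`` is an (E, 2) integer array of (in_index, out_index) pairs; the
    optional ``tags`` array labels each edge with its source omic (or other
    grouping) and drives omic-specific L1 and omic decomposition downstream.
    """

    in_ids: list[str]
    out_ids: list[str]
    edges: np.ndarray
    tags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        n_in, n_out = len(self.in_ids), len(self.out_ids)
        if self.n_edges:
            if self.edges[:, 0].min() < 0 or self.edges[:, 0].max() >= n_in:
                raise ValueError("edge in_index out of range")
            if self.edges[:, 1].min() < 0 or self.edges[:, 1].max() >= n_out:
                raise ValueError("edge out_index out of range")
        keys = self.edges[:, 0] * max(n_out, 1) + self.edges[:, 1]
        if len(np.unique(keys)) != self.n_edges:
            raise ValueError("duplicate edges in mask")
        if self.tags is not None:
            self.tags = np.asarray(self.tags, dtype=object)
            if len(self.tags) != self.n_edges:
                raise ValueError("tags length must equal edge count")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.in_ids), len(self.out_ids))

    def in_degree(self) -> np.ndarray:
        """Outgoing-edge count per input unit."""
        return np.bincount(self.edges[:, 0], minlength=len(self.in_ids))

    def out_degree(self) -> np.ndarray:
        """Incoming-edge count per output unit."""
        return np.bincount(self.edges[:, 1], minlength=len(self.out_ids))

    def to_sparse(self, data: np.ndarray | None = None):
        """COO pattern matrix (in x out); `data` fills edge values if given."""
        from scipy import sparse

        vals = np.ones(self.n_edges) if data is None else np.asarray(data, float)
        return sparse.coo_matrix(
            (vals, (self.edges[:, 0], self.edges[:, 1])), shape=self.shape
        )

    @classmethod
    def dense(cls, in_ids: list[str], out_ids: list[str]) -> "ConnectivityMask":
        """Complete-bipartite mask: a fully connected layer."""
        ii, oo = np.meshgrid(
            np.arange(len(in_ids)), np.arange(len(out_ids)), indexing="ij"
        )
        return cls(list(in_ids), list(out_ids), np.column_stack([ii.ravel(), oo.ravel()]))

    def save(self, path) -> None:
        tags = self.tags if self.tags is not None else np.array([], dtype=object)
        np.savez_compressed(
            path,
            in_ids=np.asarray(self.in_ids, dtype=object),
            out_ids=np.asarray(self.out_ids, dtype=object),
            edges=self.edges,
            tags=tags.astype(str) if len(tags) else np.array([], dtype=str),
        )

    @classmethod
    def load(cls, path) -> "ConnectivityMask":
        with np.load(path, allow_pickle=True) as z:
            tags = z["tags"]
            return cls(
                in_ids=[str(x) for x in z["in_ids"]],
                out_ids=[str(x) for x in z["out_ids"]],
                edges=z["edges"],
                tags=tags.astype(object) if len(tags) else None,
            )


@dataclass
class AnnotationSet:
    """Bundle of all prior knowledge a network build needs."""

    cpgs: list[CpGSite]
    genes: list[GeneRegion]
    hierarchy: PathwayHierarchy | None = None


def map_cpgs_to_genes(
    cpgs: list[CpGSite],
    genes: list[GeneRegion],
    max_distance: int | None = None,
) -> CpGGeneMap:
    """Assign every CpG to the gene with the nearest TSS on its chromosome.

    Distance is |position - tss| in base pairs. Ties are broken toward the gene
    with the smaller TSS, then the lexicographically smaller gene_id, so the
    assignment is deterministic. CpGs on chromosomes without any gene (or
    farther than ``max_distance``, if given) are dropped and listed in
    ``CpGGeneMap.dropped``.
    """
    if not genes:
        raise ValueError("gene list is empty: cannot annotate CpGs")
    seen: set[str] = set()
    for c in cpgs:
        if c.cpg_id in seen:
            raise ValueError(f"duplicate cpg_id {c.cpg_id!r}")
        seen.add(c.cpg_id)

    by_chrom: dict[str, list[GeneRegion]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    # Sorting by (tss, gene_id) and deduplicating equal-TSS runs keeps exactly
    # the tie-winning gene at every position, so the left neighbour wins ties.
    sorted_chrom: dict[str, tuple[np.ndarray, list[GeneRegion]]] = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        dedup = [g for k, g in enumerate(gs) if k == 0 or g.tss != gs[k - 1].tss]
        sorted_chrom[chrom] = (np.array([g.tss for g in dedup]), dedup)

    pairs: dict[str, str] = {}
    distance: dict[str, int] = {}
    dropped: list[str] = []
    for c in cpgs:
        if c.chrom not in sorted_chrom:
            dropped.append(c.cpg_id)
            continue
        tss, gs = sorted_chrom[c.chrom]
        j = int(np.searchsorted(tss, c.position))
        best: GeneRegion | None = None
        best_d = None
        # candidates: nearest on the left (and any same-tss runs) and right
        for k in (j - 1, j):
            if 0 <= k < len(gs):
                d = abs(c.position - gs[k].tss)
                if (
                    best_d is None
                    or d < best_d
                    or (d == best_d and (gs[k].tss, gs[k].gene_id) < (best.tss, best.gene_id))
                ):
                    best, best_d = gs[k], d
        # searchsorted returns the leftmost slot, so gs[j] may tie with gs[j-1]
        # at equal distance; equal-TSS duplicates left of j-1 cannot win because
        # sorting already put the lexicographically smallest first.
        if max_distance is not None and best_d > max_distance:
            dropped.append(c.cpg_id)
            continue
        pairs[c.cpg_id] = best.gene_id
        distance[c.cpg_id] = int(best_d)
    if dropped:
        logger.info("map_cpgs_to_genes: dropped %d CpGs without a gene", len(dropped))
    return CpGGeneMap(pairs=pairs, distance=distance, dropped=dropped)


def intersect_gene_sets(me_genes: set[str], ge_genes: set[str]) -> list[str]:
    """Sorted intersection of the two omics' gene sets.

    The returned ordering is THE gene-node ordering for every downstream mask,
    weight vector and report.
    """
    if not me_genes or not ge_genes:
        raise ValueError("both gene sets must be nonempty")
    overlap = sorted(set(me_genes) & set(ge_genes))
    if not overlap:
        raise ValueError("gene sets have empty intersection: no shared genes")
    return overlap


def build_gene_mask(
    cpg_map: CpGGeneMap, gene_order: list[str], cpg_order: list[str]
) -> ConnectivityMask:
    """CpG -> gene incidence: exactly one outgoing edge per retained CpG.

    CpGs whose nearest gene is not in ``gene_order`` (e.g. outside the omics
    intersection) are excluded, with a logged count. Genes left without any CpG
    are flagged with a warning but keep their (empty) column so that the gene
    ordering stays canonical.
    """
    gene_pos = {g: j for j, g in enumerate(gene_order)}
    kept_cpgs: list[str] = []
    edges: list[tuple[int, int]] = []
    n_excluded = 0
    for cpg in cpg_order:
        if cpg not in cpg_map.pairs:
            raise ValueError(f"CpG {cpg!r} missing from the CpG->gene map")
        g = cpg_map.pairs[cpg]
        if g not in gene_pos:
            n_excluded += 1
            continue
        edges.append((len(kept_cpgs), gene_pos[g]))
        kept_cpgs.append(cpg)
    if n_excluded:
        logger.info(
            "build_gene_mask: excluded %d CpGs mapping to genes outside the "
            "intersection (%d retained)", n_excluded, len(kept_cpgs),
        )
    mask = ConnectivityMask(kept_cpgs, list(gene_order), np.array(edges, dtype=np.int64))
    empty = [gene_order[j] for j, d in enumerate(mask.out_degree()) if d == 0]
    if empty:
        warnings.warn(
            f"{len(empty)} gene(s) have no annotated CpG: {empty[:5]}...", stacklevel=2
        )
    return mask


def build_pathway_masks(
    hierarchy: PathwayHierarchy, gene_order: list[str]
) -> tuple[ConnectivityMask, ConnectivityMask, ConnectivityMask, ConnectivityMask]:
    """Masks for the three pathway layers plus the skip mask.

    Returns ``(gene->local, local->mid, mid->global, skip gene->output)``.
    Pathways with no member gene after restriction to ``gene_order`` are dropped
    with a warning. Genes with no surviving local-pathway membership get one
    skip edge straight to the output node, so every gene keeps a path to the
    prediction; pathway-routed and skip genes partition ``gene_order``.
    """
    gene_set = set(gene_order)
    membership = {
        g: set(ps) for g, ps in hierarchy.membership.items() if g in gene_set and ps
    }
    local_alive = sorted({p for ps in membership.values() for p in ps})
    dropped_local = set(hierarchy.local_ids()) - set(local_alive)
    if dropped_local:
        warnings.warn(
            f"{len(dropped_local)} local pathway(s) have no member gene and were dropped",
            stacklevel=2,
        )
    mid_alive = sorted({hierarchy.parent[p] for p in local_alive})
    global_alive = sorted({hierarchy.parent[m] for m in mid_alive})

    lpos = {p: i for i, p in enumerate(local_alive)}
    mpos = {p: i for i, p in enumerate(mid_alive)}
    gpos = {p: i for i, p in enumerate(global_alive)}

    g2l = [
        (i, lpos[p])
        for i, g in enumerate(gene_order)
        for p in sorted(membership.get(g, ()))
    ]
    l2m = [(lpos[p], mpos[hierarchy.parent[p]]) for p in local_alive]
    m2g = [(mpos[m], gpos[hierarchy.parent[m]]) for m in mid_alive]
    skip = [(i, 0) for i, g in enumerate(gene_order) if g not in membership]

    def _mk(in_ids, out_ids, e):
        arr = np.array(e, dtype=np.int64) if e else np.empty((0, 2), dtype=np.int64)
        return ConnectivityMask(list(in_ids), list(out_ids), arr)

    return (
        _mk(gene_order, local_alive, g2l),
        _mk(local_alive, mid_alive, l2m),
        _mk(mid_alive, global_alive, m2g),
        _mk(gene_order, ["output"], skip),
    )
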