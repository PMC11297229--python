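"""Contribution scores and activation-pattern analysis for trained networks.

The importance of an input is the sum, over every path from that input to the
output, of the product of the absolute edge weights along the path,
normalized so the scores of all inputs sum to one. Because the layer graph is
acyclic, the path sum is computed by dynamic programming (one backward sweep
accumulating path products) rather than path enumeration; the two are
algebraically identical. Hidden-node scores redistribute the input
proportions forward along the same absolute-weight paths and are normalized
within each layer. Biases play no role: only weights define importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .vnn_core import ModelState, NetworkEngine, NetworkSpec

__all__ = [
    "ContributionReport",
    "ActivationEmbedding",
    "input_contributions",
    "node_contributions",
    "gene_omic_split",
    "aggregate_over_seeds",
    "activation_pca",
    "compute_report",
]


@dataclass
class ContributionReport:
    """Normalized contribution proportions from one trained model."""

    input_scores: pd.Series
    node_scores: dict[str, pd.Series]
    gene_omic_split: pd.DataFrame
    metadata: dict = field(default_factory=dict)


@dataclass
class ActivationEmbedding:
    """PCA of per-sample hidden activations at the gene-level layer."""

    sample_ids: list
    scores: np.ndarray            # samples x k
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame        # node x component


def _abs_weight_sparse(layer, w):
    return layer.mask.to_sparse(np.abs(w)).tocsr()


def _backward_path_mass(state: ModelState, spec: NetworkSpec, engine: NetworkEngine) -> np.ndarray:
    """r[u] = sum over u->output paths of the product of |w| along the path."""
    r = np.zeros(engine.n_units)
    r[engine.output_col] = 1.0
    for L, w in zip(reversed(engine._layers), reversed(state.weights)):
        W = _abs_weight_sparse(L["spec"], w)
        r[L["in_idx"]] += W @ r[L["out_idx"]]
    return r


def _forward_path_mass(
    engine: NetworkEngine, state: ModelState, seed_values: np.ndarray
) -> np.ndarray:
    """f[u] = sum over inputs i, paths i->u of seed[i] * product |w|."""
    f = seed_values.copy()
    for L, w in zip(engine._layers, state.weights):
        W = _abs_weight_sparse(L["spec"], w)
        f[L["out_idx"]] += W.T @ f[L["in_idx"]]
    return f


def _input_cols(spec: NetworkSpec, engine: NetworkEngine) -> tuple[list[str], np.ndarray]:
    ids = [u for ids in spec.input_blocks.values() for u in ids]
    return ids, np.array([engine.unit_index[u] for u in ids])


def input_contributions(
    state: ModelState, spec: NetworkSpec, engine: NetworkEngine | None = None
) -> pd.Series:
    """Per-input proportion of total absolute-weight path-product mass.

    Raises if every path product is zero (a fully dead network), since
    proportions are then undefined — inspect the training run instead.
    """
    engine = engine or NetworkEngine(spec)
    r = _backward_path_mass(state, spec, engine)
    ids, cols = _input_cols(spec, engine)
    raw = r[cols]
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            "all absolute-weight path products are zero; contributions undefined "
            "(check that training produced nonzero weights)"
        )
    return pd.Series(raw / total, index=ids, name="contribution")


def node_contributions(
    state: ModelState, spec: NetworkSpec, layer: str, engine: NetworkEngine | None = None
) -> pd.Series:
    """Hidden-node proportions within one layer.

    Each input's final proportion is pushed forward along the absolute-weight
    paths reaching the layer's nodes; node scores are normalized within the
    layer so they sum to one.
    """
    engine = engine or NetworkEngine(spec)
    props = input_contributions(state, spec, engine)
    seed = np.zeros(engine.n_units)
    ids, cols = _input_cols(spec, engine)
    seed[cols] = props.to_numpy()
    f = _forward_path_mass(engine, state, seed)
    ly = spec.layer(layer)
    out_cols = np.array([engine.unit_index[u] for u in ly.mask.out_ids])
    raw = f[out_cols]
    total = raw.sum()
    if total <= 0:
        raise ValueError(f"layer {layer!r} receives zero path mass")
    names = [u.split(":", 1)[1] if ":" in u else u for u in ly.mask.out_ids]
    return pd.Series(raw / total, index=names, name=f"{layer}_contribution")


def gene_omic_split(
    state: ModelState,
    spec: NetworkSpec,
    layer: str = "gene",
    engine: NetworkEngine | None = None,
) -> pd.DataFrame:
    """Per-gene partition of incoming path mass by omic tag.

    For each combined gene node, the absolute-weight path mass arriving
    through each tagged incoming edge (methylation node vs expression input
    vs covariate) is summed per tag and normalized per gene. Genes receiving
    zero mass get NaN fractions and are listed in ``df.attrs['zero_mass']``.
    """
    engine = engine or NetworkEngine(spec)
    ly = spec.layer(layer)
    if ly.mask.tags is None:
        raise ValueError(f"layer {layer!r} has no omic tags")
    seed = np.zeros(engine.n_units)
    _, cols = _input_cols(spec, engine)
    seed[cols] = 1.0
    f = _forward_path_mass(engine, state, seed)
    li = [i for i, L in enumerate(engine._layers) if L["spec"] is ly][0]
    w = state.weights[li]
    src_units = np.array([engine.unit_index[ly.mask.in_ids[i]] for i in ly.mask.edges[:, 0]])
    mass = np.abs(w) * f[src_units]

    tags = sorted(set(ly.mask.tags))
    genes = [u.split(":", 1)[1] for u in ly.mask.out_ids]
    out = np.zeros((len(genes), len(tags)))
    for k, t in enumerate(tags):
        sel = ly.mask.tags == t
        np.add.at(out[:, k], ly.mask.edges[sel, 1], mass[sel])
    totals = out.sum(axis=1)
    zero = totals <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = out / totals[:, None]
    frac[zero] = np.nan
    df = pd.DataFrame(frac, index=genes, columns=tags)
    df.attrs["zero_mass"] = [g for g, z in zip(genes, zero) if z]
    return df


def aggregate_over_seeds(reports: list[ContributionReport], layer: str | None = None):
    """Mean and sd of contribution scores across seed replicates.

    With ``layer=None`` the input scores are aggregated; otherwise that
    layer's node scores. Returns a DataFrame with columns ``mean`` and ``sd``
    (population sd over replicates, as reported in per-gene error bars).
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    series = [
        r.input_scores if layer is None else r.node_scores[layer] for r in reports
    ]
    mat = pd.concat(series, axis=1)
    if mat.isna().any().any():
        raise ValueError("reports do not share the same score index")
    return pd.DataFrame({"mean": mat.mean(axis=1), "sd": mat.std(axis=1, ddof=0)})


def omic_shares(
    state: ModelState,
    spec: NetworkSpec,
    layer: str = "gene",
    engine: NetworkEngine | None = None,
) -> pd.Series:
    """Aggregate share of each omic across the whole network.

    Per-gene omic fractions weighted by that gene node's contribution and
    summed, i.e. the proportion of total gene-layer path mass arriving
    through each omic tag. Sums to one over the tags.
    """
    engine = engine or NetworkEngine(spec)
    nodes = node_contributions(state, spec, layer, engine)
    split = gene_omic_split(state, spec, layer, engine)
    ok = ~split.isna().any(axis=1)
    shares = split[ok].mul(nodes[split.index[ok]], axis=0).sum(axis=0)
    total = shares.sum()
    if total <= 0:
        raise ValueError("zero total omic mass")
    return shares / total


def compute_report(
    state: ModelState,
    spec: NetworkSpec,
    node_layers: tuple[str, ...] = ("gene",),
    omic_layer: str | None = "gene",
    engine: NetworkEngine | None = None,
) -> ContributionReport:
    """Full contribution report: inputs, selected hidden layers, omic split."""
    engine = engine or NetworkEngine(spec)
    layer_names = {l.name for l in spec.layers}
    node_scores = {
        ln: node_contributions(state, spec, ln, engine)
        for ln in node_layers
        if ln in layer_names
    }
    if omic_layer in layer_names and spec.layer(omic_layer).mask.tags is not None:
        split = gene_omic_split(state, spec, omic_layer, engine)
    else:
        split = pd.DataFrame()
    return ContributionReport(
        input_scores=input_contributions(state, spec, engine),
        node_scores=node_scores,
        gene_omic_split=split,
        metadata=dict(state.metadata),
    )


def activation_pca(
    state: ModelState,
    spec: NetworkSpec,
    inputs: dict[str, np.ndarray],
    k: int = 2,
    layer: str = "gene",
    sample_ids: list | None = None,
    engine: NetworkEngine | None = None,
) -> ActivationEmbedding:
    """PCA over the per-sample activations of the gene-level nodes.

    Samples with similar activation patterns cluster in the leading
    components; a planted group structure (e.g. a sex-linked gene block)
    shows up as separated clusters.
    """
    engine = engine or NetworkEngine(spec)
    theta = engine.pack(state)
    _, (U, _) = engine.forward(theta, inputs, cache=True)
    ly = spec.layer(layer)
    cols = np.array([engine.unit_index[u] for u in ly.mask.out_ids])
    A = U[:, cols]
    if np.allclose(A.std(axis=0), 0):
        raise ValueError(f"activations of layer {layer!r} are constant; PCA undefined")
    k = min(k, A.shape[1], A.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(A - A.mean(axis=0))
    names = [u.split(":", 1)[1] for u in ly.mask.out_ids]
    return ActivationEmbedding(
        sample_ids=list(sample_ids) if sample_ids is not None else list(range(len(A))),
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(
            pca.components_.T, index=names, columns=[f"PC{i+1}" for i in range(k)]
        ),
    )
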