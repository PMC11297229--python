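"""Visible network architectures: masked affine layers over named units.

Every network here is an ordered sequence of masked affine layers acting on a
pool of *named units*. The pool starts with the input features (prefixed
``me:``, ``ge:``, ``cov:``) and grows by each layer's output units, so merges
(the combined gene layer consuming both the methylation gene node and the raw
expression input) and skip connections (unannotated genes wired straight to
the output) are ordinary layers whose mask simply selects the right units.

Dense and locally connected layers are masked layers too, with
complete-bipartite and windowed masks; ``LayerSpec.kind`` records the intent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .annot_masks import ConnectivityMask

ARCTANH_EPS = 1e-5

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "ModelState",
    "NetworkEngine",
    "arctanh_activation",
    "masked_affine_forward",
    "build_ge_network",
    "build_me_network",
    "build_me_ge_network",
    "build_pathway_network",
    "build_dense_equivalent",
    "add_covariates",
    "build_locally_connected_baseline",
    "init_state",
    "init_output_bias",
]


# ---------------------------------------------------------------------------
# activations


def arctanh_activation(z: np.ndarray, eps: float = ARCTANH_EPS) -> np.ndarray:
    """atanh of the pre-activation, clipped to (-1+eps, 1-eps).

    atanh is only defined on (-1, 1); affine pre-activations are unbounded, so
    they are clipped just inside the domain. The clip keeps outputs finite at
    the price of a zero gradient in the saturated region.
    """
    return np.arctanh(np.clip(z, -1.0 + eps, 1.0 - eps))


def _arctanh_grad(z: np.ndarray, eps: float = ARCTANH_EPS) -> np.ndarray:
    inside = np.abs(z) < 1.0 - eps
    g = np.zeros_like(z)
    g[inside] = 1.0 / (1.0 - z[inside] ** 2)
    return g


_ACT = {
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
        lambda z, a: a * (1.0 - a),
    ),
    "tanh": (np.tanh, lambda z, a: 1.0 - a**2),
    "arctanh": (arctanh_activation, lambda z, a: _arctanh_grad(z)),
}


def apply_activation(name: str, z: np.ndarray) -> np.ndarray:
    try:
        return _ACT[name][0](z)
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None


# ---------------------------------------------------------------------------
# specs


@dataclass
class LayerSpec:
    """One masked affine layer: out = activation(x W + b), W zero off-mask."""

    name: str
    mask: ConnectivityMask
    activation: str
    kind: str = "masked"  # masked | dense | locally_connected

    def __post_init__(self) -> None:
        if self.activation not in _ACT:
            raise ValueError(f"layer {self.name!r}: unknown activation {self.activation!r}")
        if np.any(self.mask.out_degree() == 0):
            bad = [o for o, d in zip(self.mask.out_ids, self.mask.out_degree()) if d == 0]
            raise ValueError(f"layer {self.name!r}: output units with no incoming edge: {bad[:5]}")


@dataclass
class NetworkSpec:
    """Ordered layers plus the named input blocks they consume."""

    layers: list[LayerSpec]
    input_blocks: dict[str, list[str]]
    task: str  # classification | regression

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"task must be classification or regression, got {self.task!r}")
        available: set[str] = set()
        for block, ids in self.input_blocks.items():
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate unit names in input block {block!r}")
            available |= set(ids)
        for layer in self.layers:
            missing = [u for u in layer.mask.in_ids if u not in available]
            if missing:
                raise ValueError(
                    f"layer {layer.name!r} consumes undefined units {missing[:5]}"
                )
            available |= set(layer.mask.out_ids)
        out_units = self.layers[-1].mask.out_ids
        if len(out_units) != 1:
            raise ValueError("network must end in exactly one output unit")
        expected = "sigmoid" if self.task == "classification" else "relu"
        if self.layers[-1].activation != expected:
            raise ValueError(
                f"{self.task} networks must end in {expected}, "
                f"got {self.layers[-1].activation!r}"
            )

    @property
    def output_unit(self) -> str:
        return self.layers[-1].mask.out_ids[0]

    def hidden_activation(self) -> str:
        return "arctanh" if self.task == "classification" else "relu"

    def block_features(self, block: str) -> list[str]:
        """Feature names of a block with the ``prefix:`` stripped."""
        return [u.split(":", 1)[1] for u in self.input_blocks[block]]

    def layer(self, name: str) -> LayerSpec:
        for sp in self.layers:
            if sp.name == name:
                return sp
        raise KeyError(f"no layer named {name!r}")


@dataclass
class ModelState:
    """Trained values: per layer a weight vector aligned to mask edges + bias."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def validate(self, spec: NetworkSpec) -> None:
        for sp, w, b in zip(spec.layers, self.weights, self.biases):
            if w.shape != (sp.mask.n_edges,):
                raise ValueError(f"layer {sp.name!r}: weight vector does not match edges")
            if b.shape != (len(sp.mask.out_ids),):
                raise ValueError(f"layer {sp.name!r}: bias vector does not match outputs")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {sp.name!r}: non-finite parameters")


def masked_affine_forward(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    mask: ConnectivityMask,
    activation: str = "linear",
) -> np.ndarray:
    """activation(x W + b) with W dense-equivalent to zeros off the mask."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(mask.in_ids):
        raise ValueError(
            f"input has {x.shape[-1] if x.ndim else 0} columns, "
            f"mask expects {len(mask.in_ids)}"
        )
    if np.isnan(x).any():
        raise ValueError("input contains NaN")
    w = np.asarray(weights, dtype=float)
    if w.shape != (mask.n_edges,):
        raise ValueError("weights must align one-to-one with mask edges")
    z = x @ mask.to_sparse(w).tocsr() + np.asarray(bias, dtype=float)
    return apply_activation(activation, z)


# ---------------------------------------------------------------------------
# builders

_ME, _GE, _COV = "me:", "ge:", "cov:"


def _prefixed(prefix: str, ids: list[str]) -> list[str]:
    return [prefix + i for i in ids]


def _out_activation(task: str) -> str:
    return "sigmoid" if task == "classification" else "relu"


def _hidden_activation(task: str) -> str:
    return "arctanh" if task == "classification" else "relu"


def build_ge_network(gene_order: list[str], task: str) -> NetworkSpec:
    """Expression-only network: all gene inputs wired straight to the output.

    With an L1 penalty this is the neural analogue of LASSO regression.
    """
    ge_units = _prefixed(_GE, gene_order)
    mask = ConnectivityMask(
        ge_units, ["output"], np.column_stack([np.arange(len(ge_units)), np.zeros(len(ge_units), int)])
    )
    out = LayerSpec("output", mask, _out_activation(task), kind="masked")
    return NetworkSpec([out], {"expression": ge_units}, task)


def _gene_layer_from_mask(gene_mask: ConnectivityMask, task: str, node_prefix: str) -> LayerSpec:
    mask = ConnectivityMask(
        _prefixed(_ME, gene_mask.in_ids),
        _prefixed(node_prefix, gene_mask.out_ids),
        gene_mask.edges.copy(),
        tags=np.array(["me"] * gene_mask.n_edges, dtype=object),
    )
    return LayerSpec("me_gene", mask, _hidden_activation(task), kind="masked")


def build_me_network(gene_mask: ConnectivityMask, task: str) -> NetworkSpec:
    """Methylation network: CpGs grouped to gene nodes, genes to the output."""
    nonempty = gene_mask.out_degree() > 0
    if not nonempty.all():
        keep = np.where(nonempty)[0]
        remap = -np.ones(len(gene_mask.out_ids), dtype=np.int64)
        remap[keep] = np.arange(len(keep))
        edges = gene_mask.edges.copy()
        edges[:, 1] = remap[edges[:, 1]]
        gene_mask = ConnectivityMask(
            gene_mask.in_ids, [gene_mask.out_ids[i] for i in keep], edges
        )
    me_gene = _gene_layer_from_mask(gene_mask, task, "megene:")
    genes = me_gene.mask.out_ids
    out_mask = ConnectivityMask(
        genes, ["output"], np.column_stack([np.arange(len(genes)), np.zeros(len(genes), int)])
    )
    out = LayerSpec("output", out_mask, _out_activation(task))
    return NetworkSpec([me_gene, out], {"methylation": me_gene.mask.in_ids}, task)


def build_me_ge_network(
    gene_mask: ConnectivityMask, gene_order: list[str], task: str
) -> NetworkSpec:
    """Multi-omic network merging the omics at the gene level.

    CpGs collapse to one methylation node per gene; each combined gene node
    then receives exactly two incoming edges — that gene's methylation node
    (tag ``me``) and that gene's expression input (tag ``ge``) — and the
    combined nodes feed the output. The tags drive omic-specific L1 and the
    per-gene omic decomposition.
    """
    if list(gene_mask.out_ids) != list(gene_order):
        raise ValueError("gene_mask column order must equal gene_order (the intersected list)")
    if (gene_mask.out_degree() == 0).any():
        raise ValueError(
            "every gene in the combined network needs at least one CpG; "
            "restrict gene_order first"
        )
    me_gene = _gene_layer_from_mask(gene_mask, task, "megene:")
    n = len(gene_order)
    megene_units = me_gene.mask.out_ids
    ge_units = _prefixed(_GE, gene_order)
    in_ids = megene_units + ge_units
    edges = np.concatenate(
        [
            np.column_stack([np.arange(n), np.arange(n)]),          # me edge per gene
            np.column_stack([n + np.arange(n), np.arange(n)]),      # ge edge per gene
        ]
    )
    tags = np.array(["me"] * n + ["ge"] * n, dtype=object)
    gene_layer = LayerSpec(
        "gene",
        ConnectivityMask(in_ids, _prefixed("gene:", gene_order), edges, tags=tags),
        _hidden_activation(task),
    )
    out_mask = ConnectivityMask(
        gene_layer.mask.out_ids,
        ["output"],
        np.column_stack([np.arange(n), np.zeros(n, int)]),
    )
    out = LayerSpec("output", out_mask, _out_activation(task))
    return NetworkSpec(
        [me_gene, gene_layer, out],
        {"methylation": me_gene.mask.in_ids, "expression": ge_units},
        task,
    )


def build_pathway_network(
    me_ge_spec: NetworkSpec,
    pathway_masks: tuple[ConnectivityMask, ConnectivityMask, ConnectivityMask, ConnectivityMask],
) -> NetworkSpec:
    """Add the three-level pathway hierarchy on top of the combined gene layer.

    Combined gene nodes feed local -> mid -> global pathway layers; genes
    without any pathway annotation keep a skip edge straight to the output, so
    the output node collects the global pathways plus the skip genes.
    """
    g2l, l2m, m2g, skip = pathway_masks
    gene_layer = me_ge_spec.layer("gene")
    gene_units = gene_layer.mask.out_ids
    if [u.split(":", 1)[1] for u in gene_units] != list(g2l.in_ids):
        raise ValueError("pathway masks were built for a different gene order")
    hidden = me_ge_spec.hidden_activation()

    def _layer(name, mask, in_prefix, out_prefix, act):
        return LayerSpec(
            name,
            ConnectivityMask(
                _prefixed(in_prefix, mask.in_ids),
                _prefixed(out_prefix, mask.out_ids),
                mask.edges.copy(),
            ),
            act,
        )

    local = _layer("pw_local", g2l, "gene:", "pw_local:", hidden)
    mid = _layer("pw_mid", l2m, "pw_local:", "pw_mid:", hidden)
    glob = _layer("pw_global", m2g, "pw_mid:", "pw_global:", hidden)

    if not glob.mask.out_ids and skip.n_edges == 0:
        raise ValueError("pathway network has no route to the output")
    skip_genes = ["gene:" + g2l.in_ids[i] for i in skip.edges[:, 0]]
    out_in = glob.mask.out_ids + skip_genes
    edges = np.column_stack([np.arange(len(out_in)), np.zeros(len(out_in), int)])
    tags = np.array(
        ["pathway"] * len(glob.mask.out_ids) + ["skip"] * len(skip_genes), dtype=object
    )
    out = LayerSpec(
        "output",
        ConnectivityMask(out_in, ["output"], edges, tags=tags),
        _out_activation(me_ge_spec.task),
    )
    layers = [me_ge_spec.layer("me_gene"), gene_layer]
    layers += [ly for ly in (local, mid, glob) if ly.mask.out_ids]
    layers.append(out)
    return NetworkSpec(layers, dict(me_ge_spec.input_blocks), me_ge_spec.task)


def build_dense_equivalent(
    me_ge_spec: NetworkSpec, dims: tuple[int, ...] = (321, 44, 6)
) -> NetworkSpec:
    """Same neuron counts as the pathway network, fully connected instead.

    Serves as the no-prior-knowledge comparison: three dense layers between
    the combined gene layer and the output.
    """
    gene_layer = me_ge_spec.layer("gene")
    hidden = me_ge_spec.hidden_activation()
    layers = [me_ge_spec.layer("me_gene"), gene_layer]
    prev = gene_layer.mask.out_ids
    for k, width in enumerate(dims, start=1):
        out_ids = [f"dense{k}:{j}" for j in range(width)]
        layers.append(
            LayerSpec(f"dense{k}", ConnectivityMask.dense(prev, out_ids), hidden, kind="dense")
        )
        prev = out_ids
    layers.append(
        LayerSpec(
            "output",
            ConnectivityMask.dense(prev, ["output"]),
            _out_activation(me_ge_spec.task),
            kind="dense",
        )
    )
    return NetworkSpec(layers, dict(me_ge_spec.input_blocks), me_ge_spec.task)


def add_covariates(
    spec: NetworkSpec, covariate_ids: list[str], mode: str = "last_layer"
) -> NetworkSpec:
    """Wire covariates into an existing network.

    ``last_layer`` feeds every covariate straight into the output node;
    ``per_gene`` feeds every covariate into every combined gene node, which
    lets the per-gene covariate weights be inspected afterwards. New edges are
    tagged ``covariate``.
    """
    if mode not in ("last_layer", "per_gene"):
        raise ValueError("mode must be 'last_layer' or 'per_gene'")
    cov_units = _prefixed(_COV, list(covariate_ids))
    target = "output" if mode == "last_layer" else "gene"
    layers = []
    for ly in spec.layers:
        if ly.name != target:
            layers.append(ly)
            continue
        m = ly.mask
        n_in, n_out = m.shape
        if mode == "last_layer":
            new_edges = np.column_stack(
                [n_in + np.arange(len(cov_units)), np.zeros(len(cov_units), int)]
            )
        else:
            cc, gg = np.meshgrid(np.arange(len(cov_units)), np.arange(n_out), indexing="ij")
            new_edges = np.column_stack([n_in + cc.ravel(), gg.ravel()])
        old_tags = (
            m.tags if m.tags is not None else np.array(["untagged"] * m.n_edges, dtype=object)
        )
        mask = ConnectivityMask(
            m.in_ids + cov_units,
            m.out_ids,
            np.concatenate([m.edges, new_edges]),
            tags=np.concatenate(
                [old_tags, np.array(["covariate"] * len(new_edges), dtype=object)]
            ),
        )
        layers.append(LayerSpec(ly.name, mask, ly.activation, kind=ly.kind))
    blocks = dict(spec.input_blocks)
    blocks["covariates"] = cov_units
    return NetworkSpec(layers, blocks, spec.task)


def build_locally_connected_baseline(
    input_ids: list[str],
    window: int,
    stride: int,
    dense_dims: tuple[int, int],
    task: str,
) -> NetworkSpec:
    """Baseline: locally connected 1D layer + two dense layers on concatenated omics.

    The locally connected layer slides an *unshared-weight* window over the
    concatenated feature axis — a hybrid between a convolution (local
    receptive fields) and a dense layer (no weight sharing).
    """
    d = len(input_ids)
    if window < 1 or stride < 1 or window > d:
        raise ValueError("window and stride must be >= 1 and window <= input size")
    starts = list(range(0, d - window + 1, stride))
    lc_units = [f"lc:{k}" for k in range(len(starts))]
    edges = np.array(
        [(s + o, k) for k, s in enumerate(starts) for o in range(window)], dtype=np.int64
    )
    hidden = _hidden_activation(task)
    layers = [
        LayerSpec("local", ConnectivityMask(list(input_ids), lc_units, edges), hidden,
                  kind="locally_connected")
    ]
    prev = lc_units
    for k, width in enumerate(dense_dims, start=1):
        out_ids = [f"dense{k}:{j}" for j in range(width)]
        layers.append(
            LayerSpec(f"dense{k}", ConnectivityMask.dense(prev, out_ids), hidden, kind="dense")
        )
        prev = out_ids
    layers.append(
        LayerSpec("output", ConnectivityMask.dense(prev, ["output"]), _out_activation(task),
                  kind="dense")
    )
    return NetworkSpec(layers, {"concat": list(input_ids)}, task)


# ---------------------------------------------------------------------------
# parameter state


def init_state(spec: NetworkSpec, seed: int, gain: float = 0.05) -> ModelState:
    """Glorot-uniform weights restricted to mask edges; zero biases.

    The fan of each edge is taken from the *masked* degrees (in-degree of its
    target unit, out-degree of its source unit), not the dense layer shape, so
    sparse layers do not start with vanishingly small weights. ``gain``
    shrinks the Glorot limit; the small default keeps initial pre-activations
    well inside the clipped arctanh domain (-1, 1), where the gradient is
    alive — plain Glorot saturates most units of a clipped-arctanh layer at
    initialization and training stalls.
    """
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for ly in spec.layers:
        m = ly.mask
        fan_in = m.out_degree()[m.edges[:, 1]]
        fan_out = m.in_degree()[m.edges[:, 0]]
        limit = gain * np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit))
        biases.append(np.zeros(len(m.out_ids)))
    return ModelState(weights, biases, metadata={"seed": int(seed), "init_gain": gain})


def init_output_bias(state: ModelState, y_train: np.ndarray) -> ModelState:
    """Set the output neuron's bias to the training-set phenotype mean."""
    y = np.asarray(y_train, dtype=float)
    if y.size == 0:
        raise ValueError("y_train is empty")
    state.biases[-1] = np.array([float(y.mean())])
    state.metadata["train_phenotype_mean"] = float(y.mean())
    return state


# ---------------------------------------------------------------------------
# compiled engine


class NetworkEngine:
    """Compiled forward/backward over a NetworkSpec.

    Precomputes the global unit table, per-layer gather indices and CSR
    structures so that training touches no Python-level graph logic. The
    parameter vector is the concatenation of every layer's edge-weight vector
    followed by its bias vector.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        unit_order: list[str] = []
        for ids in spec.input_blocks.values():
            unit_order.extend(ids)
        for ly in spec.layers:
            unit_order.extend(ly.mask.out_ids)
        self.unit_index = {u: i for i, u in enumerate(unit_order)}
        if len(self.unit_index) != len(unit_order):
            raise ValueError("unit names collide across blocks/layers")
        self.n_units = len(unit_order)

        self._layers = []
        offset = 0
        self.slices: list[tuple[slice, slice]] = []
        for ly in spec.layers:
            m = ly.mask
            in_idx = np.array([self.unit_index[u] for u in m.in_ids])
            out_idx = np.array([self.unit_index[u] for u in m.out_ids])
            rows, cols = m.edges[:, 0], m.edges[:, 1]
            # CSR structure with a permutation from edge order to csr data order
            template = sparse.coo_matrix(
                (np.arange(m.n_edges, dtype=float), (rows, cols)), shape=m.shape
            ).tocsr()
            perm = template.data.astype(np.int64)
            templateT = sparse.coo_matrix(
                (np.arange(m.n_edges, dtype=float), (cols, rows)),
                shape=(m.shape[1], m.shape[0]),
            ).tocsr()
            permT = templateT.data.astype(np.int64)
            w_sl = slice(offset, offset + m.n_edges)
            offset += m.n_edges
            b_sl = slice(offset, offset + len(m.out_ids))
            offset += len(m.out_ids)
            self.slices.append((w_sl, b_sl))
            self._layers.append(
                dict(
                    spec=ly, in_idx=in_idx, out_idx=out_idx, rows=rows, cols=cols,
                    csr=(template.indices, template.indptr, perm, m.shape),
                    csrT=(templateT.indices, templateT.indptr, permT, (m.shape[1], m.shape[0])),
                )
            )
        self.n_params = offset
        self.output_col = self.unit_index[spec.output_unit]

    # -- parameter packing ---------------------------------------------------

    def pack(self, state: ModelState) -> np.ndarray:
        theta = np.empty(self.n_params)
        for (w_sl, b_sl), w, b in zip(self.slices, state.weights, state.biases):
            theta[w_sl] = w
            theta[b_sl] = b
        return theta

    def unpack(self, theta: np.ndarray, metadata: dict | None = None) -> ModelState:
        return ModelState(
            weights=[theta[w_sl].copy() for w_sl, _ in self.slices],
            biases=[theta[b_sl].copy() for _, b_sl in self.slices],
            metadata=dict(metadata or {}),
        )

    def _csr(self, cached, data):
        indices, indptr, perm, shape = cached
        return sparse.csr_matrix((data[perm], indices, indptr), shape=shape)

    # -- forward / backward ---------------------------------------------------

    def assemble(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        """Place input-block matrices into the global unit table."""
        n = None
        for block in self.spec.input_blocks:
            if block not in inputs:
                raise ValueError(f"missing input block {block!r}")
            n = len(inputs[block])
        U = np.zeros((n, self.n_units))
        for block, ids in self.spec.input_blocks.items():
            X = np.asarray(inputs[block], dtype=float)
            if X.shape != (n, len(ids)):
                raise ValueError(
                    f"input block {block!r} has shape {X.shape}, expected {(n, len(ids))}"
                )
            if np.isnan(X).any():
                raise ValueError(f"input block {block!r} contains NaN")
            cols = [self.unit_index[u] for u in ids]
            U[:, cols] = X
        return U

    def forward(self, theta: np.ndarray, inputs: dict[str, np.ndarray], cache: bool = False):
        U = self.assemble(inputs)
        Zs = []
        for (w_sl, b_sl), L in zip(self.slices, self._layers):
            X = U[:, L["in_idx"]]
            W = self._csr(L["csr"], theta[w_sl])
            Z = X @ W + theta[b_sl]
            U[:, L["out_idx"]] = apply_activation(L["spec"].activation, Z)
            if cache:
                Zs.append(Z)
        yhat = U[:, self.output_col]
        return (yhat, (U, Zs)) if cache else yhat

    def backward(self, theta: np.ndarray, cache, dY: np.ndarray) -> np.ndarray:
        """Gradient of a scalar loss wrt theta, given dLoss/dOutput."""
        U, Zs = cache
        dU = np.zeros_like(U)
        dU[:, self.output_col] = dY
        grad = np.zeros(self.n_params)
        for (w_sl, b_sl), L, Z in zip(
            reversed(self.slices), reversed(self._layers), reversed(Zs)
        ):
            ly = L["spec"]
            A = U[:, L["out_idx"]]
            dZ = dU[:, L["out_idx"]] * _ACT[ly.activation][1](Z, A)
            X = U[:, L["in_idx"]]
            rows, cols = L["rows"], L["cols"]
            n_in, n_out = ly.mask.shape
            if ly.mask.n_edges * 4 < n_in * n_out:
                gw = np.einsum("ne,ne->e", X[:, rows], dZ[:, cols])
            else:
                gw = (X.T @ dZ)[rows, cols]
            grad[w_sl] = gw
            grad[b_sl] = dZ.sum(axis=0)
            WT = self._csr(L["csrT"], theta[w_sl])
            dU[:, L["in_idx"]] += dZ @ WT  # in_idx unique within a layer
        return grad

    def predict(self, state: ModelState, inputs: dict[str, np.ndarray]) -> np.ndarray:
        state.validate(self.spec)
        return self.forward(self.pack(state), inputs)
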