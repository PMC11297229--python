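"""Shared fixtures: tiny networks, random DAG generators, independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from visomix.annot_masks import ConnectivityMask
from visomix.vnn_core import LayerSpec, ModelState, NetworkSpec


def path_enum_raw_scores(spec: NetworkSpec, state: ModelState) -> dict[str, float]:
    """Brute-force path enumeration: raw score of every unit.

    For each unit u, the sum over all u -> output paths of the product of the
    absolute edge weights, computed by plain recursion with NO memoisation, so
    every path is walked explicitly. Independent of the DP implementation.
    """
    out_unit = spec.layers[-1].mask.out_ids[0]
    adj: dict[str, list[tuple[str, float]]] = {}
    for ly, w in zip(spec.layers, state.weights):
        for k, (i, j) in enumerate(ly.mask.edges):
            adj.setdefault(ly.mask.in_ids[i], []).append(
                (ly.mask.out_ids[j], abs(float(w[k])))
            )

    def mass(u: str) -> float:
        if u == out_unit:
            return 1.0
        return sum(wt * mass(v) for v, wt in adj.get(u, []))

    units = set()
    for ids in spec.input_blocks.values():
        units |= set(ids)
    for ly in spec.layers:
        units |= set(ly.mask.out_ids)
    return {u: mass(u) for u in units}


@pytest.fixture
def path_oracle():
    return path_enum_raw_scores


def random_mask(rng, in_ids, out_ids, density=0.5, tags=None) -> ConnectivityMask:
    """Random mask where every output unit keeps at least one incoming edge."""
    n_in, n_out = len(in_ids), len(out_ids)
    edges = set()
    for j in range(n_out):
        edges.add((int(rng.integers(n_in)), j))
    n_extra = int(density * n_in * n_out)
    for _ in range(n_extra):
        edges.add((int(rng.integers(n_in)), int(rng.integers(n_out))))
    edges = np.array(sorted(edges), dtype=np.int64)
    tag_arr = None
    if tags is not None:
        tag_arr = np.array([tags[int(rng.integers(len(tags)))] for _ in edges], dtype=object)
    return ConnectivityMask(list(in_ids), list(out_ids), edges, tags=tag_arr)


def random_network(seed: int, n_inputs: int = 6, widths=(4, 3)) -> tuple[NetworkSpec, ModelState]:
    """Small random DAG network (with an input skip into the second layer)."""
    rng = np.random.default_rng(seed)
    inputs = [f"x:{i}" for i in range(n_inputs)]
    layers = []
    prev = inputs
    for li, w in enumerate(widths):
        outs = [f"h{li}:{j}" for j in range(w)]
        ins = list(prev)
        if li == 1:  # skip edges from raw inputs into the second hidden layer
            ins = ins + inputs[:2]
        layers.append(
            LayerSpec(f"h{li}", random_mask(rng, ins, outs, density=0.6), "linear")
        )
        prev = outs
    out_mask = random_mask(rng, prev, ["output"], density=1.0)
    layers.append(LayerSpec("output", out_mask, "relu"))
    spec = NetworkSpec(layers, {"x": inputs}, "regression")
    state = ModelState(
        weights=[rng.standard_normal(ly.mask.n_edges) for ly in spec.layers],
        biases=[rng.standard_normal(len(ly.mask.out_ids)) for ly in spec.layers],
    )
    return spec, state


@pytest.fixture
def make_random_network():
    return random_network
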