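"""The point-cloud graph neural network with auto-registration.

Each of the three (unshared) layers updates vertex states h_i by

    Δx_i  = MLP_ω(h_i)                               (offset, Å)
    e_ij  = MLP_f([x_j − x_i + Δx_i ⊕ h_j])          (edge features)
    h_i'  = MLP_g(Max_j e_ij) + h_i                  (residual update)

Vertices with no incident edges keep their state unchanged.  Only
relative coordinates enter the computation, so the forward pass is
invariant to global translations of the structure.  A final 4-layer MLP
(300 → 128 → 64 → 1) with a logistic output scores each vertex as
binding site or not.

MLP_f's first-layer weight (303 × 300) is stored as a 3-row relative-
coordinate block and a 300-row neighbor-state block; the state block is
applied once per vertex and gathered per edge, which is mathematically
identical to concatenating first and much cheaper.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .graphs import AggregationNet, GraphConfig, aggregate_initial_states
from .nn.layers import kaiming
from .surface import ChemNet


class GNNLayer:
    """One auto-registration message-passing layer (unshared weights)."""

    def __init__(self, rng: np.random.Generator, state_dim: int = 300,
                 offset_hidden: int = 64):
        D = state_dim
        self.mlp_w = nn.MLP([D, offset_hidden, 3], rng)
        W1 = kaiming(rng, 3 + D, D)       # first layer of MLP_f, in blocks
        self.Wf_rel = nn.Parameter(W1[:3])
        self.Wf_state = nn.Parameter(W1[3:])
        self.bf1 = nn.Parameter(np.zeros(D, dtype=np.float32))
        self.f_lin2 = nn.Linear(D, D, rng)
        # small-scale output layer: the residual stack starts near the
        # identity, keeping state magnitudes stable across iterations
        self.mlp_g = nn.MLP([D, D, D], rng, final_scale=0.1)

    def parameters(self):
        return (self.mlp_w.parameters()
                + [self.Wf_rel, self.Wf_state, self.bf1]
                + self.f_lin2.parameters() + self.mlp_g.parameters())

    def __call__(self, states: nn.Tensor, coords: np.ndarray,
                 edges: np.ndarray) -> nn.Tensor:
        if len(edges) == 0:
            return states
        src, dst = edges[:, 0], edges[:, 1]
        offsets = self.mlp_w(states)                       # (M, 3)
        base = coords[dst] - coords[src]                   # x_j − x_i
        rel = nn.constant(base) + nn.gather_rows(offsets, src)
        state_emb = states @ self.Wf_state                 # (M, D), per-vertex
        hidden = nn.add_bias_relu(rel @ self.Wf_rel,
                                  nn.gather_rows(state_emb, dst), self.bf1)
        e = self.f_lin2(hidden)                            # (E, D)
        # Max over each source vertex's edges; vertices without edges are
        # left untouched (identity update)
        active, compact = np.unique(src, return_inverse=True)
        agg = nn.segment_max(e, compact, len(active))
        update = self.mlp_g(agg)
        return nn.scatter_rows(update, active, states.shape[0]) + states


class PointGNNModel:
    """End-to-end model: chemical net, aggregation net, T=3 GNN layers,
    vertex classifier.  All parts receive gradients during training."""

    T = 3

    def __init__(self, seed: int = 0, config: GraphConfig = None,
                 classifier_dims=(128, 64)):
        self.config = config or GraphConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        D = self.config.state_dim
        self.chem_net = ChemNet(rng)
        self.embed_net = AggregationNet(rng, D)
        self.layers = [GNNLayer(rng, D) for _ in range(self.T)]
        # near-zero head: a fresh model predicts ~0.5 everywhere, so the
        # initial loss sits at chance level for balanced labels
        self.classifier = nn.MLP([D, *classifier_dims, 1], rng,
                                 final_scale=0.01)
        self.classifier_dims = tuple(classifier_dims)

    def parameters(self):
        ps = self.chem_net.parameters() + self.embed_net.parameters()
        for layer in self.layers:
            ps += layer.parameters()
        return ps + self.classifier.parameters()

    def set_training(self, flag: bool):
        self.chem_net.set_training(flag)

    # -- forward -----------------------------------------------------------

    def initial_states(self, enc) -> nn.Tensor:
        """Featurize and aggregate an :class:`EncodedStructure` into
        initial vertex states."""
        chem = self.chem_net(nn.constant(enc.chem_pair_input),
                             enc.chem_point_ids, enc.n_points)
        full = nn.concat([chem, nn.constant(enc.geom_feat)], axis=1)
        return aggregate_initial_states(full, enc.point_coords, enc.selected,
                                        self.config.r0, self.embed_net,
                                        pairs=enc.agg_pairs)

    def logits(self, enc) -> nn.Tensor:
        states = self.initial_states(enc)
        for layer in self.layers:
            states = layer(states, enc.vertex_coords, enc.edges)
        return self.classifier(states)

    def forward(self, enc) -> np.ndarray:
        """Per-vertex binding-site probabilities, strictly in (0, 1)."""
        self.set_training(False)
        out = nn.sigmoid(self.logits(enc))
        return out.data.ravel().astype(np.float64)

    # -- serialization -----------------------------------------------------

    def state_arrays(self):
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["bn_mean"] = self.chem_net.bn.running_mean
        arrays["bn_var"] = self.chem_net.bn.running_var
        return arrays

    def load_state_arrays(self, arrays):
        for i, p in enumerate(self.parameters()):
            a = np.asarray(arrays[f"p{i}"])
            if a.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {a.shape} != {p.data.shape}")
            p.data = a.astype(np.float32).copy()
        self.chem_net.bn.running_mean = np.asarray(arrays["bn_mean"], np.float32).copy()
        self.chem_net.bn.running_var = np.asarray(arrays["bn_var"], np.float32).copy()

    def save(self, path):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_arrays())
        sidecar = {
            "seed": self.seed,
            "classifier_dims": list(self.classifier_dims),
            "graph_config": {
                "voxel_size": self.config.voxel_size, "r0": self.config.r0,
                "r": self.config.r, "max_edges": self.config.max_edges,
                "state_dim": self.config.state_dim,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path):
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(seed=sidecar["seed"],
                    config=GraphConfig(**sidecar["graph_config"]),
                    classifier_dims=tuple(sidecar["classifier_dims"]))
        with np.load(path.with_suffix(".npz")) as arrays:
            model.load_state_arrays(dict(arrays))
        return model
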