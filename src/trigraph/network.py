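"""Three-level message passing over the atom-bond / bond-angle / angle-dihedral graphs.

One iteration updates the levels top-down — dihedral-edged angle graph (I),
then angle-edged bond graph (H), then bond-edged atom graph (G) — so each
lower level consumes the *current* iteration's higher-level hidden states as
its edge features.  Aggregation and combination are GIN-style: sum over
(neighbour state + edge embedding), then ``MLP((1 + eps) * h + aggregate)``,
with optional residual connections, layer normalisation and graph
normalisation (aggregates scaled by 1/sqrt(level node count per graph)).
After K iterations the atom states are mean-pooled into the molecule
embedding; the per-atom states are kept for atom-level heads.

All inputs are internal coordinates, so the embedding is invariant to rigid
motions and atom re-ordering but *not* to mirror reflection: torsions are
signed, which is what lets the encoder separate enantiomers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .molgraph import InitialFeatures, TriGraph
from .nn import Tensor, gather, relu, segment_sum

CHECKPOINT_VERSION = 1


@dataclass
class NetworkConfig:
    hidden: int = 32
    n_iterations: int = 8          # K
    dropout: float = 0.2           # applied only when a training rng is passed
    residual: bool = True
    layer_norm: bool = True
    graph_norm: bool = True
    readout: str = "mean"
    use_dihedrals: bool = True     # ablation: drop the I level (angle-only model)
    use_angles: bool = True        # ablation: drop H and I (plain atom-bond GNN)
    seed: int = 0                  # weight initialisation

    def __post_init__(self):
        if self.n_iterations < 1 or self.hidden < 1:
            raise ValueError("n_iterations and hidden width must be >= 1")
        if self.readout != "mean":
            raise ValueError("only mean readout is supported")


@dataclass
class Embedding:
    """Molecule-level vectors plus the final per-element hidden states."""

    h_graph: np.ndarray  # (n_graphs, hidden)
    h_atom: np.ndarray   # (n_atoms, hidden)
    h_bond: np.ndarray
    h_angle: np.ndarray


@dataclass
class GraphBatch:
    """Several molecules merged into one disjoint-union three-level graph."""

    n_graphs: int
    x_atom: np.ndarray
    x_bond: np.ndarray
    x_angle: np.ndarray
    x_dihedral: np.ndarray
    g_edges: np.ndarray
    g_edge_bond: np.ndarray
    h_edges: np.ndarray
    h_edge_angle: np.ndarray
    i_edges: np.ndarray
    i_edge_dihedral: np.ndarray
    atom_graph: np.ndarray   # graph membership per atom
    bond_graph: np.ndarray
    angle_graph: np.ndarray
    # feature-mask flags (True = replace input features by the mask token)
    mask_atom: np.ndarray = None
    mask_bond: np.ndarray = None
    mask_angle: np.ndarray = None
    mask_dihedral: np.ndarray = None
    # offsets of each molecule into the concatenated index spaces
    atom_offset: np.ndarray = None
    bond_offset: np.ndarray = None
    angle_offset: np.ndarray = None
    dihedral_offset: np.ndarray = None

    @property
    def n_atoms(self) -> int:
        return len(self.x_atom)

    @property
    def n_bonds(self) -> int:
        return len(self.x_bond)

    @property
    def n_angles(self) -> int:
        return len(self.x_angle)


def make_batch(items: list[tuple[TriGraph, InitialFeatures]],
               mask_plans: list | None = None) -> GraphBatch:
    """Disjoint union of per-molecule graphs with index offsets."""
    xa, xb, xg, xd = [], [], [], []
    ge, gb, he, ha, ie, idh = [], [], [], [], [], []
    agraph, bgraph, anggraph = [], [], []
    ma, mb, mang, mdih = [], [], [], []
    offs = {"atom": [0], "bond": [0], "angle": [0], "dihedral": [0]}
    for k, (graph, feats) in enumerate(items):
        oa, ob, og, od = (offs["atom"][-1], offs["bond"][-1],
                          offs["angle"][-1], offs["dihedral"][-1])
        xa.append(feats.x_atom)
        xb.append(feats.x_bond)
        xg.append(feats.x_angle)
        xd.append(feats.x_dihedral)
        if len(graph.g_edges):
            ge.append(graph.g_edges + oa)
            gb.append(graph.g_edge_bond + ob)
        if len(graph.h_edges):
            he.append(graph.h_edges + ob)
            ha.append(graph.h_edge_angle + og)
        if len(graph.i_edges):
            ie.append(graph.i_edges + og)
            idh.append(graph.i_edge_dihedral + od)
        agraph.append(np.full(graph.n_atoms, k))
        bgraph.append(np.full(graph.n_bonds, k))
        anggraph.append(np.full(graph.n_angles, k))
        for name, n in (("atom", graph.n_atoms), ("bond", graph.n_bonds),
                        ("angle", graph.n_angles), ("dihedral", graph.n_dihedrals)):
            offs[name].append(offs[name][-1] + n)
        plan = mask_plans[k] if mask_plans is not None else None
        for flags, n, idx in ((ma, graph.n_atoms, None if plan is None else plan.feature_masked_atoms),
                              (mb, graph.n_bonds, None if plan is None else plan.masked_bonds),
                              (mang, graph.n_angles, None if plan is None else plan.masked_angles),
                              (mdih, graph.n_dihedrals, None if plan is None else plan.masked_dihedrals)):
            f = np.zeros(n, dtype=bool)
            if idx is not None and len(idx):
                f[np.asarray(idx, dtype=np.intp)] = True
            flags.append(f)

    def cat(parts, width=None):
        parts = [p for p in parts if len(p)]
        if not parts:
            shape = (0,) if width is None else (0, width)
            return np.zeros(shape, dtype=np.intp if width else float)
        return np.concatenate(parts)

    return GraphBatch(
        n_graphs=len(items),
        x_atom=np.concatenate(xa),
        x_bond=np.concatenate(xb) if sum(len(x) for x in xb) else np.zeros((0, xb[0].shape[1])),
        x_angle=np.concatenate(xg) if sum(len(x) for x in xg) else np.zeros((0, xg[0].shape[1])),
        x_dihedral=np.concatenate(xd) if sum(len(x) for x in xd) else np.zeros((0, xd[0].shape[1])),
        g_edges=cat(ge, 2), g_edge_bond=cat(gb),
        h_edges=cat(he, 2), h_edge_angle=cat(ha),
        i_edges=cat(ie, 2), i_edge_dihedral=cat(idh),
        atom_graph=cat(agraph), bond_graph=cat(bgraph), angle_graph=cat(anggraph),
        mask_atom=np.concatenate(ma), mask_bond=np.concatenate(mb),
        mask_angle=np.concatenate(mang), mask_dihedral=np.concatenate(mdih),
        atom_offset=np.array(offs["atom"]), bond_offset=np.array(offs["bond"]),
        angle_offset=np.array(offs["angle"]), dihedral_offset=np.array(offs["dihedral"]),
    )


class _GINLayer(nn.Module):
    """Sum aggregation + two-layer-perceptron combine with learnable eps."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        self.mlp = nn.MLP(hidden, 2 * hidden, hidden, rng)
        self.eps = nn.Parameter(np.zeros(1))
        self.norm = nn.LayerNorm(hidden)

    def __call__(self, h: Tensor, agg: Tensor, cfg: NetworkConfig,
                 dropout_mask: np.ndarray | None) -> Tensor:
        out = self.mlp((1.0 + self.eps) * h + agg)
        if dropout_mask is not None:
            out = out * Tensor(dropout_mask)
        if cfg.residual:
            out = h + out
        if cfg.layer_norm:
            out = self.norm(out)
        return out


class TriGraphEncoder(nn.Module):
    """The three-level message-passing encoder."""

    def __init__(self, dims: dict[str, int], config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()
        self.dims = dict(dims)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        d = cfg.hidden
        self.proj_atom = nn.Linear(dims["atom"], d, rng)
        self.proj_bond = nn.Linear(dims["bond"], d, rng)
        self.proj_angle = nn.Linear(dims["angle"], d, rng)
        self.proj_dihedral = nn.Linear(dims["dihedral"], d, rng)
        # learned mask tokens, one per level
        self.mask_atom_tok = nn.Parameter(rng.normal(0, 0.1, d))
        self.mask_bond_tok = nn.Parameter(rng.normal(0, 0.1, d))
        self.mask_angle_tok = nn.Parameter(rng.normal(0, 0.1, d))
        self.mask_dihedral_tok = nn.Parameter(rng.normal(0, 0.1, d))
        self.angle_layers = [_GINLayer(d, rng) for _ in range(cfg.n_iterations)]
        self.bond_layers = [_GINLayer(d, rng) for _ in range(cfg.n_iterations)]
        self.atom_layers = [_GINLayer(d, rng) for _ in range(cfg.n_iterations)]

    # -- input embedding ------------------------------------------------------
    def _embed_inputs(self, batch: GraphBatch):
        def embed(x, proj, mask, token):
            h = proj(Tensor(x))
            if mask is not None and mask.any():
                keep = (~mask)[:, None].astype(float)
                h = h * Tensor(keep) + Tensor(mask[:, None].astype(float)) * token
            return h

        h_atom = embed(batch.x_atom, self.proj_atom, batch.mask_atom, self.mask_atom_tok)
        h_bond = embed(batch.x_bond, self.proj_bond, batch.mask_bond, self.mask_bond_tok)
        h_angle = embed(batch.x_angle, self.proj_angle, batch.mask_angle, self.mask_angle_tok)
        x_dih = batch.x_dihedral
        if not self.config.use_dihedrals:
            x_dih = np.zeros_like(x_dih)
        h_dih = embed(x_dih, self.proj_dihedral, batch.mask_dihedral, self.mask_dihedral_tok)
        return h_atom, h_bond, h_angle, h_dih

    # -- per-level updates ----------------------------------------------------
    @staticmethod
    def _aggregate(h_nodes: Tensor, edges: np.ndarray, edge_feat: Tensor,
                   edge_feat_idx: np.ndarray, n_nodes: int,
                   node_scale: np.ndarray | None) -> Tensor:
        if len(edges) == 0:
            agg = Tensor(np.zeros((n_nodes, h_nodes.shape[1])))
        else:
            msg = gather(h_nodes, edges[:, 0]) + gather(edge_feat, edge_feat_idx)
            agg = segment_sum(msg, edges[:, 1], n_nodes)
        if node_scale is not None:
            agg = agg * Tensor(node_scale[:, None])
        return agg

    def _level_scale(self, membership: np.ndarray, n_graphs: int) -> np.ndarray | None:
        if not self.config.graph_norm or len(membership) == 0:
            return None
        counts = np.bincount(membership, minlength=n_graphs).astype(float)
        return 1.0 / np.sqrt(np.maximum(counts, 1.0))[membership]

    def update_angle_level(self, h_angle: Tensor, h_dih: Tensor, batch: GraphBatch,
                           t: int, dropout_mask=None) -> Tensor:
        """Angles aggregate neighbour angles across shared dihedrals (I level)."""
        agg = self._aggregate(h_angle, batch.i_edges, h_dih, batch.i_edge_dihedral,
                              batch.n_angles,
                              self._level_scale(batch.angle_graph, batch.n_graphs))
        return self.angle_layers[t](h_angle, agg, self.config, dropout_mask)

    def update_bond_level(self, h_bond: Tensor, h_angle: Tensor, batch: GraphBatch,
                          t: int, dropout_mask=None) -> Tensor:
        """Bonds aggregate neighbour bonds with the shared angle's current state."""
        agg = self._aggregate(h_bond, batch.h_edges, h_angle, batch.h_edge_angle,
                              batch.n_bonds,
                              self._level_scale(batch.bond_graph, batch.n_graphs))
        return self.bond_layers[t](h_bond, agg, self.config, dropout_mask)

    def update_atom_level(self, h_atom: Tensor, h_bond: Tensor, batch: GraphBatch,
                          t: int, dropout_mask=None) -> Tensor:
        """Atoms aggregate neighbour atoms with the connecting bond's current state."""
        agg = self._aggregate(h_atom, batch.g_edges, h_bond, batch.g_edge_bond,
                              batch.n_atoms,
                              self._level_scale(batch.atom_graph, batch.n_graphs))
        return self.atom_layers[t](h_atom, agg, self.config, dropout_mask)

    # -- forward ---------------------------------------------------------------
    def forward_states(self, batch: GraphBatch, rng: np.random.Generator | None = None
                       ) -> tuple[Tensor, Tensor, Tensor]:
        """Run K iterations; returns (h_atom, h_bond, h_angle) final Tensors."""
        cfg = self.config
        h_atom, h_bond, h_angle, h_dih = self._embed_inputs(batch)

        def dmask(n):
            if rng is None or cfg.dropout <= 0 or n == 0:
                return None
            keep = rng.random((n, cfg.hidden)) >= cfg.dropout
            return keep.astype(float) / (1.0 - cfg.dropout)

        for t in range(cfg.n_iterations):
            if cfg.use_angles and cfg.use_dihedrals:
                h_angle = self.update_angle_level(h_angle, h_dih, batch, t,
                                                  dmask(batch.n_angles))
            if cfg.use_angles:
                h_bond = self.update_bond_level(h_bond, h_angle, batch, t,
                                                dmask(batch.n_bonds))
            h_atom = self.update_atom_level(h_atom, h_bond, batch, t,
                                            dmask(batch.n_atoms))
            for name, h in (("angle", h_angle), ("bond", h_bond), ("atom", h_atom)):
                if not np.all(np.isfinite(h.data)):
                    raise FloatingPointError(
                        f"non-finite hidden state at iteration {t}, level {name}")
        return h_atom, h_bond, h_angle

    def readout(self, h_atom: Tensor, batch: GraphBatch) -> Tensor:
        """Mean-pool atom states into one vector per molecule."""
        counts = np.bincount(batch.atom_graph, minlength=batch.n_graphs).astype(float)
        pooled = segment_sum(h_atom, batch.atom_graph, batch.n_graphs)
        return pooled * Tensor(1.0 / np.maximum(counts, 1.0)[:, None])

    def forward(self, batch: GraphBatch, rng: np.random.Generator | None = None
                ) -> Embedding:
        h_atom, h_bond, h_angle = self.forward_states(batch, rng)
        h_graph = self.readout(h_atom, batch)
        return Embedding(h_graph=h_graph.data.copy(), h_atom=h_atom.data.copy(),
                         h_bond=h_bond.data.copy(), h_angle=h_angle.data.copy())


def embed_molecule(model: TriGraphEncoder, graph: TriGraph,
                   feats: InitialFeatures) -> np.ndarray:
    """Convenience: the molecule vector h_G of a single molecule."""
    return model.forward(make_batch([(graph, feats)])).h_graph[0]


# ---------------------------------------------------------------------------
# Checkpoints

def _named_parameters(module: nn.Module, prefix: str = "") -> list[tuple[str, Tensor]]:
    out = []
    for name, v in vars(module).items():
        key = f"{prefix}{name}"
        if isinstance(v, Tensor) and v.requires_grad:
            out.append((key, v))
        elif isinstance(v, nn.Module):
            out.extend(_named_parameters(v, key + "."))
        elif isinstance(v, (list, tuple)):
            for k, item in enumerate(v):
                if isinstance(item, nn.Module):
                    out.extend(_named_parameters(item, f"{key}.{k}."))
    return out


def save_checkpoint(path, model: TriGraphEncoder, extra: dict | None = None) -> None:
    """Weights + versioned header (config and feature dimensions)."""
    header = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "dims": model.dims,
        "extra": extra or {},
    }
    arrays = {name: p.data for name, p in _named_parameters(model)}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TriGraphEncoder:
    """Rebuild an encoder; refuses on version or dimension mismatch."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        model = TriGraphEncoder(header["dims"], NetworkConfig(**header["config"]))
        params = dict(_named_parameters(model))
        for name, p in params.items():
            if name not in data:
                raise ValueError(f"checkpoint missing parameter {name}")
            if data[name].shape != p.data.shape:
                raise ValueError(
                    f"dimension mismatch for {name}: "
                    f"{data[name].shape} vs {p.data.shape}")
            p.data = data[name].astype(np.float64)
    return model
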