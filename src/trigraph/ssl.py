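"""Multiscale self-supervised pretraining: masking, distance binning, losses.

Two families of tasks are defined on top of the encoder:

* **geometric** — with 15% of atoms (and their first-order neighbourhood of
  bonds, angles and dihedrals) masked at the input, predict the masked bond
  lengths, bond angles and signed torsions from the final atom states, and
  classify every sampled atom-pair distance into 30 equal-width bins;
* **electronic** — with the same masking, regress the per-atom partial
  charge and per-bond Wiberg-style bond order of the masked elements.

The canonical two-stage recipe runs the geometric stage first (cheap MMFF94
conformers) and warm-starts the electronic stage from it (conformers with
quantum-chemistry labels); single-stage geometry-only / electronic-only
runs are also supported, as is no pretraining at all.

Bond-length, angle and electronic losses are mean squared errors over the
masked elements; torsions are regressed as their (sin, cos) pair by default
so the loss respects 2*pi periodicity (a raw-angle mode is available); the
distance task is a mean categorical cross-entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .molgraph import (FeatureConfig, GeometricFeatures, Molecule, TriGraph,
                       build_trigraph, compute_geometry, featurize)
from .network import GraphBatch, NetworkConfig, TriGraphEncoder, make_batch
from .nn import Tensor, gather

logger = logging.getLogger(__name__)

GEOMETRIC_TERMS = ("length", "angle", "dihedral", "distance")
ELECTRONIC_TERMS = ("charge", "wiberg")


# ---------------------------------------------------------------------------
# Masking

@dataclass
class MaskPlan:
    """Masked element index sets for one molecule.

    ``masked_atoms`` are the selected atoms (the prediction targets at the
    atom level); ``feature_masked_atoms`` additionally includes their bonded
    neighbours, whose input features are hidden along with the selection.
    Bonds / angles / dihedrals are masked iff they contain a selected atom.
    """

    masked_atoms: np.ndarray
    masked_bonds: np.ndarray
    masked_angles: np.ndarray
    masked_dihedrals: np.ndarray
    feature_masked_atoms: np.ndarray
    seed: int


def make_mask(mol: Molecule, graph: TriGraph, rate: float = 0.15,
              seed: int = 0, neighborhood: str = "full") -> MaskPlan:
    """Select ``max(1, ceil(rate * n_atoms))`` atoms and mask around them.

    Masked features are those of the selected atoms plus every bond, angle
    and dihedral of their first-order neighbourhood — adjacent atoms define
    that neighbourhood but keep their own features visible, so the context
    required to recover the hidden geometry survives.  With
    ``neighborhood="atoms_bonds"`` (the electronic tasks) angles and
    dihedrals are left alone: only the selected atoms and their bonds are
    hidden.  Deterministic for a fixed seed.
    """
    if not (0.0 < rate <= 1.0):
        raise ValueError(f"mask rate must be in (0, 1], got {rate}")
    if neighborhood not in ("full", "atoms_bonds"):
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    n = mol.n_atoms
    k = max(1, math.ceil(rate * n))
    rng = np.random.default_rng(seed)
    selected = np.sort(rng.choice(n, size=k, replace=False))
    sel = set(int(i) for i in selected)

    masked_bonds = np.array(
        [i for i, (a, b) in enumerate(graph.bonds) if a in sel or b in sel],
        dtype=np.intp)
    if neighborhood == "full":
        masked_angles = np.array(
            [i for i, tri in enumerate(graph.angles) if any(a in sel for a in tri)],
            dtype=np.intp)
        masked_dihedrals = np.array(
            [i for i, quad in enumerate(graph.dihedrals) if any(a in sel for a in quad)],
            dtype=np.intp)
    else:
        masked_angles = np.zeros(0, dtype=np.intp)
        masked_dihedrals = np.zeros(0, dtype=np.intp)
    feature_masked = selected.astype(np.intp)
    return MaskPlan(selected.astype(np.intp), masked_bonds, masked_angles,
                    masked_dihedrals, feature_masked, seed)


# ---------------------------------------------------------------------------
# Distance binning

@dataclass
class DistanceBinner:
    """30 equal-width distance classes on [lower, upper] Angstrom."""

    n_bins: int = 30
    lower: float = 0.0
    upper: float = 15.0

    @property
    def width(self) -> float:
        return (self.upper - self.lower) / self.n_bins

    def __call__(self, d):
        return bin_distance(d, self)


def bin_distance(d, binner: DistanceBinner):
    """floor((d - lower) / width), clamped into [0, n_bins - 1]."""
    idx = np.floor((np.asarray(d, dtype=float) - binner.lower) / binner.width)
    out = np.clip(idx, 0, binner.n_bins - 1).astype(np.intp)
    return out if out.ndim else int(out)


# ---------------------------------------------------------------------------
# Loss bookkeeping

@dataclass
class LossBreakdown:
    """The six SSL loss components, their weights and the weighted total."""

    terms: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.weights.get(k, 1.0) * v for k, v in self.terms.items()))

    def merge(self, other: "LossBreakdown") -> "LossBreakdown":
        out = LossBreakdown(dict(self.terms), dict(self.weights), dict(self.counts))
        out.terms.update(other.terms)
        out.weights.update(other.weights)
        out.counts.update(other.counts)
        return out


def geometric_losses(predictions: dict[str, np.ndarray], targets: GeometricFeatures,
                     plan: MaskPlan, binner: DistanceBinner,
                     weights: dict[str, float] | None = None,
                     dihedral_mode: str = "sincos") -> LossBreakdown:
    """Geometric SSL losses from plain prediction arrays (one molecule).

    ``predictions['length'|'angle']`` align with the plan's masked bond /
    angle order; ``predictions['dihedral']`` is (k, 2) sin-cos rows (or (k,)
    raw angles); ``predictions['distance_logits']`` holds one 30-way logit
    row per pair in ``predictions['distance_pairs']``.  Degenerate
    (collinear) angles and dihedrals are excluded.
    """
    w = {t: 1.0 for t in GEOMETRIC_TERMS} | (weights or {})
    out = LossBreakdown(weights={k: w[k] for k in GEOMETRIC_TERMS})

    keep_a = [i for i in plan.masked_angles if not targets.angle_degenerate[i]]
    keep_d = [i for i in plan.masked_dihedrals if not targets.dihedral_degenerate[i]]

    def mse(pred, target):
        return float(np.mean((np.asarray(pred) - np.asarray(target)) ** 2))

    out.counts["length"] = len(plan.masked_bonds)
    out.terms["length"] = (mse(predictions["length"], targets.lengths[plan.masked_bonds])
                           if len(plan.masked_bonds) else 0.0)

    out.counts["angle"] = len(keep_a)
    if keep_a:
        sel = [list(plan.masked_angles).index(i) for i in keep_a]
        out.terms["angle"] = mse(np.asarray(predictions["angle"])[sel],
                                 targets.angles[keep_a])
    else:
        out.terms["angle"] = 0.0

    out.counts["dihedral"] = len(keep_d)
    if keep_d:
        sel = [list(plan.masked_dihedrals).index(i) for i in keep_d]
        pred = np.asarray(predictions["dihedral"])[sel]
        theta = targets.dihedrals[keep_d]
        if dihedral_mode == "sincos":
            tgt = np.stack([np.sin(theta), np.cos(theta)], axis=1)
            out.terms["dihedral"] = float(np.mean(((pred - tgt) ** 2).sum(axis=1)))
        else:
            out.terms["dihedral"] = mse(pred.reshape(-1), theta)
    else:
        out.terms["dihedral"] = 0.0

    pairs = np.asarray(predictions.get("distance_pairs", np.zeros((0, 2), dtype=np.intp)))
    out.counts["distance"] = len(pairs)
    if len(pairs):
        logits = np.asarray(predictions["distance_logits"], dtype=float)
        target_bins = bin_distance(targets.dist_matrix[pairs[:, 0], pairs[:, 1]], binner)
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        out.terms["distance"] = float(-logp[np.arange(len(pairs)), target_bins].mean())
    else:
        out.terms["distance"] = 0.0
    return out


def electronic_losses(predictions: dict[str, np.ndarray], mol: Molecule,
                      plan: MaskPlan, weights: dict[str, float] | None = None
                      ) -> LossBreakdown:
    """Charge / bond-order MSE over the masked atoms and bonds."""
    if mol.atom_labels is None or mol.bond_labels is None:
        raise ValueError(f"{mol.id}: electronic labels missing")
    w = {t: 1.0 for t in ELECTRONIC_TERMS} | (weights or {})
    out = LossBreakdown(weights={k: w[k] for k in ELECTRONIC_TERMS})
    out.counts["charge"] = len(plan.masked_atoms)
    out.terms["charge"] = (
        float(np.mean((np.asarray(predictions["charge"])
                       - np.asarray(mol.atom_labels)[plan.masked_atoms]) ** 2))
        if len(plan.masked_atoms) else 0.0)
    out.counts["wiberg"] = len(plan.masked_bonds)
    out.terms["wiberg"] = (
        float(np.mean((np.asarray(predictions["wiberg"])
                       - np.asarray(mol.bond_labels)[plan.masked_bonds]) ** 2))
        if len(plan.masked_bonds) else 0.0)
    return out


# ---------------------------------------------------------------------------
# Prediction heads

class _PairHead(nn.Module):
    """Symmetric head on an atom pair: f(h_u, h_v) = f(h_v, h_u)."""

    def __init__(self, hidden: int, n_out: int, rng):
        self.mlp = nn.MLP(hidden, hidden, n_out, rng)

    def __call__(self, hu: Tensor, hv: Tensor) -> Tensor:
        return self.mlp(hu + hv)


class _AngleHead(nn.Module):
    """Apex-aware symmetric head on an atom triple (u, v, w), apex v."""

    def __init__(self, hidden: int, rng):
        self.lin_end = nn.Linear(hidden, hidden, rng)
        self.lin_apex = nn.Linear(hidden, hidden, rng)
        self.out = nn.MLP(hidden, hidden, 1, rng)

    def __call__(self, hu, hv, hw):
        return self.out(nn.relu(self.lin_end(hu + hw) + self.lin_apex(hv)))


class _DihedralHead(nn.Module):
    """Symmetric under chain reversal (u,v,w,x) -> (x,w,v,u)."""

    def __init__(self, hidden: int, n_out: int, rng):
        self.lin_outer = nn.Linear(hidden, hidden, rng)
        self.lin_inner = nn.Linear(hidden, hidden, rng)
        self.out = nn.MLP(hidden, hidden, n_out, rng)

    def __call__(self, hu, hv, hw, hx):
        return self.out(nn.relu(self.lin_outer(hu + hx) + self.lin_inner(hv + hw)))


class PretrainHeads(nn.Module):
    """All six SSL prediction heads over the final atom states."""

    def __init__(self, hidden: int, binner: DistanceBinner, seed: int = 0,
                 dihedral_mode: str = "sincos"):
        rng = np.random.default_rng(seed + 104729)
        self.f_length = _PairHead(hidden, 1, rng)
        self.f_angle = _AngleHead(hidden, rng)
        self.f_dihedral = _DihedralHead(hidden, 2 if dihedral_mode == "sincos" else 1, rng)
        self.f_distance = _PairHead(hidden, binner.n_bins, rng)
        self.f_charge = nn.MLP(hidden, hidden, 1, rng)
        self.f_wiberg = _PairHead(hidden, 1, rng)
        self.dihedral_mode = dihedral_mode


# ---------------------------------------------------------------------------
# Pretraining

@dataclass
class PretrainConfig:
    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-3                # trunk learning rate
    head_lr: float | None = None    # prediction heads; default 3 * lr
    ema_decay: float = 0.9          # per-batch weight averaging; 0 disables
    mask_rate: float = 0.15
    grad_clip: float = 5.0          # global gradient-norm ceiling
    max_distance_pairs: int = 500   # ordered pairs sampled per molecule
    # Loss combination: "auto" scales each regression term by the inverse
    # variance of its targets (standardised residuals), so millimetre-scale
    # length errors are not drowned by the O(1) cross-entropy gradients;
    # explicit weights override.  Reported loss terms are always unweighted.
    weights: dict[str, float] | str = "auto"
    dihedral_mode: str = "sincos"
    binner: DistanceBinner = field(default_factory=DistanceBinner)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    seed: int = 0


@dataclass
class EncodedMolecule:
    """A molecule with its graph, geometry and input features precomputed."""

    mol: Molecule
    graph: TriGraph
    geo: GeometricFeatures
    feats: "object"


def encode_dataset(mols: list[Molecule], features: FeatureConfig | None = None
                   ) -> list[EncodedMolecule]:
    out = []
    cfg = features or FeatureConfig()
    for m in mols:
        if m.coords is None:
            raise ValueError(f"{m.id}: conformer required before encoding")
        g = build_trigraph(m)
        geo = compute_geometry(m.coords, g)
        out.append(EncodedMolecule(m, g, geo, featurize(m, g, geo, cfg)))
    return out


@dataclass
class PretrainResult:
    model: TriGraphEncoder
    heads: PretrainHeads
    history: list[dict[str, float]]   # per-epoch mean of each loss term + total


def _sample_pairs(n_atoms: int, max_pairs: int, rng) -> np.ndarray:
    """Ordered atom pairs (u, v), u != v, subsampled without replacement."""
    if n_atoms < 2:
        return np.zeros((0, 2), dtype=np.intp)
    total = n_atoms * (n_atoms - 1)
    k = min(total, max_pairs)
    flat = rng.choice(total, size=k, replace=False) if k < total else np.arange(total)
    u = flat // (n_atoms - 1)
    r = flat % (n_atoms - 1)
    v = np.where(r >= u, r + 1, r)
    return np.stack([u, v], axis=1).astype(np.intp)


def _auto_weights(items: list["EncodedMolecule"], stage: str) -> dict[str, float]:
    """Inverse-variance balancing of the regression terms (targets
    standardised to unit scale); classification terms keep weight 1."""
    def inv_var(values, floor=1e-3):
        v = np.asarray(values, dtype=float)
        return 1.0 / max(float(v.var()), floor) if v.size else 1.0

    if stage == "geometry":
        lengths = np.concatenate([e.geo.lengths for e in items if e.graph.n_bonds])
        angles = np.concatenate(
            [e.geo.angles[~e.geo.angle_degenerate] for e in items]
            or [np.zeros(0)])
        theta = np.concatenate(
            [e.geo.dihedrals[~e.geo.dihedral_degenerate] for e in items]
            or [np.zeros(0)])
        sc = (np.concatenate([np.sin(theta), np.cos(theta)])
              if theta.size else np.zeros(0))
        return {"length": inv_var(lengths), "angle": inv_var(angles),
                "dihedral": inv_var(sc), "distance": 1.0}
    charges = np.concatenate([np.asarray(e.mol.atom_labels) for e in items])
    orders = np.concatenate([np.asarray(e.mol.bond_labels) for e in items
                             if e.mol.n_bonds] or [np.zeros(0)])
    return {"charge": inv_var(charges), "wiberg": inv_var(orders)}


def _batch_geometric_loss(model, heads, batch, items, plans, pair_sets, cfg,
                          rng=None, weights=None) -> tuple[Tensor, LossBreakdown]:
    h_atom, _, _ = model.forward_states(batch, rng)
    terms: dict[str, Tensor] = {}
    counts: dict[str, int] = {}

    # global atom indices of the masked elements
    len_u, len_v, len_t = [], [], []
    ang_u, ang_v, ang_w, ang_t = [], [], [], []
    dih_idx = [[] for _ in range(4)]
    dih_t = []
    pu, pv, pt = [], [], []
    for k, enc in enumerate(items):
        oa = batch.atom_offset[k]
        plan = plans[k]
        for b in plan.masked_bonds:
            i, j = enc.graph.bonds[b]
            len_u.append(oa + i); len_v.append(oa + j)
            len_t.append(enc.geo.lengths[b])
        for a in plan.masked_angles:
            if enc.geo.angle_degenerate[a]:
                continue
            u, v, w = enc.graph.angles[a]
            ang_u.append(oa + u); ang_v.append(oa + v); ang_w.append(oa + w)
            ang_t.append(enc.geo.angles[a])
        for d in plan.masked_dihedrals:
            if enc.geo.dihedral_degenerate[d]:
                continue
            for col, atom in zip(dih_idx, enc.graph.dihedrals[d]):
                col.append(oa + atom)
            dih_t.append(enc.geo.dihedrals[d])
        for u, v in pair_sets[k]:
            pu.append(oa + u); pv.append(oa + v)
            pt.append(enc.geo.dist_matrix[u, v])

    if len_u:
        pred = heads.f_length(gather(h_atom, len_u), gather(h_atom, len_v))
        diff = pred.reshape(-1) - Tensor(np.array(len_t))
        terms["length"] = (diff * diff).mean()
    counts["length"] = len(len_u)
    if ang_u:
        pred = heads.f_angle(gather(h_atom, ang_u), gather(h_atom, ang_v),
                             gather(h_atom, ang_w))
        diff = pred.reshape(-1) - Tensor(np.array(ang_t))
        terms["angle"] = (diff * diff).mean()
    counts["angle"] = len(ang_u)
    if dih_t:
        pred = heads.f_dihedral(*(gather(h_atom, c) for c in dih_idx))
        theta = np.array(dih_t)
        if heads.dihedral_mode == "sincos":
            tgt = np.stack([np.sin(theta), np.cos(theta)], axis=1)
            diff = pred - Tensor(tgt)
            terms["dihedral"] = (diff * diff).sum(axis=1).mean()
        else:
            diff = pred.reshape(-1) - Tensor(theta)
            terms["dihedral"] = (diff * diff).mean()
    counts["dihedral"] = len(dih_t)
    if pu:
        logits = heads.f_distance(gather(h_atom, pu), gather(h_atom, pv))
        bins = bin_distance(np.array(pt), cfg.binner)
        terms["distance"] = nn.cross_entropy(logits, np.atleast_1d(bins))
    counts["distance"] = len(pu)

    return _combine_terms(terms, counts, weights, GEOMETRIC_TERMS)


def _batch_electronic_loss(model, heads, batch, items, plans, cfg,
                           rng=None, weights=None) -> tuple[Tensor, LossBreakdown]:
    h_atom, _, _ = model.forward_states(batch, rng)
    terms: dict[str, Tensor] = {}
    counts: dict[str, int] = {}
    qi, qt = [], []
    wu, wv, wt = [], [], []
    for k, enc in enumerate(items):
        oa = batch.atom_offset[k]
        plan = plans[k]
        for a in plan.masked_atoms:
            qi.append(oa + a); qt.append(enc.mol.atom_labels[a])
        bond_key = {(min(b.i, b.j), max(b.i, b.j)): lbl
                    for b, lbl in zip(enc.mol.bonds, enc.mol.bond_labels)}
        for b in plan.masked_bonds:
            i, j = enc.graph.bonds[b]
            wu.append(oa + i); wv.append(oa + j)
            wt.append(bond_key[(i, j)])
    if qi:
        pred = heads.f_charge(gather(h_atom, qi))
        diff = pred.reshape(-1) - Tensor(np.array(qt))
        terms["charge"] = (diff * diff).mean()
    counts["charge"] = len(qi)
    if wu:
        pred = heads.f_wiberg(gather(h_atom, wu), gather(h_atom, wv))
        diff = pred.reshape(-1) - Tensor(np.array(wt))
        terms["wiberg"] = (diff * diff).mean()
    counts["wiberg"] = len(wu)
    return _combine_terms(terms, counts, weights, ELECTRONIC_TERMS)


def _combine_terms(terms, counts, weights, term_names):
    weights = {t: 1.0 for t in term_names} | dict(weights or {})
    total: Tensor | None = None
    for name, t in terms.items():
        wt = t * weights[name]
        total = wt if total is None else total + wt
    breakdown = LossBreakdown(
        terms={name: (terms[name].item() if name in terms else 0.0)
               for name in term_names},
        weights={name: weights[name] for name in term_names},
        counts=dict(counts),
    )
    return total, breakdown


def pretrain(dataset: list[Molecule] | list[EncodedMolecule], stage: str,
             config: PretrainConfig | None = None,
             init_model: TriGraphEncoder | None = None,
             heads: PretrainHeads | None = None) -> PretrainResult:
    """Minimise a stage's combined SSL loss with Adam mini-batches.

    ``stage`` is ``"geometry"`` or ``"electronic"``; the electronic stage may
    warm-start from the geometry stage's encoder via ``init_model``.  A fresh
    MaskPlan is drawn per molecule per epoch.  Deterministic for fixed seeds.
    """
    cfg = config or PretrainConfig()
    if stage not in ("geometry", "electronic"):
        raise ValueError(f"unknown stage {stage!r}")
    items = (dataset if dataset and isinstance(dataset[0], EncodedMolecule)
             else encode_dataset(dataset, cfg.features))
    if stage == "electronic":
        skipped = [e.mol.id for e in items
                   if e.mol.atom_labels is None or e.mol.bond_labels is None]
        if skipped:
            logger.warning("electronic stage: skipping %d unlabelled molecules (%s...)",
                           len(skipped), skipped[0])
            items = [e for e in items
                     if e.mol.atom_labels is not None and e.mol.bond_labels is not None]
    if not items:
        raise ValueError("no usable molecules for pretraining")

    weights = (_auto_weights(items, stage) if cfg.weights == "auto"
               else dict(cfg.weights))
    dims = items[0].feats.dims
    model = init_model or TriGraphEncoder(dims, replace(cfg.network, seed=cfg.seed))
    if heads is None:
        heads = PretrainHeads(model.config.hidden, cfg.binner, seed=cfg.seed,
                              dihedral_mode=cfg.dihedral_mode)
    params = model.parameters() + heads.parameters()
    trunk_opt = nn.Adam(model.parameters(), lr=cfg.lr)
    head_opt = nn.Adam(heads.parameters(),
                       lr=cfg.head_lr if cfg.head_lr is not None else 3 * cfg.lr)
    order_rng = np.random.default_rng(cfg.seed + 1)
    drop_rng = np.random.default_rng(cfg.seed + 2)
    # Polyak-averaged weights smooth the noisy small-batch trajectory; the
    # returned model carries the average, not the final iterate.
    ema = [p.data.copy() for p in params] if cfg.ema_decay else None

    history: list[dict[str, float]] = []
    best_state = [p.data.copy() for p in params]
    for epoch in range(cfg.epochs):
        order = order_rng.permutation(len(items))
        epoch_terms: dict[str, float] = {}
        epoch_counts: dict[str, int] = {}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            chunk = [items[i] for i in idx]
            nbhd = "full" if stage == "geometry" else "atoms_bonds"
            plans = [make_mask(e.mol, e.graph, cfg.mask_rate,
                               seed=(cfg.seed * 1_000_003 + epoch * 9973 + int(i)) & 0x7FFFFFFF,
                               neighborhood=nbhd)
                     for i, e in zip(idx, chunk)]
            batch = make_batch([(e.graph, e.feats) for e in chunk], plans)
            if stage == "geometry":
                pair_rng = np.random.default_rng((cfg.seed * 31 + epoch * 7 + start) & 0x7FFFFFFF)
                pair_sets = [_sample_pairs(e.graph.n_atoms, cfg.max_distance_pairs, pair_rng)
                             for e in chunk]
                total, breakdown = _batch_geometric_loss(
                    model, heads, batch, chunk, plans, pair_sets, cfg, drop_rng,
                    weights=weights)
            else:
                total, breakdown = _batch_electronic_loss(
                    model, heads, batch, chunk, plans, cfg, drop_rng,
                    weights=weights)
            if total is None:
                continue
            if not np.isfinite(total.item()):
                logger.error("non-finite loss at epoch %d; keeping last checkpoint", epoch)
                for p, s in zip(params, best_state):
                    p.data = s
                return PretrainResult(model, heads, history)
            trunk_opt.zero_grad()
            head_opt.zero_grad()
            total.backward()
            if cfg.grad_clip:
                total_norm = np.sqrt(sum(float((p.grad**2).sum())
                                         for p in params if p.grad is not None))
                if total_norm > cfg.grad_clip:
                    scale = cfg.grad_clip / (total_norm + 1e-12)
                    for p in params:
                        if p.grad is not None:
                            p.grad *= scale
            trunk_opt.step()
            head_opt.step()
            if ema is not None:
                for e, p in zip(ema, params):
                    e *= cfg.ema_decay
                    e += (1.0 - cfg.ema_decay) * p.data
            for k, v in breakdown.terms.items():
                epoch_terms[k] = epoch_terms.get(k, 0.0) + v
                epoch_counts[k] = epoch_counts.get(k, 0) + 1
            n_batches += 1
        record = {k: epoch_terms[k] / max(epoch_counts[k], 1) for k in epoch_terms}
        record["total"] = float(sum(record.values()))
        record["epoch"] = float(epoch)
        history.append(record)
        best_state = [p.data.copy() for p in params]
    if ema is not None:
        for p, e in zip(params, ema):
            p.data = e
    return PretrainResult(model, heads, history)


def masked_target_baseline(items: list[EncodedMolecule], plans: list[MaskPlan],
                           what: str = "length") -> float:
    """MSE of the constant-mean predictor on a masked target set."""
    vals: list[float] = []
    for enc, plan in zip(items, plans):
        if what == "length":
            vals.extend(enc.geo.lengths[plan.masked_bonds])
        elif what == "charge":
            vals.extend(np.asarray(enc.mol.atom_labels)[plan.masked_atoms])
        else:
            raise ValueError(what)
    v = np.asarray(vals)
    return float(np.mean((v - v.mean()) ** 2))
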