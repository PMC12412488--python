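"""Message-passing invariances, the loop oracle, ablations and checkpoints."""

import dataclasses

import numpy as np
import pytest
from rdkit import Chem

from trigraph.molgraph import (build_trigraph, compute_geometry, featurize,
                               mirror_coords, parse_molecule)
from trigraph.network import (NetworkConfig, TriGraphEncoder, embed_molecule,
                              load_checkpoint, make_batch, save_checkpoint)

from conftest import random_rotation

CFG = NetworkConfig(hidden=16, n_iterations=3, dropout=0.0, seed=5)


def encode(mol):
    graph = build_trigraph(mol)
    geo = compute_geometry(mol.coords, graph)
    return graph, featurize(mol, graph, geo)


# ---------------------------------------------------------------------------
# Loop oracle: re-implement one model's forward pass with plain Python loops.

def loop_forward(model, graph, feats):
    """Independent nested-loop evaluation of the same weights."""
    import trigraph.nn as nn
    from trigraph.nn import Tensor

    def lin(layer, x):
        return x @ layer.W.data + layer.b.data

    def mlp(m, x):
        return lin(m.fc2, np.maximum(lin(m.fc1, x), 0.0))

    def lnorm(norm, x, enabled):
        if not enabled:
            return x
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / np.sqrt(var + 1e-5) * norm.gamma.data + norm.beta.data

    cfg = model.config
    h_atom = lin(model.proj_atom, feats.x_atom)
    h_bond = lin(model.proj_bond, feats.x_bond)
    h_angle = lin(model.proj_angle, feats.x_angle)
    h_dih = lin(model.proj_dihedral, feats.x_dihedral)

    def scale(n):
        return 1.0 / np.sqrt(max(n, 1)) if cfg.graph_norm else 1.0

    for t in range(cfg.n_iterations):
        # I level: angles via dihedral edges
        layer = model.angle_layers[t]
        agg = np.zeros_like(h_angle)
        for (src, dst), d in zip(graph.i_edges, graph.i_edge_dihedral):
            agg[dst] += h_angle[src] + h_dih[d]
        agg *= scale(graph.n_angles)
        out = mlp(layer.mlp, (1 + layer.eps.data) * h_angle + agg)
        h_angle = lnorm(layer.norm, h_angle + out if cfg.residual else out,
                        cfg.layer_norm)
        # H level: bonds via angle edges
        layer = model.bond_layers[t]
        agg = np.zeros_like(h_bond)
        for (src, dst), a in zip(graph.h_edges, graph.h_edge_angle):
            agg[dst] += h_bond[src] + h_angle[a]
        agg *= scale(graph.n_bonds)
        out = mlp(layer.mlp, (1 + layer.eps.data) * h_bond + agg)
        h_bond = lnorm(layer.norm, h_bond + out if cfg.residual else out,
                       cfg.layer_norm)
        # G level: atoms via bond edges
        layer = model.atom_layers[t]
        agg = np.zeros_like(h_atom)
        for (src, dst), b in zip(graph.g_edges, graph.g_edge_bond):
            agg[dst] += h_atom[src] + h_bond[b]
        agg *= scale(graph.n_atoms)
        out = mlp(layer.mlp, (1 + layer.eps.data) * h_atom + agg)
        h_atom = lnorm(layer.norm, h_atom + out if cfg.residual else out,
                       cfg.layer_norm)
    return h_atom.mean(axis=0)


def test_forward_matches_nested_loop_oracle(encoded_small, feature_dims):
    model = TriGraphEncoder(feature_dims, CFG)
    for mol, graph, geo, feats in encoded_small:
        expected = loop_forward(model, graph, feats)
        got = embed_molecule(model, graph, feats)
        np.testing.assert_allclose(got, expected, atol=1e-6, err_msg=mol.id)


# ---------------------------------------------------------------------------
# Invariances

def test_se3_and_permutation_invariance(druglike_conformers, feature_dims):
    model = TriGraphEncoder(feature_dims, CFG)
    rng = np.random.default_rng(17)
    for mol in druglike_conformers:
        graph, feats = encode(mol)
        ref = embed_molecule(model, graph, feats)
        for _ in range(10):
            rot = random_rotation(rng)
            moved = mol.with_coords(mol.coords @ rot.T + rng.normal(size=3))
            g2, f2 = encode(moved)
            np.testing.assert_allclose(embed_molecule(model, g2, f2), ref,
                                       atol=1e-5, err_msg=mol.id)


def test_atom_permutation_leaves_embedding_unchanged(feature_dims):
    # same structure entered through two different SMILES atom orders
    model = TriGraphEncoder(feature_dims, CFG)
    from trigraph.molgraph import generate_conformer
    a = generate_conformer(parse_molecule("OCC", "a"), 1, 3)
    graph_a, feats_a = encode(a)
    # re-index atoms of the same conformer: map ethanol O-C-C -> C-C-O
    perm = [2, 1, 0]
    b = parse_molecule("CCO", "b").with_coords(a.coords[perm])
    graph_b, feats_b = encode(b)
    np.testing.assert_allclose(embed_molecule(model, graph_a, feats_a),
                               embed_molecule(model, graph_b, feats_b), atol=1e-5)


def test_mirror_sensitivity_iff_nontrivial_dihedrals(encoded_small, feature_dims):
    model = TriGraphEncoder(feature_dims, CFG)
    for mol, graph, geo, feats in encoded_small:
        geo_m = compute_geometry(mirror_coords(mol.coords), graph)
        feats_m = featurize(mol, graph, geo_m)
        d = np.linalg.norm(embed_molecule(model, graph, feats)
                           - embed_molecule(model, graph, feats_m))
        ok = ~geo.dihedral_degenerate
        nontrivial = (np.abs(np.sin(geo.dihedrals)) > 1e-3) & ok
        if not nontrivial.any():
            assert d < 1e-5, mol.id
        # (molecules with torsions may or may not separate under random
        # weights; the guaranteed direction is tested in the chirality suite)


def test_enantiomer_pair_distances(druglike_conformers, feature_dims):
    model_on = TriGraphEncoder(feature_dims, CFG)
    model_off = TriGraphEncoder(feature_dims,
                                dataclasses.replace(CFG, use_dihedrals=False))
    for mol in druglike_conformers[:8]:
        graph, feats = encode(mol)
        geo = compute_geometry(mol.coords, graph)
        nontrivial = (~geo.dihedral_degenerate) & (np.abs(np.sin(geo.dihedrals)) > 1e-2)
        if not nontrivial.any():
            continue
        mirrored = mol.with_coords(mirror_coords(mol.coords))
        g2, f2 = encode(mirrored)
        d_on = np.linalg.norm(embed_molecule(model_on, graph, feats)
                              - embed_molecule(model_on, g2, f2))
        d_off = np.linalg.norm(embed_molecule(model_off, graph, feats)
                               - embed_molecule(model_off, g2, f2))
        assert d_off < 1e-5, mol.id
        assert d_on > 1e-3, mol.id


# ---------------------------------------------------------------------------
# Structural contracts

def test_benzene_symmetry_equalizes_atom_states(feature_dims):
    from trigraph.molgraph import generate_conformer
    mol = generate_conformer(parse_molecule("c1ccccc1", "benzene"), 1, 0)
    graph, feats = encode(mol)
    # idealised geometry so all initial features match exactly
    r = 1.39
    coords = np.array([[r * np.cos(a), r * np.sin(a), 0.0]
                       for a in np.linspace(0, 2 * np.pi, 7)[:6]])
    geo = compute_geometry(coords, graph)
    feats = featurize(mol, graph, geo)
    model = TriGraphEncoder(feature_dims, CFG)
    batch = make_batch([(graph, feats)])
    h_atom, _, _ = model.forward_states(batch)
    spread = np.abs(h_atom.data - h_atom.data[0]).max()
    assert spread < 1e-8


def test_empty_level_molecules_run(feature_dims):
    from trigraph.molgraph import generate_conformer
    model = TriGraphEncoder(feature_dims, CFG)
    for smiles in ("C", "CO", "CCC"):  # no bonds / no angles / no dihedrals
        mol = generate_conformer(parse_molecule(smiles, smiles), 1, 0)
        graph, feats = encode(mol)
        vec = embed_molecule(model, graph, feats)
        assert np.all(np.isfinite(vec))


def test_ablation_nesting_runs(encoded_small, feature_dims):
    angle_only = TriGraphEncoder(feature_dims,
                                 dataclasses.replace(CFG, use_dihedrals=False))
    atom_bond = TriGraphEncoder(
        feature_dims, dataclasses.replace(CFG, use_dihedrals=False, use_angles=False))
    for mol, graph, geo, feats in encoded_small[:6]:
        for model in (angle_only, atom_bond):
            assert np.all(np.isfinite(embed_molecule(model, graph, feats)))


def test_batched_forward_equals_individual(encoded_small, feature_dims):
    model = TriGraphEncoder(feature_dims, CFG)
    items = [(g, f) for _, g, _, f in encoded_small[:6]]
    batch_out = model.forward(make_batch(items)).h_graph
    for k, (g, f) in enumerate(items):
        np.testing.assert_allclose(batch_out[k], embed_molecule(model, g, f),
                                   atol=1e-9)


# ---------------------------------------------------------------------------
# Checkpoints

def test_checkpoint_roundtrip(tmp_path, encoded_small, feature_dims):
    model = TriGraphEncoder(feature_dims, CFG)
    path = tmp_path / "enc.npz"
    save_checkpoint(path, model, extra={"stage": "geometry"})
    loaded = load_checkpoint(path)
    _, graph, _, feats = encoded_small[0]
    np.testing.assert_array_equal(embed_molecule(model, graph, feats),
                                  embed_molecule(loaded, graph, feats))


def test_checkpoint_refuses_dimension_mismatch(tmp_path, feature_dims):
    model = TriGraphEncoder(feature_dims, CFG)
    path = tmp_path / "enc.npz"
    save_checkpoint(path, model)
    import json
    import numpy as np_
    with np_.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    header = json.loads(bytes(arrays["__header__"]).decode())
    header["dims"]["atom"] += 1  # corrupt the declared feature width
    arrays["__header__"] = np_.frombuffer(json.dumps(header).encode(), dtype=np_.uint8)
    np_.savez(path, **arrays)
    with pytest.raises(ValueError, match="mismatch"):
        load_checkpoint(path)
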