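"""Stereoisomer and conformer discrimination experiments.

Because the encoder consumes signed torsions, mirror-image conformers
(identical bond lengths and angles, negated dihedrals) map to different
embeddings, while an encoder with the dihedral channel ablated cannot tell
them apart.  This module provides the pieces to quantify that: full
stereoisomer enumeration, coordinate perturbation with uniform noise,
Kabsch-aligned RMSD, the Davies-Bouldin cluster-separation index, and a
driver that embeds original vs perturbed conformers under several encoder
variants and reports separation statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.EnumerateStereoisomers import (EnumerateStereoisomers,
                                               StereoEnumerationOptions)

from .molgraph import Molecule, generate_conformer, mirror_coords, parse_molecule
from .network import TriGraphEncoder, embed_molecule
from .ssl import encode_dataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stereoisomers

@dataclass
class IsomerSet:
    parent_id: str
    smiles: list[str]              # isomeric SMILES, one per stereoisomer
    molecules: list[Molecule]      # with MMFF94 conformers
    embeddings: np.ndarray | None = None  # (n_isomers, hidden) once computed


def enumerate_stereoisomers(smiles: str, parent_id: str = "mol",
                            seed: int = 0, n_candidates: int = 1,
                            max_isomers: int = 16) -> IsomerSet:
    """All stereocenter assignments of a molecule, each with an MMFF94 conformer.

    A molecule with k independent centers yields 2**k isomers.  Molecules
    without stereocenters return an empty set with a warning.
    """
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"{parent_id}: invalid SMILES")
    opts = StereoEnumerationOptions(onlyUnassigned=False, unique=True,
                                    maxIsomers=max_isomers)
    iso_smiles = sorted(Chem.MolToSmiles(m) for m in EnumerateStereoisomers(rdmol, opts))
    if len(iso_smiles) < 2:
        logger.warning("%s: no stereocenters to enumerate", parent_id)
        return IsomerSet(parent_id, [], [])
    mols = []
    for k, s in enumerate(iso_smiles):
        m = parse_molecule(s, f"{parent_id}_iso{k}")
        mols.append(generate_conformer(m, n_candidates=n_candidates,
                                       seed=(seed * 131 + k) & 0x7FFFFFFF))
    return IsomerSet(parent_id, iso_smiles, mols)


# ---------------------------------------------------------------------------
# Perturbation / alignment

def perturb_conformer(coords: np.ndarray, noise_max: float = 0.5,
                      seed: int = 0) -> np.ndarray:
    """Add independent uniform(0, noise_max) draws to every coordinate."""
    if noise_max <= 0:
        raise ValueError("noise_max must be > 0")
    rng = np.random.default_rng(seed)
    c = np.asarray(coords, dtype=float)
    return c + rng.uniform(0.0, noise_max, size=c.shape)


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (translation + proper rotation).

    Reflections are excluded, so enantiomeric geometries keep a nonzero
    RMSD.  With fewer than 3 atoms only the translation is removed (a
    rotation is underdetermined); this is flagged with a warning.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if len(a) < 3:
        warnings.warn("fewer than 3 atoms: translation-only alignment")
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    u, s, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    # restrict to proper rotations: flip the smallest singular direction
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    a_rot = a @ rot
    return float(np.sqrt(np.mean(np.sum((a_rot - b) ** 2, axis=1))))


def davies_bouldin(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (S_i + S_j) / M_ij ratio, with S the mean centroid distance within a
    cluster and M the distance between centroids.  Lower is better."""
    x = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 labelled groups")
    centroids = np.stack([x[labels == c].mean(axis=0) for c in uniq])
    spreads = np.array([
        np.mean(np.linalg.norm(x[labels == c] - centroids[k], axis=1))
        for k, c in enumerate(uniq)
    ])
    n = len(uniq)
    ratios = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            m = np.linalg.norm(centroids[i] - centroids[j])
            if m < 1e-12:
                raise ZeroDivisionError(
                    f"coincident centroids for groups {uniq[i]!r} and {uniq[j]!r}")
            ratios[i, j] = (spreads[i] + spreads[j]) / m
    return float(np.mean(ratios.max(axis=1)))


# ---------------------------------------------------------------------------
# Experiment driver

@dataclass
class SeparationReport:
    """Separation statistics for original vs perturbed conformer embeddings."""

    per_encoder_distance: dict[str, np.ndarray]  # per-molecule embedding distance
    mean_distance: dict[str, float]
    db_index: dict[str, float]                   # over {original, perturbed} labels
    mean_rmsd: float                             # mean Kabsch-aligned RMSD
    rmsds: np.ndarray = field(default_factory=lambda: np.zeros(0))


def run_discrimination_experiment(mols: list[Molecule],
                                  encoders: dict[str, TriGraphEncoder],
                                  noise_max: float = 0.5,
                                  seed: int = 0) -> SeparationReport:
    """Embed each conformer and a noise-perturbed copy under every encoder.

    Reports per-molecule embedding distances, the Davies-Bouldin index over
    the {original, perturbed} groups, and the mean Kabsch-aligned RMSD of
    the perturbation itself.  Molecules must carry conformers.
    """
    if not encoders:
        raise ValueError("at least one encoder variant required")
    perturbed = [m.with_coords(perturb_conformer(m.coords, noise_max,
                                                 seed=(seed * 613 + k) & 0x7FFFFFFF))
                 for k, m in enumerate(mols)]
    rmsds = np.array([kabsch_rmsd(m.coords, p.coords)
                      for m, p in zip(mols, perturbed)])

    enc_orig = encode_dataset(mols)
    enc_pert = encode_dataset(perturbed)
    per_dist: dict[str, np.ndarray] = {}
    mean_dist: dict[str, float] = {}
    db: dict[str, float] = {}
    for name, model in encoders.items():
        e_orig = np.stack([embed_molecule(model, e.graph, e.feats) for e in enc_orig])
        e_pert = np.stack([embed_molecule(model, e.graph, e.feats) for e in enc_pert])
        d = np.linalg.norm(e_orig - e_pert, axis=1)
        per_dist[name] = d
        mean_dist[name] = float(d.mean())
        stacked = np.concatenate([e_orig, e_pert])
        labels = np.array(["original"] * len(mols) + ["perturbed"] * len(mols))
        db[name] = davies_bouldin(stacked, labels)
    return SeparationReport(per_dist, mean_dist, db, float(rmsds.mean()), rmsds)


def enantiomer_embedding_distance(mol: Molecule, model: TriGraphEncoder) -> float:
    """Embedding distance between a conformer and its mirror image.

    The mirrored copy has identical lengths/angles and negated torsions, so
    this isolates exactly the dihedral channel's contribution.
    """
    if mol.coords is None:
        raise ValueError(f"{mol.id}: conformer required")
    pair = [mol, mol.with_coords(mirror_coords(mol.coords))]
    enc = encode_dataset(pair)
    e = [embed_molecule(model, x.graph, x.feats) for x in enc]
    return float(np.linalg.norm(e[0] - e[1]))
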