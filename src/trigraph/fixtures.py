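"""Deterministic built-in data: molecules, surrogate electronic labels, toy targets.

Everything any pipeline stage consumes can be produced here without a
download: a curated drug-like molecule list (rings, heteroatoms, 1-4
stereocenters, plus degenerate edge cases), surrogate quantum-chemistry
labels (per-atom partial charges in roughly [-1, 1], per-bond orders near
the nominal order), and toy property targets with a known generating
formula.

The surrogate charges are a deliberately *topological* signal
(electronegativity contrast with the bonded neighbourhood) so that learning
checks isolate the model machinery from conformer noise; the surrogate bond
orders depend on the actual bond length on purpose, exercising the
geometric input path.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .molgraph import (Molecule, generate_conformer, parse_molecule,
                       read_sdf_file, to_sdf_block)

# Pauling electronegativities for the heavy-atom vocabulary.
ELECTRONEGATIVITY = {
    "C": 2.55, "N": 3.04, "O": 3.44, "S": 2.58, "F": 3.98, "Cl": 3.16,
    "Br": 2.96, "I": 2.66, "P": 2.19, "B": 2.04, "Si": 1.90, "Se": 2.55,
}

# Reference equilibrium lengths (Angstrom) by nominal bond order.
REFERENCE_LENGTHS = {1.0: 1.50, 1.5: 1.40, 2.0: 1.33, 3.0: 1.20}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic label generators."""

    n_molecules: int | None = None  # None = full builtin set
    seed: int = 0
    label_noise: float = 0.02       # sd of gaussian noise on charges / orders
    kappa: float = -0.2             # charge per unit electronegativity contrast
    length_sensitivity: float = 1.0  # bond-order change per Angstrom stretch
    electronegativity: dict[str, float] = field(
        default_factory=lambda: dict(ELECTRONEGATIVITY))


# ---------------------------------------------------------------------------
# Built-in molecule list

_NAMED = [
    # edge cases: single heavy atom, diatomic, linear nitrile (collinear triple)
    "C", "CO", "C#N", "CC#N", "CC(C)=O", "O=C=O",
    # small drugs / natural products
    "CC(=O)Oc1ccccc1C(=O)O",                 # aspirin
    "CC(=O)Nc1ccc(O)cc1",                    # paracetamol
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",            # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",            # ibuprofen
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",          # naproxen
    "OC(=O)c1ccccc1O",                       # salicylic acid
    "Nc1ccc(cc1)S(N)(=O)=O",                 # sulfanilamide
    "CN1CCC[C@H]1c1cccnc1",                  # nicotine (1 stereocenter)
    "CC(C)[C@@H]1CC[C@@H](C)C[C@H]1O",       # menthol (3 stereocenters)
    "C[C@@H](NC)[C@H](O)c1ccccc1",           # ephedrine (2 stereocenters)
    "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O",  # glucopyranose
    "OC[C@@H](O)[C@H](O)[C@H](O)C=O",        # ribose chain (3 stereocenters)
    "C[C@H](N)C(=O)O",                       # alanine
    "N[C@@H](Cc1ccccc1)C(=O)O",              # phenylalanine
    "C[C@@H](O)[C@H](N)C(=O)O",              # threonine (2 stereocenters)
    "N[C@@H](CO)C(=O)O",                     # serine
    "OC(=O)[C@@H]1CCCN1",                    # proline
    "C[C@H](O)CC", "C[C@H](Cl)CC", "C[C@H](O)c1ccccc1",
    "C[C@H](O)[C@@H](C)N", "O[C@H]1CC[C@@H](O)CC1",
    "C[C@@H]1CC[C@H](C)CC1", "C[C@H](O)[C@@H](N)[C@H](C)O",
    "C[C@H](O)[C@@H](O)[C@H](O)[C@@H](O)C",  # 4 stereocenters
    "C[C@@H]1C[C@H](O)C[C@@H](C)C1",
    "O[C@@H]1[C@H](O)[C@@H](O)[C@H](O)C1",   # cyclopentane tetraol
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "C1COCCN1", "C1CCNC1",
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccc2ncccc2c1",
    "CCCCCC", "CCCCCCCC", "CC(C)CC(C)(C)C", "C1CC1", "CCC", "C=C", "C#C",
    "CC(=O)OCC", "CCOC(=O)c1ccccc1", "CCN(CC)CC", "CN(C)C=O", "CS(=O)C",
    "O=C(O)CCCCC(=O)O", "NCCO", "OCCO", "OCC(O)CO", "ClCCl", "FC(F)F",
]

_PARA_R = [
    "C", "CC", "CCC", "CCCC", "OC", "OCC", "N(C)C", "F",
    "Cl", "Br", "I", "C(=O)O", "C(=O)OC", "C(=O)N", "C#N", "C(C)C",
    "C(C)(C)C", "C(=O)C", "SC", "CO", "CCO", "CCN", "C(F)(F)F",
    "OC(F)(F)F", "S(=O)(=O)N", "C=C", "OCC(=O)O", "N9CCOCC9",
    "CN9CCCC9", "OCCN(C)C", "N9CCN(C)CC9", "CC(=O)N",
]

_TEMPLATES = [
    "CC(=O)Nc1ccc({R})cc1",                   # acetanilides
    "O=C(Nc1ccc({R})cc1)c1ccc(C)cc1",         # toluamide anilides
    "Cc1ccc(S(=O)(=O)N{R0})cc1",              # tosylamides (alkyl R only)
    "c1ccc(-c2ccc({R})cc2)cc1",               # biphenyls
    "COc1ccc(CC(=O)O{R0})cc1",                # arylacetate esters
    "O=C(O{R0})c1ccc(O)cc1",                  # 4-hydroxybenzoates
    "c1ccc(CN2CCN({R0})CC2)cc1",              # benzylpiperazines
    "O=C({R0})Nc1ccc(OC)cc1",                 # anisidide amides
    "COc1ccc(-c2nc(N3CCOCC3)cc({R})n2)cc1",   # anisyl pyrimidines
    "O=C(N{R0})c1ccc2ccccc2c1",               # naphthamides
]

_ALKYL_R = ["CC", "CCC", "CCCC", "CCCCC", "C(C)C", "CCO", "CCN(C)C",
            "CC(C)C", "CCOC", "CCCOC", "CCN9CCCC9", "CCc9ccccc9",
            "C9CCCCC9", "Cc9ccccc9", "Cc9ccco9", "CCN9CCOCC9"]


def _expand_templates() -> list[str]:
    out = []
    for tpl in _TEMPLATES:
        if "{R0}" in tpl:
            out += [tpl.replace("{R0}", r) for r in _ALKYL_R]
        else:
            out += [tpl.replace("{R}", r) for r in _PARA_R]
    return out


def builtin_molecules() -> list[tuple[str, str]]:
    """The curated fixture set as ``(id, SMILES)`` pairs (deterministic).

    Spans rings, heteroatoms, molecules with 1-4 stereocenters, and
    degenerate cases (single heavy atom, diatomics, a linear nitrile).
    """
    smiles: list[str] = []
    seen: set[str] = set()
    for s in _NAMED + _expand_templates():
        canon = Chem.CanonSmiles(s)
        if canon not in seen:
            seen.add(canon)
            smiles.append(s)
    return [(f"fx{k:03d}", s) for k, s in enumerate(smiles)]


def builtin_dataset(spec: FixtureSpec | None = None) -> list[Molecule]:
    """Parsed builtin molecules (no conformers attached)."""
    spec = spec or FixtureSpec()
    pairs = builtin_molecules()
    if spec.n_molecules is not None:
        pairs = pairs[: spec.n_molecules]
    return [parse_molecule(s, mol_id) for mol_id, s in pairs]


def druglike_subset(mols: list[Molecule], min_heavy: int = 12) -> list[Molecule]:
    """Members of a molecule list at drug-like size (>= min_heavy atoms).

    The perturbation / discrimination experiments emulate sampling from a
    commercial drug-like library, which contains no tiny fragments; the
    fixture set's degenerate graph-test cases are excluded there.
    """
    return [m for m in mols if m.n_atoms >= min_heavy]


def attach_conformers(mols: list[Molecule], seed: int = 0,
                      n_candidates: int = 1) -> list[Molecule]:
    """MMFF94 conformers for a molecule list, one deterministic sub-seed each."""
    out = []
    for k, m in enumerate(mols):
        out.append(generate_conformer(m, n_candidates=n_candidates,
                                      seed=(seed * 7919 + k) & 0x7FFFFFFF))
    return out


# ---------------------------------------------------------------------------
# Surrogate electronic labels

def surrogate_electronic_labels(mol: Molecule, spec: FixtureSpec | None = None,
                                rng: np.random.Generator | None = None,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Surrogate (charge, bond-order) labels emulating DFT-derived targets.

    charge(u) = kappa * (EN(u) - mean EN of bonded neighbours) + noise,
    re-centred so the molecule's charges sum to its total formal charge;
    order(u,v) = nominal order - c * (l_uv - reference length) + noise.
    """
    spec = spec or FixtureSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if mol.coords is None:
        raise ValueError(f"{mol.id}: conformer required for surrogate labels")
    en = spec.electronegativity
    for a in mol.atoms:
        if a.symbol not in en:
            raise KeyError(f"{mol.id}: element {a.symbol} missing from EN table")

    nbrs: list[list[int]] = [[] for _ in range(mol.n_atoms)]
    for b in mol.bonds:
        nbrs[b.i].append(b.j)
        nbrs[b.j].append(b.i)
    charges = np.zeros(mol.n_atoms)
    for u, a in enumerate(mol.atoms):
        if nbrs[u]:
            nbr_en = np.mean([en[mol.atoms[v].symbol] for v in nbrs[u]])
            charges[u] = spec.kappa * (en[a.symbol] - nbr_en)
    charges += rng.normal(0.0, spec.label_noise, size=mol.n_atoms)
    charges = np.clip(charges, -1.0, 1.0)
    total_formal = float(sum(a.formal_charge for a in mol.atoms))
    charges += (total_formal - charges.sum()) / mol.n_atoms

    coords = np.asarray(mol.coords)
    orders = np.zeros(mol.n_bonds)
    for k, b in enumerate(mol.bonds):
        length = float(np.linalg.norm(coords[b.i] - coords[b.j]))
        ref = REFERENCE_LENGTHS[b.order]
        orders[k] = b.order - spec.length_sensitivity * (length - ref)
    orders += rng.normal(0.0, spec.label_noise, size=mol.n_bonds)
    return charges, orders


# ---------------------------------------------------------------------------
# Toy property targets

# label = W_HETERO*(heteroatom count) + W_RING*(ring count)
#         + W_ROT*(rotatable-bond count) + gaussian noise
W_HETERO, W_RING, W_ROT = 0.5, 0.3, -0.2
# classification threshold: the median noiseless score of the builtin set
CLASS_THRESHOLD = 1.3


def descriptor_counts(mol: Molecule) -> tuple[int, int, int]:
    """(heteroatoms, rings, rotatable bonds) for the toy-target formula."""
    n_hetero = sum(1 for a in mol.atoms if a.symbol != "C")
    if mol.rdmol is not None:
        n_rings = mol.rdmol.GetRingInfo().NumRings()
        n_rot = Descriptors.NumRotatableBonds(mol.rdmol)
    else:  # pragma: no cover
        n_rings, n_rot = 0, 0
    return n_hetero, int(n_rings), int(n_rot)


def toy_property_targets(mol: Molecule, kind: str = "regression",
                         seed: int = 0, noise: float = 0.1) -> float:
    """A label with a known generating process, keyed by molecule id + seed."""
    n_het, n_ring, n_rot = descriptor_counts(mol)
    score = W_HETERO * n_het + W_RING * n_ring + W_ROT * n_rot
    h = int.from_bytes(hashlib.sha256(f"{mol.id}:{seed}".encode()).digest()[:4], "big")
    eps = float(np.random.default_rng(h).normal(0.0, noise)) if noise > 0 else 0.0
    if kind == "regression":
        return score + eps
    if kind == "classification":
        return float(score + eps > CLASS_THRESHOLD)
    raise ValueError(f"unknown task kind {kind!r}")


# ---------------------------------------------------------------------------
# On-disk dataset

def dataset_digest(mols: list[Molecule]) -> str:
    """Stable hash of ids + coordinates rounded to 1e-4 Angstrom."""
    h = hashlib.sha256()
    for m in mols:
        h.update(m.id.encode())
        if m.coords is not None:
            h.update(np.round(np.asarray(m.coords), 4).tobytes())
    return h.hexdigest()[:16]


def write_dataset(out_dir, mols: list[Molecule], spec: FixtureSpec | None = None) -> str:
    """Write manifest, SDF conformers, electronic labels and toy targets.

    These are exactly the formats the pretraining / fine-tuning readers
    consume, closing the loop. Returns the dataset digest.
    """
    spec = spec or FixtureSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    with open(out / "manifest.tsv", "w") as fh:
        fh.write("id\tsmiles\n")
        for m in mols:
            smiles = Chem.MolToSmiles(m.rdmol) if m.rdmol is not None else ""
            fh.write(f"{m.id}\t{smiles}\n")
    with open(out / "conformers.sdf", "w") as fh:
        for m in mols:
            fh.write(to_sdf_block(m))
    with open(out / "atom_labels.tsv", "w") as fa, open(out / "bond_labels.tsv", "w") as fb:
        fa.write("id\tatom_index\tcharge\n")
        fb.write("id\tbond_index\torder\n")
        for m in mols:
            charges, orders = surrogate_electronic_labels(m, spec, rng)
            for i, q in enumerate(charges):
                fa.write(f"{m.id}\t{i}\t{q:.6f}\n")
            for i, w in enumerate(orders):
                fb.write(f"{m.id}\t{i}\t{w:.6f}\n")
    with open(out / "properties.tsv", "w") as fh:
        fh.write("id\tregression\tclassification\n")
        for m in mols:
            y = toy_property_targets(m, "regression", spec.seed)
            c = toy_property_targets(m, "classification", spec.seed)
            fh.write(f"{m.id}\t{y:.6f}\t{c:.0f}\n")
    return dataset_digest(mols)


def read_dataset(data_dir) -> list[Molecule]:
    """Read a written dataset back: conformers + electronic labels attached."""
    data = Path(data_dir)
    mols = read_sdf_file(data / "conformers.sdf")
    atom_labels: dict[str, dict[int, float]] = {}
    bond_labels: dict[str, dict[int, float]] = {}
    have = {}
    for fname, store in (("atom_labels.tsv", atom_labels),
                         ("bond_labels.tsv", bond_labels)):
        path = data / fname
        have[fname] = path.exists()
        if not have[fname]:
            continue
        with open(path) as fh:
            next(fh)
            for line in fh:
                mol_id, idx, val = line.split("\t")
                store.setdefault(mol_id, {})[int(idx)] = float(val)
    for m in mols:
        if have["atom_labels.tsv"]:
            d = atom_labels.get(m.id, {})
            m.atom_labels = np.array([d[i] for i in range(m.n_atoms)])
        if have["bond_labels.tsv"]:
            d = bond_labels.get(m.id, {})
            m.bond_labels = np.array([d[i] for i in range(m.n_bonds)])
    return mols


def read_properties(data_dir) -> dict[str, dict[str, float]]:
    """Property table as {column: {id: value}}."""
    out: dict[str, dict[str, float]] = {}
    with open(Path(data_dir) / "properties.tsv") as fh:
        header = next(fh).strip().split("\t")[1:]
        for col in header:
            out[col] = {}
        for line in fh:
            parts = line.strip().split("\t")
            for col, val in zip(header, parts[1:]):
                out[col][parts[0]] = float(val)
    return out
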