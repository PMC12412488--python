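"""Molecule parsing, MMFF94 conformers, the three-level graph, and geometry.

A molecule is encoded at three linked levels:

* the atom-bond graph ``G`` (atoms are nodes, bonds are edges),
* the bond-angle graph ``H`` (bonds are nodes; a bond angle, i.e. a pair of
  bonds sharing an atom, is an edge),
* the angle-dihedral graph ``I`` (bond angles are nodes; a dihedral, i.e. a
  pair of angles sharing a central bond, is an edge).

Together with the internal coordinates measured on a conformer (bond
lengths, bond angles, signed torsions, the all-pairs distance matrix) this
is a complete, rigid-motion-invariant description of a 3D molecular
structure.  Torsions are kept *signed*, so mirror images (enantiomers)
receive different encodings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")


class ParseError(ValueError):
    """Input text could not be interpreted as a molecule."""


class EmbedError(RuntimeError):
    """Conformer embedding or force-field setup failed."""


class GeometryError(ValueError):
    """Coordinates are degenerate beyond what flags can absorb."""


# ---------------------------------------------------------------------------
# Molecule

_HYB_TAGS = {
    Chem.HybridizationType.S: "S",
    Chem.HybridizationType.SP: "SP",
    Chem.HybridizationType.SP2: "SP2",
    Chem.HybridizationType.SP3: "SP3",
    Chem.HybridizationType.SP3D: "SP3D",
    Chem.HybridizationType.SP3D2: "SP3D2",
}

_CHI_TAGS = {
    Chem.ChiralType.CHI_UNSPECIFIED: "none",
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "CW",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "CCW",
}


@dataclass
class Atom:
    symbol: str
    formal_charge: int
    degree: int
    n_implicit_h: int
    hybridization: str
    aromatic: bool
    chirality: str


@dataclass
class Bond:
    i: int
    j: int
    order: float  # 1, 1.5, 2, 3
    in_ring: bool
    stereo: str


@dataclass
class Molecule:
    """Heavy-atom molecular graph with optional 3D coordinates and labels."""

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    coords: np.ndarray | None = None  # (n_atoms, 3) in Angstrom
    atom_labels: np.ndarray | None = None  # per-atom partial charges
    bond_labels: np.ndarray | None = None  # per-bond Wiberg-style orders
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def validate(self) -> None:
        n = self.n_atoms
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"{self.id}: bond endpoint out of range")
            if b.i == b.j:
                raise ValueError(f"{self.id}: self-bond at atom {b.i}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"{self.id}: duplicate bond {key}")
            seen.add(key)
        if self.coords is not None:
            c = np.asarray(self.coords)
            if c.shape != (n, 3) or not np.all(np.isfinite(c)):
                raise ValueError(f"{self.id}: bad coordinate array")

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        out = Molecule(self.id, self.atoms, self.bonds, np.asarray(coords, dtype=float),
                       self.atom_labels, self.bond_labels, self.rdmol)
        out.validate()
        return out


def _from_rdmol(rdmol: Chem.Mol, mol_id: str) -> Molecule:
    rdmol = Chem.RemoveHs(rdmol)
    if rdmol.GetNumAtoms() == 0 or all(a.GetAtomicNum() <= 1 for a in rdmol.GetAtoms()):
        raise ParseError(f"{mol_id}: no heavy atoms")
    Chem.AssignStereochemistry(rdmol, cleanIt=True, force=True)
    atoms = [
        Atom(
            symbol=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            degree=a.GetDegree(),
            n_implicit_h=a.GetTotalNumHs(),
            hybridization=_HYB_TAGS.get(a.GetHybridization(), "other"),
            aromatic=a.GetIsAromatic(),
            chirality=_CHI_TAGS.get(a.GetChiralTag(), "other"),
        )
        for a in rdmol.GetAtoms()
    ]
    bonds = [
        Bond(
            i=b.GetBeginAtomIdx(),
            j=b.GetEndAtomIdx(),
            order=1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble()),
            in_ring=b.IsInRing(),
            stereo=str(b.GetStereo()).removeprefix("STEREO").lower(),
        )
        for b in rdmol.GetBonds()
    ]
    coords = None
    if rdmol.GetNumConformers() > 0:
        coords = np.array(rdmol.GetConformer().GetPositions(), dtype=float)
    mol = Molecule(mol_id, atoms, bonds, coords, rdmol=rdmol)
    mol.validate()
    return mol


def parse_molecule(text: str, mol_id: str = "mol") -> Molecule:
    """Parse a SMILES string or a single-record SDF (V2000) block.

    Explicit hydrogens are stripped; the implicit-hydrogen count survives as
    an atom attribute.  SDF coordinates, when present, are attached.
    """
    if "V2000" in text or "$$$$" in text or text.count("\n") > 3:
        rdmol = Chem.MolFromMolBlock(text, removeHs=True)
        if rdmol is None:
            raise ParseError(f"{mol_id}: invalid SDF block")
    else:
        rdmol = Chem.MolFromSmiles(text.strip())
        if rdmol is None:
            raise ParseError(f"{mol_id}: invalid SMILES {text.strip()!r}")
    return _from_rdmol(rdmol, mol_id)


def read_smiles_file(path) -> list[Molecule]:
    """One molecule per line: ``SMILES[<tab>id]``."""
    mols = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"line{k + 1}"
            mols.append(parse_molecule(smiles, mol_id))
    return mols


def to_sdf_block(mol: Molecule) -> str:
    """Serialize a molecule (with conformer) to a V2000 SDF record."""
    if mol.coords is None or mol.rdmol is None:
        raise ValueError(f"{mol.id}: conformer required for SDF export")
    rdmol = Chem.Mol(mol.rdmol)
    conf = Chem.Conformer(rdmol.GetNumAtoms())
    for i, xyz in enumerate(np.asarray(mol.coords)):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    rdmol.RemoveAllConformers()
    rdmol.AddConformer(conf)
    rdmol.SetProp("_Name", mol.id)
    return Chem.MolToMolBlock(rdmol, kekulize=True) + "$$$$\n"


def read_sdf_file(path) -> list[Molecule]:
    mols = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for k, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"{path}: unreadable SDF record #{k}")
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"sdf{k}"
        mols.append(_from_rdmol(rdmol, name))
    return mols


# ---------------------------------------------------------------------------
# Conformers

def generate_conformer(mol: Molecule, n_candidates: int = 5, seed: int = 0) -> Molecule:
    """Embed ``n_candidates`` conformers, MMFF94-optimize each, keep the
    lowest-energy one.  Deterministic for a fixed seed (single-threaded)."""
    if mol.rdmol is None:
        raise EmbedError(f"{mol.id}: no structure to embed")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    mh = Chem.AddHs(Chem.Mol(mol.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.numThreads = 1
    conf_ids = AllChem.EmbedMultipleConfs(mh, numConfs=n_candidates, params=params)
    if len(conf_ids) == 0:
        params.useRandomCoords = True
        conf_ids = AllChem.EmbedMultipleConfs(mh, numConfs=n_candidates, params=params)
    if len(conf_ids) == 0:
        raise EmbedError(f"{mol.id}: conformer embedding failed")
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(mh, maxIters=500)
    except Exception as exc:  # pragma: no cover - exotic elements
        raise EmbedError(f"{mol.id}: MMFF94 setup failed: {exc}") from exc
    energies = [e if ok == 0 or e is not None else np.inf for ok, e in results]
    best = int(np.argmin(energies))
    n_heavy = mol.n_atoms
    coords = np.array(mh.GetConformer(conf_ids[best]).GetPositions())[:n_heavy]
    return mol.with_coords(coords)


def mirror_coords(coords: np.ndarray) -> np.ndarray:
    """Reflect through the xy-plane: the enantiomeric conformer.

    Lengths, angles and distances are untouched; every torsion flips sign.
    """
    out = np.array(coords, dtype=float, copy=True)
    out[:, 2] *= -1.0
    return out


# ---------------------------------------------------------------------------
# The three graphs

@dataclass
class TriGraph:
    """Linked atom-bond (G), bond-angle (H) and angle-dihedral (I) graphs.

    ``bonds`` / ``angles`` / ``dihedrals`` hold one canonical copy per
    undirected element; the edge arrays carry both orientations so message
    passing is symmetric.
    """

    n_atoms: int
    bonds: np.ndarray        # (n_bonds, 2) undirected, i<j
    g_edges: np.ndarray      # (2*n_bonds, 2) directed (src, dst)
    g_edge_bond: np.ndarray  # (2*n_bonds,) undirected bond id per directed edge
    angles: np.ndarray       # (n_angles, 3) canonical (u, v, w), u<w, apex v
    h_edges: np.ndarray      # (2*n_angles, 2) directed (src bond id, dst bond id)
    h_edge_angle: np.ndarray  # (2*n_angles,) undirected angle id
    dihedrals: np.ndarray    # (n_dihedrals, 4) canonical (u, v, w, x)
    i_edges: np.ndarray      # (2*n_dihedrals, 2) directed (src angle id, dst angle id)
    i_edge_dihedral: np.ndarray  # (2*n_dihedrals,)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_dihedrals(self) -> int:
        return len(self.dihedrals)


def _canon_angle(u: int, v: int, w: int) -> tuple[int, int, int]:
    return (u, v, w) if u < w else (w, v, u)


def _canon_dihedral(u: int, v: int, w: int, x: int) -> tuple[int, int, int, int]:
    return (u, v, w, x) if (v, w, u, x) < (w, v, x, u) else (x, w, v, u)


def build_trigraph(mol: Molecule) -> TriGraph:
    """Enumerate bonds, bond angles and dihedrals and their incidences.

    Angles are all triples (u, v, w) with u, w neighbours of the apex v and
    u != w; dihedrals are all quadruples (u, v, w, x) around each bond
    (v, w) with u a neighbour of v (u != w), x a neighbour of w (x != v),
    and u != x (a three-ring closes with u == x, which is no dihedral).
    """
    n = mol.n_atoms
    nbrs: list[list[int]] = [[] for _ in range(n)]
    bond_id: dict[tuple[int, int], int] = {}
    bonds = []
    for b in mol.bonds:
        i, j = (b.i, b.j) if b.i < b.j else (b.j, b.i)
        bond_id[(i, j)] = len(bonds)
        bonds.append((i, j))
        nbrs[i].append(j)
        nbrs[j].append(i)
    for lst in nbrs:
        lst.sort()

    def bid(a: int, b: int) -> int:
        return bond_id[(a, b) if a < b else (b, a)]

    g_edges, g_edge_bond = [], []
    for k, (i, j) in enumerate(bonds):
        g_edges += [(i, j), (j, i)]
        g_edge_bond += [k, k]

    angles = []
    angle_id: dict[tuple[int, int, int], int] = {}
    for v in range(n):
        for a in range(len(nbrs[v])):
            for b in range(a + 1, len(nbrs[v])):
                u, w = nbrs[v][a], nbrs[v][b]
                key = _canon_angle(u, v, w)
                angle_id[key] = len(angles)
                angles.append(key)

    h_edges, h_edge_angle = [], []
    for k, (u, v, w) in enumerate(angles):
        h_edges += [(bid(u, v), bid(v, w)), (bid(v, w), bid(u, v))]
        h_edge_angle += [k, k]

    dihedrals = []
    seen: set[tuple[int, int, int, int]] = set()
    for v, w in bonds:
        for side in ((v, w), (w, v)):
            vv, ww = side
            for u in nbrs[vv]:
                if u == ww:
                    continue
                for x in nbrs[ww]:
                    if x == vv or x == u:
                        continue
                    key = _canon_dihedral(u, vv, ww, x)
                    if key not in seen:
                        seen.add(key)
                        dihedrals.append(key)

    i_edges, i_edge_dihedral = [], []
    for k, (u, v, w, x) in enumerate(dihedrals):
        a1 = angle_id[_canon_angle(u, v, w)]
        a2 = angle_id[_canon_angle(v, w, x)]
        i_edges += [(a1, a2), (a2, a1)]
        i_edge_dihedral += [k, k]

    def arr(x, ncol):
        return (np.array(x, dtype=np.intp) if x
                else np.zeros((0, ncol), dtype=np.intp) if ncol > 1
                else np.zeros(0, dtype=np.intp))

    return TriGraph(
        n_atoms=n,
        bonds=arr(bonds, 2),
        g_edges=arr(g_edges, 2),
        g_edge_bond=arr(g_edge_bond, 1),
        angles=arr(angles, 3),
        h_edges=arr(h_edges, 2),
        h_edge_angle=arr(h_edge_angle, 1),
        dihedrals=arr(dihedrals, 4),
        i_edges=arr(i_edges, 2),
        i_edge_dihedral=arr(i_edge_dihedral, 1),
    )


# ---------------------------------------------------------------------------
# Geometry

@dataclass
class GeometricFeatures:
    lengths: np.ndarray           # per undirected bond, Angstrom
    angles: np.ndarray            # per undirected angle, radians in [0, pi]
    dihedrals: np.ndarray         # per undirected dihedral, radians in [-pi, pi)
    dist_matrix: np.ndarray       # (n, n) Angstrom
    angle_degenerate: np.ndarray  # bool flags: collinear triples
    dihedral_degenerate: np.ndarray  # bool flags: collinear frames

    def validate(self) -> None:
        if np.any(self.lengths <= 0):
            raise GeometryError("non-positive bond length")
        if not np.allclose(self.dist_matrix, self.dist_matrix.T, atol=1e-9):
            raise GeometryError("distance matrix not symmetric")


_COLLINEAR_EPS = 1e-7


def signed_dihedral(p0, p1, p2, p3) -> tuple[float, bool]:
    """Signed torsion about the p1-p2 axis via the atan2 convention.

    Returns (theta in [-pi, pi), degenerate flag). A collinear frame (either
    bonded triple collinear) has no defined torsion; it reports 0, flagged.
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n0 = np.cross(b0, b1)
    n1 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if np.linalg.norm(n0) < _COLLINEAR_EPS or np.linalg.norm(n1) < _COLLINEAR_EPS or nb1 < _COLLINEAR_EPS:
        return 0.0, True
    theta = math.atan2(np.dot(np.cross(n0, n1), b1 / nb1), np.dot(n0, n1))
    if theta >= math.pi:  # fold +pi onto -pi so the range is [-pi, pi)
        theta -= 2 * math.pi
    return theta, False


def compute_geometry(coords: np.ndarray, graph: TriGraph) -> GeometricFeatures:
    """All internal coordinates of a conformer on a TriGraph."""
    c = np.asarray(coords, dtype=float)
    if c.shape != (graph.n_atoms, 3) or not np.all(np.isfinite(c)):
        raise GeometryError("coords must be a finite (n_atoms, 3) array")

    diff = c[:, None, :] - c[None, :, :]
    dist_matrix = np.sqrt((diff**2).sum(axis=-1))

    if graph.n_bonds:
        lengths = np.linalg.norm(c[graph.bonds[:, 0]] - c[graph.bonds[:, 1]], axis=1)
        if np.any(lengths < 1e-6):
            k = int(np.argmin(lengths))
            raise GeometryError(f"coincident bonded atoms {tuple(graph.bonds[k])}")
    else:
        lengths = np.zeros(0)

    n_a = graph.n_angles
    angles = np.zeros(n_a)
    angle_degenerate = np.zeros(n_a, dtype=bool)
    if n_a:
        v1 = c[graph.angles[:, 0]] - c[graph.angles[:, 1]]
        v2 = c[graph.angles[:, 2]] - c[graph.angles[:, 1]]
        nrm = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        cosang = np.clip((v1 * v2).sum(axis=1) / np.maximum(nrm, 1e-300), -1.0, 1.0)
        angles = np.arccos(cosang)
        angle_degenerate = np.abs(np.abs(cosang) - 1.0) < _COLLINEAR_EPS

    n_d = graph.n_dihedrals
    dihedrals = np.zeros(n_d)
    dihedral_degenerate = np.zeros(n_d, dtype=bool)
    for k, (u, v, w, x) in enumerate(graph.dihedrals):
        dihedrals[k], dihedral_degenerate[k] = signed_dihedral(c[u], c[v], c[w], c[x])

    geo = GeometricFeatures(lengths, angles, dihedrals, dist_matrix,
                            angle_degenerate, dihedral_degenerate)
    geo.validate()
    return geo


# ---------------------------------------------------------------------------
# Initial features

ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se"]
HYBRIDIZATIONS = ["S", "SP", "SP2", "SP3", "SP3D", "SP3D2"]
CHIRALITIES = ["none", "CW", "CCW"]
BOND_ORDERS = [1.0, 1.5, 2.0, 3.0]
BOND_STEREO = ["none", "z", "e", "cis", "trans", "any"]


@dataclass
class FeatureConfig:
    """Vocabularies and radial-basis layout for the initial features."""

    n_rbf: int = 20
    length_range: tuple[float, float] = (0.0, 5.0)       # Angstrom
    angle_range: tuple[float, float] = (0.0, math.pi)
    dihedral_range: tuple[float, float] = (-math.pi, math.pi)
    max_degree: int = 6
    max_implicit_h: int = 4
    charge_range: tuple[int, int] = (-2, 2)


def rbf_expand(values: np.ndarray, lo: float, hi: float, n: int,
               period: float | None = None) -> np.ndarray:
    """Gaussian radial basis: n centers evenly spaced on [lo, hi], width =
    center spacing; each basis element is 1 at its center, in (0, 1] overall.

    With ``period`` set, distances to the centers are angular (wrapped), so
    a torsion of pi - eps and one of -pi + eps receive nearly identical
    features instead of sitting at opposite ends of the grid.
    """
    centers = np.linspace(lo, hi, n, endpoint=period is None)
    width = (centers[1] - centers[0]) if n > 1 else (hi - lo) or 1.0
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    diff = v - centers
    if period is not None:
        diff = (diff + period / 2.0) % period - period / 2.0
    return np.exp(-0.5 * (diff / width) ** 2)


def _onehot(index: int, size: int) -> np.ndarray:
    out = np.zeros(size)
    out[index] = 1.0
    return out


def _vocab_onehot(value, vocab: list) -> np.ndarray:
    # unknown level -> reserved trailing "other" bucket
    idx = vocab.index(value) if value in vocab else len(vocab)
    return _onehot(idx, len(vocab) + 1)


@dataclass
class InitialFeatures:
    x_atom: np.ndarray      # (n_atoms, d_atom) one-hot blocks
    x_bond: np.ndarray      # (n_bonds, d_bond) one-hot blocks + RBF(length)
    x_angle: np.ndarray     # (n_angles, n_rbf) RBF(angle)
    x_dihedral: np.ndarray  # (n_dihedrals, n_rbf) RBF(signed torsion)
    dims: dict[str, int] = field(default_factory=dict)


def featurize(mol: Molecule, graph: TriGraph, geo: GeometricFeatures,
              config: FeatureConfig | None = None) -> InitialFeatures:
    """One-hot categorical features plus RBF-expanded internal coordinates."""
    cfg = config or FeatureConfig()
    lo_q, hi_q = cfg.charge_range

    atom_rows = []
    ring_atoms = set()
    for b in mol.bonds:
        if b.in_ring:
            ring_atoms.update((b.i, b.j))
    for a_idx, a in enumerate(mol.atoms):
        q = min(max(a.formal_charge, lo_q), hi_q) - lo_q
        atom_rows.append(np.concatenate([
            _vocab_onehot(a.symbol, ELEMENTS),
            _onehot(min(a.degree, cfg.max_degree), cfg.max_degree + 1),
            _onehot(q, hi_q - lo_q + 1),
            _onehot(min(a.n_implicit_h, cfg.max_implicit_h), cfg.max_implicit_h + 1),
            _vocab_onehot(a.hybridization, HYBRIDIZATIONS),
            [1.0 if a.aromatic else 0.0],
            [1.0 if a_idx in ring_atoms else 0.0],
            _vocab_onehot(a.chirality, CHIRALITIES),
        ]))
    x_atom = np.array(atom_rows)

    bond_by_key = {(min(b.i, b.j), max(b.i, b.j)): b for b in mol.bonds}
    bond_rows = []
    for k, (i, j) in enumerate(graph.bonds):
        b = bond_by_key[(i, j)]
        bond_rows.append(np.concatenate([
            _vocab_onehot(b.order, BOND_ORDERS),
            [1.0 if b.in_ring else 0.0],
            _vocab_onehot(b.stereo, BOND_STEREO),
            rbf_expand([geo.lengths[k]], *cfg.length_range, cfg.n_rbf)[0],
        ]))
    x_bond = (np.array(bond_rows) if bond_rows
              else np.zeros((0, len(BOND_ORDERS) + 1 + 1 + len(BOND_STEREO) + 1 + cfg.n_rbf)))

    x_angle = rbf_expand(geo.angles, *cfg.angle_range, cfg.n_rbf)
    # torsions live on a circle: use the periodic basis
    x_dihedral = rbf_expand(geo.dihedrals, *cfg.dihedral_range, cfg.n_rbf,
                            period=2.0 * math.pi)
    # degenerate (collinear) elements carry no usable torsion signal
    if len(geo.dihedral_degenerate):
        x_dihedral[geo.dihedral_degenerate] = 0.0
    if len(geo.angle_degenerate):
        x_angle[geo.angle_degenerate] = 0.0

    return InitialFeatures(
        x_atom=x_atom,
        x_bond=x_bond,
        x_angle=x_angle.reshape(graph.n_angles, -1) if graph.n_angles else np.zeros((0, cfg.n_rbf)),
        x_dihedral=(x_dihedral.reshape(graph.n_dihedrals, -1)
                    if graph.n_dihedrals else np.zeros((0, cfg.n_rbf))),
        dims={
            "atom": x_atom.shape[1],
            "bond": x_bond.shape[1],
            "angle": cfg.n_rbf,
            "dihedral": cfg.n_rbf,
        },
    )
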