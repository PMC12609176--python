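"""Structure parsing and residue-level featurization.

A protein chain is turned into

* a 62-dimensional per-residue feature matrix with a fixed block layout
  (secondary structure one-hot | torsion sin/cos | atomic | backbone H-bond
  flags | pseudo-position | physicochemical | amino-acid one-hot), and
* a residue graph whose nodes are residues and whose edges connect residues
  with Calpha-Calpha distance strictly below a cutoff (default 8 A), carrying
  that distance as the edge attribute.

Secondary structure is assigned with DSSP-style rules from Kabsch-Sander
backbone hydrogen bonds (electrostatic energy below -0.5 kcal/mol); amide
hydrogens are placed geometrically when the file has none, as is the case
for predicted-structure models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    AA_3TO1,
    AA_ORDER,
    AROMATIC,
    BACKBONE_ATOMS,
    CHI_ATOMS,
    ELEMENTS,
    HBOND_CAPABILITY,
    PHYSCHEM,
    SIDECHAIN_CHARGE,
)
from .errors import ConsistencyError, EmptyInputError, FormatError

logger = logging.getLogger(__name__)

N_FEATURES = 62
SS_STATES = ("H", "G", "I", "E", "B", "T", "S", "C", "X")  # X = unassigned
TORSION_NAMES = ("phi", "psi", "omega", "chi1", "chi2", "chi3", "chi4", "chi5")

# fixed block offsets within the 62-dim vector
BLOCK_SS = slice(0, 9)
BLOCK_TORSION = slice(9, 25)
BLOCK_ATOMIC = slice(25, 32)
BLOCK_HBOND = slice(32, 34)
BLOCK_POSITION = slice(34, 35)
BLOCK_PHYSCHEM = slice(35, 41)
BLOCK_AA = slice(41, 62)

KS_COUPLING = 0.084 * 332.0  # kcal/mol * A, Kabsch-Sander electrostatic model
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
PEPTIDE_BOND_MAX = 2.5  # A; C(i)-N(i+1) beyond this is a chain break


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) A
    b_factor: float = 0.0
    occupancy: float = 1.0


@dataclass
class Residue:
    index: int  # 0-based position in chain
    name: str  # 3-letter code
    one_letter: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords_of(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coords

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


@dataclass
class ProteinStructure:
    chain_id: str
    residues: list[Residue]
    skipped: list[dict] = field(default_factory=list)  # rejected residues

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        out = np.empty((len(self.residues), 3))
        for i, r in enumerate(self.residues):
            ca = r.coords_of("CA")
            if ca is None:
                raise ConsistencyError(f"residue {i} has no CA atom")
            out[i] = ca
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a copy with every atom rigidly transformed (x -> R x + t)."""
        new_res = []
        for r in self.residues:
            atoms = [Atom(a.name, a.element, rotation @ a.coords + translation,
                          a.b_factor, a.occupancy) for a in r.atoms]
            new_res.append(Residue(r.index, r.name, r.one_letter, atoms))
        return ProteinStructure(self.chain_id, new_res, list(self.skipped))


@dataclass
class TorsionSet:
    """L x 8 torsion angles in degrees, order phi, psi, omega, chi1..chi5."""

    angles: np.ndarray  # (L, 8) degrees in (-180, 180]; 0 where undefined
    defined: np.ndarray  # (L, 8) bool


@dataclass
class HBondMap:
    """Backbone hydrogen bonds: acceptor i (C=O) to donor j (N-H)."""

    flags: np.ndarray  # (L, 2) int, columns (is_donor, is_acceptor)
    bond: np.ndarray  # (L, L) bool, bond[i, j]: O of i accepts from N-H of j


@dataclass
class NodeFeatureMatrix:
    values: np.ndarray  # (L, 62)

    @staticmethod
    def feature_names() -> list[str]:
        names = [f"ss_{s}" for s in SS_STATES]
        for t in TORSION_NAMES:
            names += [f"{t}_sin", f"{t}_cos"]
        names += ["atomic_mass", "b_factor", "sidechain_status",
                  "sidechain_charge", "hbond_capability", "aromatic",
                  "vdw_radius"]
        names += ["hb_donor", "hb_acceptor", "pseudo_position"]
        names += ["pc_hydrophobicity", "pc_polarity", "pc_charge", "pc_pka",
                  "pc_volume", "pc_mass"]
        names += [f"aa_{a}" for a in AA_ORDER]
        return names


@dataclass
class ResidueGraph:
    n_nodes: int
    edges: np.ndarray  # (E, 2) int, i < j
    edge_distance: np.ndarray  # (E,) A
    coords: np.ndarray  # (L, 3) Calpha positions

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for (i, j) in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _is_amino(res: gemmi.Residue) -> bool:
    if res.name in AA_3TO1:
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


def parse_structure(path, chain: str | None = None, model: int | None = None) -> ProteinStructure:
    """Parse a PDB or mmCIF file into a single-chain :class:`ProteinStructure`.

    Waters and hetero compounds are excluded; alternate locations resolve to
    the highest-occupancy conformer (ties: first by file order); residues
    lacking a Calpha are rejected and reported in ``structure.skipped``.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    st.remove_empty_chains()
    if len(st) == 0:
        raise EmptyInputError(f"{path} contains no models")
    if model is None:
        if len(st) > 1:
            logger.info("%s has %d models; using model 1", path, len(st))
        gmodel = st[0]
    else:
        if model < 1 or model > len(st):
            raise FormatError(f"model {model} not in {path} (1..{len(st)})")
        gmodel = st[model - 1]

    gchain = None
    if chain is not None:
        for c in gmodel:
            if c.name == chain:
                gchain = c
                break
        if gchain is None:
            raise FormatError(f"chain {chain!r} not found in {path}")
    else:
        for c in gmodel:
            if any(_is_amino(r) for r in c):
                gchain = c
                break
        if gchain is None:
            raise EmptyInputError(f"{path} has no chain with amino-acid residues")

    residues: list[Residue] = []
    skipped: list[dict] = []
    for gres in gchain:
        if gres.is_water() or not _is_amino(gres):
            continue
        # altloc resolution: per atom name keep highest occupancy, ties first
        chosen: dict[str, gemmi.Atom] = {}
        for a in gres:
            prev = chosen.get(a.name)
            if prev is None or a.occ > prev.occ:
                chosen[a.name] = a
        atoms = [Atom(a.name, a.element.name.upper(),
                      np.array([a.pos.x, a.pos.y, a.pos.z]),
                      float(a.b_iso), float(a.occ))
                 for a in chosen.values()]
        res = Residue(len(residues), gres.name,
                      AA_3TO1.get(gres.name, "X"), atoms)
        if res.atom("CA") is None:
            skipped.append({"seqid": str(gres.seqid), "name": gres.name,
                            "reason": "missing CA"})
            logger.warning("skipping residue %s %s: missing CA", gres.seqid, gres.name)
            continue
        if not np.all(np.isfinite(np.array([a.coords for a in res.atoms]))):
            raise FormatError(f"non-finite coordinates in residue {gres.seqid}")
        residues.append(res)
    if not residues:
        raise EmptyInputError(f"{path} chain {gchain.name!r} has no amino-acid residues")
    return ProteinStructure(gchain.name, residues, skipped)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float | None:
    """Signed dihedral angle in degrees, in (-180, 180]; None when degenerate."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b1n = np.linalg.norm(b1)
    if n1n < 1e-9 or n2n < 1e-9 or b1n < 1e-9:
        return None  # collinear atoms
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b1 / b1n)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def compute_torsions(structure: ProteinStructure) -> TorsionSet:
    """Backbone (phi, psi, omega) and side-chain (chi1..chi5) torsions.

    phi is undefined at the first residue; psi and omega at the last.
    chi_k requires the residue type to possess the standard quadruple and
    all four atoms to be present. Collinear defining atoms flag the angle
    undefined.
    """
    L = len(structure)
    angles = np.zeros((L, 8))
    defined = np.zeros((L, 8), dtype=bool)

    def set_angle(i: int, k: int, pts: list[np.ndarray | None]) -> None:
        if any(p is None for p in pts):
            return
        ang = dihedral(*pts)  # type: ignore[arg-type]
        if ang is None:
            logger.warning("collinear atoms for %s of residue %d", TORSION_NAMES[k], i)
            return
        angles[i, k] = ang
        defined[i, k] = True

    res = structure.residues
    for i, r in enumerate(res):
        n, ca, c = r.coords_of("N"), r.coords_of("CA"), r.coords_of("C")
        if i > 0:
            set_angle(i, 0, [res[i - 1].coords_of("C"), n, ca, c])  # phi
        if i < L - 1:
            set_angle(i, 1, [n, ca, c, res[i + 1].coords_of("N")])  # psi
            set_angle(i, 2, [ca, c, res[i + 1].coords_of("N"),
                             res[i + 1].coords_of("CA")])  # omega
        for k, quad in enumerate(CHI_ATOMS.get(r.name, [])):
            set_angle(i, 3 + k, [r.coords_of(a) for a in quad])
    return TorsionSet(angles, defined)


def _place_amide_hydrogens(structure: ProteinStructure) -> list[np.ndarray | None]:
    """Amide H per residue: from the file if present, else placed 1.01 A from
    N along the bisector of (N-C_prev, N-CA). Prolines and chain-start
    residues have none."""
    res = structure.residues
    out: list[np.ndarray | None] = []
    for i, r in enumerate(res):
        if r.name == "PRO":
            out.append(None)
            continue
        h = r.coords_of("H")
        if h is not None:
            out.append(h)
            continue
        n, ca = r.coords_of("N"), r.coords_of("CA")
        cp = res[i - 1].coords_of("C") if i > 0 else None
        if n is None or ca is None or cp is None or \
                np.linalg.norm(n - cp) > PEPTIDE_BOND_MAX:
            out.append(None)  # chain start or break: no defined H direction
            continue
        u1 = (n - cp) / np.linalg.norm(n - cp)
        u2 = (n - ca) / np.linalg.norm(n - ca)
        u = u1 + u2
        nu = np.linalg.norm(u)
        out.append(None if nu < 1e-9 else n + 1.01 * u / nu)
    return out


def kabsch_sander_energy(c: np.ndarray, o: np.ndarray,
                         n: np.ndarray, h: np.ndarray) -> float:
    """Electrostatic H-bond energy (kcal/mol) for acceptor C=O, donor N-H."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # atom clash: treat as the DSSP minimum energy
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_hbonds(structure: ProteinStructure) -> HBondMap:
    """Kabsch-Sander backbone hydrogen bonds.

    A bond exists from the carbonyl of residue i to the amide of residue j
    (|i - j| >= 2) when the electrostatic energy is below -0.5 kcal/mol.
    The per-residue flags are (is_donor, is_acceptor).
    """
    res = structure.residues
    L = len(res)
    hs = _place_amide_hydrogens(structure)
    bond = np.zeros((L, L), dtype=bool)
    ca = np.full((L, 3), np.nan)
    for i, r in enumerate(res):
        p = r.coords_of("CA")
        if p is not None:
            ca[i] = p
    # candidate pruning: donors/acceptors further than 9 A (Calpha) never bond
    for i in range(L):
        c, o = res[i].coords_of("C"), res[i].coords_of("O")
        if c is None or o is None:
            continue
        for j in range(L):
            if abs(i - j) < 2:
                continue
            n, h = res[j].coords_of("N"), hs[j]
            if n is None or h is None:
                continue
            if np.all(np.isfinite(ca[i])) and np.all(np.isfinite(ca[j])) and \
                    np.linalg.norm(ca[i] - ca[j]) > 9.0:
                continue
            if kabsch_sander_energy(c, o, n, h) < HBOND_ENERGY_CUTOFF:
                bond[i, j] = True
    flags = np.zeros((L, 2), dtype=int)
    flags[:, 0] = bond.any(axis=0).astype(int)  # residue donates its N-H
    flags[:, 1] = bond.any(axis=1).astype(int)  # residue's C=O accepts
    return HBondMap(flags, bond)


# ---------------------------------------------------------------------------
# secondary structure (DSSP-style 8 states + unassigned)
# ---------------------------------------------------------------------------

def assign_secondary_structure(structure: ProteinStructure, hbonds: HBondMap) -> list[str]:
    """8-state DSSP-style assignment from backbone H-bond patterns.

    Priority: H (alpha) > E/B (strands) > G (3-10) > I (pi) > T (turn) >
    S (bend) > C (coil). Residues without a complete backbone are 'X'
    (unassigned).
    """
    res = structure.residues
    L = len(res)
    bond = hbonds.bond

    def turn(i: int, n: int) -> bool:
        return i + n < L and bond[i, i + n]

    ss = ["C"] * L

    def paint(span, state):
        for k in span:
            if ss[k] == "C":
                ss[k] = state

    # alpha helix: two consecutive 4-turns at i-1 and i -> residues i..i+3
    for i in range(1, L):
        if turn(i - 1, 4) and turn(i, 4):
            paint(range(i, min(i + 4, L)), "H")

    # beta bridges and ladders
    bridges: list[tuple[int, int, str]] = []
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            para = (bond[i - 1, j] and bond[j, i + 1]) or \
                   (bond[j - 1, i] and bond[i, j + 1])
            anti = (bond[i, j] and bond[j, i]) or \
                   (bond[i - 1, j + 1] and bond[j - 1, i + 1])
            if para or anti:
                bridges.append((i, j, "P" if para else "A"))
    in_ladder = set()
    bset = set((i, j, t) for i, j, t in bridges)
    for i, j, t in bridges:
        ext = ((i + 1, j + 1, "P") in bset or (i - 1, j - 1, "P") in bset) if t == "P" \
            else ((i + 1, j - 1, "A") in bset or (i - 1, j + 1, "A") in bset)
        if ext:
            in_ladder.add((i, j, t))
    for i, j, t in bridges:
        state = "E" if (i, j, t) in in_ladder else "B"
        for k in (i, j):
            if ss[k] in ("C", "B") and state == "E":
                ss[k] = "E"
            elif ss[k] == "C":
                ss[k] = state

    # 3-10 helix: two consecutive 3-turns
    for i in range(1, L):
        if turn(i - 1, 3) and turn(i, 3):
            paint(range(i, min(i + 3, L)), "G")
    # pi helix: two consecutive 5-turns
    for i in range(1, L):
        if turn(i - 1, 5) and turn(i, 5):
            paint(range(i, min(i + 5, L)), "I")

    # turns: residues strictly inside any single n-turn
    for n in (3, 4, 5):
        for i in range(L):
            if turn(i, n):
                paint(range(i + 1, min(i + n, L)), "T")

    # bends: Calpha(i-2), Calpha(i), Calpha(i+2) kink > 70 degrees
    for i in range(2, L - 2):
        a = res[i - 2].coords_of("CA")
        b = res[i].coords_of("CA")
        c = res[i + 2].coords_of("CA")
        if a is None or b is None or c is None:
            continue
        u, v = b - a, c - b
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        ang = math.degrees(math.acos(np.clip(u @ v / (nu * nv), -1.0, 1.0)))
        if ang > 70.0:
            paint([i], "S")

    for i, r in enumerate(res):
        if not r.has_backbone or r.coords_of("O") is None:
            ss[i] = "X"
    return ss


# ---------------------------------------------------------------------------
# per-residue scalar features
# ---------------------------------------------------------------------------

def residue_atomic_features(residue: Residue) -> np.ndarray:
    """7 atomic-level features aggregated to the residue.

    (mean heavy-atom mass, mean B-factor, side-chain status, formal
    side-chain charge at pH 7, H-bonding capability count, aromatic-ring
    flag, mean heavy-atom vdW radius)
    """
    heavy = [a for a in residue.atoms if a.element != "H"]
    masses, radii = [], []
    for a in heavy:
        if a.element in ELEMENTS:
            m, r = ELEMENTS[a.element]
            masses.append(m)
            radii.append(r)
    mean_mass = float(np.mean(masses)) if masses else 0.0
    mean_radius = float(np.mean(radii)) if radii else 0.0
    mean_b = float(np.mean([a.b_factor for a in residue.atoms])) if residue.atoms else 0.0
    has_sidechain = float(any(
        a.name not in BACKBONE_ATOMS and a.name != "CB" for a in residue.atoms))
    one = residue.one_letter
    if one == "X":
        logger.warning("unknown residue type %s: lookup features set to 0", residue.name)
    charge = SIDECHAIN_CHARGE.get(one, 0.0)
    hb_cap = float(HBOND_CAPABILITY.get(one, 0))
    aromatic = float(one in AROMATIC)
    return np.array([mean_mass, mean_b, has_sidechain, charge, hb_cap,
                     aromatic, mean_radius])


def physchem_features(residue_type: str) -> np.ndarray:
    """Z-scored (hydrophobicity, polarity, charge, pKa, volume, mass)."""
    return PHYSCHEM.get(residue_type, PHYSCHEM["X"]).copy()


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_node_features(structure: ProteinStructure, torsions: TorsionSet,
                        ss: list[str], hbonds: HBondMap) -> NodeFeatureMatrix:
    """Concatenate the feature blocks into the fixed 62-dim layout.

    Undefined torsions contribute (0, 0); the pseudo-position of residue i
    (0-based) in a chain of length L is (i + 1) / L, strictly in (0, 1].
    """
    L = len(structure)
    if not (torsions.angles.shape[0] == len(ss) == hbonds.flags.shape[0] == L):
        raise ConsistencyError(
            f"inconsistent lengths: structure {L}, torsions "
            f"{torsions.angles.shape[0]}, ss {len(ss)}, hbonds {hbonds.flags.shape[0]}")
    out = np.zeros((L, N_FEATURES))
    for i, r in enumerate(structure.residues):
        out[i, BLOCK_SS][SS_STATES.index(ss[i])] = 1.0
        rad = np.radians(torsions.angles[i])
        sc = np.stack([np.sin(rad), np.cos(rad)], axis=1)  # (8, 2)
        sc[~torsions.defined[i]] = 0.0
        out[i, BLOCK_TORSION] = sc.ravel()
        out[i, BLOCK_ATOMIC] = residue_atomic_features(r)
        out[i, BLOCK_HBOND] = hbonds.flags[i]
        out[i, BLOCK_POSITION] = (i + 1) / L
        out[i, BLOCK_PHYSCHEM] = physchem_features(r.one_letter)
        aa_idx = AA_ORDER.index(r.one_letter if r.one_letter in AA_ORDER else "X")
        out[i, BLOCK_AA][aa_idx] = 1.0
    if not np.all(np.isfinite(out)):
        raise ConsistencyError("non-finite node features")
    return NodeFeatureMatrix(out)


def featurize(structure: ProteinStructure) -> tuple[NodeFeatureMatrix, ResidueGraph]:
    """One-call pipeline: torsions, H-bonds, secondary structure, graph."""
    torsions = compute_torsions(structure)
    hbonds = assign_hbonds(structure)
    ss = assign_secondary_structure(structure, hbonds)
    feats = build_node_features(structure, torsions, ss, hbonds)
    graph = build_graph(structure)
    return feats, graph


def build_graph(structure: ProteinStructure, cutoff: float = 8.0) -> ResidueGraph:
    """Residue graph with an edge whenever the Calpha distance is strictly
    below `cutoff` (A); the edge attribute is that distance."""
    coords = structure.ca_coords()
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(r=cutoff))
    edges, dists = [], []
    for i, j in pairs:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < cutoff:  # query_pairs includes ties at exactly the cutoff
            edges.append((i, j))
            dists.append(d)
    return ResidueGraph(
        n_nodes=len(structure),
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        edge_distance=np.array(dists),
        coords=coords,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def features_to_frame(structure: ProteinStructure, feats: NodeFeatureMatrix) -> pd.DataFrame:
    """Node features as a table with 1-based residue numbers."""
    df = pd.DataFrame(feats.values, columns=NodeFeatureMatrix.feature_names())
    df.insert(0, "aa", list(structure.sequence))
    df.insert(0, "residue_number", np.arange(1, len(structure) + 1))
    return df


def write_feature_tsv(path, structure: ProteinStructure, feats: NodeFeatureMatrix) -> None:
    features_to_frame(structure, feats).to_csv(path, sep="\t", index=False)


def write_edges_tsv(path, graph: ResidueGraph) -> None:
    df = pd.DataFrame({
        "i": graph.edges[:, 0] + 1,
        "j": graph.edges[:, 1] + 1,
        "distance_A": graph.edge_distance,
    })
    df.to_csv(path, sep="\t", index=False)


def write_features_h5(path, feats: NodeFeatureMatrix, graph: ResidueGraph) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("node_features", data=feats.values.astype("<f4"))
        f.create_dataset("edges", data=graph.edges)
        f.create_dataset("edge_dist", data=graph.edge_distance.astype("<f4"))
        f.create_dataset("coords", data=graph.coords.astype("<f4"))
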