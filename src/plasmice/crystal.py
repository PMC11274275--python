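"""Hexagonal ice (Ih) supercell builder and structure container.

The oxygen sublattice of ice Ih is the hexagonal-diamond (wurtzite
topology) network: every oxygen has four hydrogen-bonded neighbours at
~2.76 Å in a tetrahedral arrangement.  Protons are placed subject to
the Bernal-Fowler ice rules — two covalent hydrogens per oxygen and
exactly one hydrogen per O···O hydrogen bond — which leaves an
exponentially large set of valid proton configurations.  A seeded
random orientation followed by path-reversal repair samples one of
them reproducibly.

The cell used here is the orthorhombic (a, √3·a, c) representation of
the hexagonal cell, holding 8 water molecules, so that all box angles
are 90° and periodic replication is trivial.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "Structure",
    "build_ice_ih",
    "validate_ice_rules",
    "write_structure",
    "read_structure",
    "DEFAULT_LATTICE",
    "O_H_BOND_LENGTH",
    "H_O_H_ANGLE_DEG",
]

# rigid water geometry (TIP3P)
O_H_BOND_LENGTH = 0.9572   # Å
H_O_H_ANGLE_DEG = 104.52

#: hexagonal lattice constants (a, c) in Å reproducing the reference
#: 768-molecule box when replicated (8, 3, 4): 36.146/8 and 29.414/4.
DEFAULT_LATTICE = (4.518250, 7.353500)

O_O_CUTOFF = 3.0  # Å, hydrogen-bond network detection


@dataclasses.dataclass
class Structure:
    """Atomic structure with molecular topology and an orthorhombic box.

    Attributes
    ----------
    species : (N,) array of str
        Element symbol per atom ("O" or "H" for water systems).
    positions : (N, 3) float array
        Cartesian coordinates in Å.
    molecule : (N,) int array
        Molecule index per atom.
    bonds : (Nb, 2) int array
        Covalent bond list as atom-index pairs (O-H for water).
    box : (3,) float array
        Orthorhombic box edge lengths in Å (α = β = γ = 90°).
    """

    species: np.ndarray
    positions: np.ndarray
    molecule: np.ndarray
    bonds: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype="U2")
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.molecule = np.asarray(self.molecule, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def n_molecules(self) -> int:
        return 0 if self.n_atoms == 0 else len(np.unique(self.molecule))

    def indices(self, element: str) -> np.ndarray:
        return np.flatnonzero(self.species == element)

    def wrapped(self) -> "Structure":
        """Copy with all positions wrapped into [0, box)."""
        s = self.copy()
        s.positions = np.mod(s.positions, s.box)
        return s

    def copy(self) -> "Structure":
        return Structure(
            self.species.copy(),
            self.positions.copy(),
            self.molecule.copy(),
            self.bonds.copy(),
            self.box.copy(),
        )


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return d - box * np.round(d / box)


def _oxygen_lattice(replications, lattice_constants):
    """Oxygen fractional sites of the orthorhombic ice-Ih cell, replicated.

    8 sites per cell: the wurtzite 4-site basis of the hexagonal cell plus
    its centred copy at (+1/2, +1/2, 0) of the orthorhombic cell.
    """
    a, c = lattice_constants
    cell = np.array([a, np.sqrt(3.0) * a, c])
    # fractional coordinates in the orthorhombic cell
    base = np.array(
        [
            [0.0, 1.0 / 3.0, 0.0],
            [0.5, 1.0 / 6.0, 0.5],
            [0.0, 1.0 / 3.0, 3.0 / 8.0],
            [0.5, 1.0 / 6.0, 7.0 / 8.0],
        ]
    )
    basis = np.vstack([base, base + np.array([0.5, 0.5, 0.0])])
    basis %= 1.0

    na, nb, nc = replications
    shifts = np.array(
        [[i, j, k] for i in range(na) for j in range(nb) for k in range(nc)],
        dtype=float,
    )
    frac = (shifts[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    frac /= np.array([na, nb, nc])
    box = cell * np.array([na, nb, nc])
    return frac * box, box


def _neighbour_graph(pos_o: np.ndarray, box: np.ndarray):
    """4-regular O-O hydrogen-bond adjacency.

    Returns an (Ne, 2) edge list together with the (Ne, 3) displacement
    vector from the first to the second endpoint.  All 27 periodic images
    are scanned so that small cells where one pair is bonded through two
    distinct images (a multigraph) are handled correctly.
    """
    n = len(pos_o)
    edge_list, vec_list = [], []
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                shift = np.array([sx, sy, sz], dtype=float) * box
                d = pos_o[None, :, :] + shift - pos_o[:, None, :]
                r = np.linalg.norm(d, axis=-1)
                ii, jj = np.nonzero((r < O_O_CUTOFF) & (r > 1e-6))
                # dedupe (i, j, shift) against (j, i, -shift)
                keep = (ii < jj) | ((ii == jj) & ((sx, sy, sz) > (0, 0, 0)))
                for i, j in zip(ii[keep], jj[keep]):
                    edge_list.append((int(i), int(j)))
                    vec_list.append(d[i, j])
    edges = np.array(edge_list, dtype=int).reshape(-1, 2)
    evecs = np.array(vec_list, dtype=float).reshape(-1, 3)
    deg = np.bincount(edges.ravel(), minlength=n)
    if not np.all(deg == 4):
        raise ValueError(
            f"oxygen sublattice is not 4-regular (degrees {np.unique(deg)}); "
            "check lattice constants / replications"
        )
    return edges, evecs


def _orient_edges(edges: np.ndarray, n: int, rng: np.random.Generator,
                  max_sweeps: int = 10000) -> np.ndarray:
    """Orient each H-bond edge donor→acceptor with out-degree 2 everywhere.

    Random initial orientation, then repeated path reversal from a
    surplus-donor oxygen to a deficit one.  Reversing a simple path
    decrements the start's out-degree and increments the end's, leaving
    interior vertices unchanged, so total imbalance strictly decreases.
    """
    ne = len(edges)
    # direction[e] = 0 means edges[e,0] donates to edges[e,1]; 1 the reverse
    direction = rng.integers(0, 2, size=ne)

    def out_degrees():
        donors = np.where(direction == 0, edges[:, 0], edges[:, 1])
        return np.bincount(donors, minlength=n)

    # incidence lists: for each vertex, (edge index, end index of vertex)
    inc = [[] for _ in range(n)]
    for e, (i, j) in enumerate(edges):
        inc[i].append((e, 0))
        inc[j].append((e, 1))

    outdeg = out_degrees()
    limit = 64 * ne
    for _ in range(max_sweeps):
        surplus = np.flatnonzero(outdeg > 2)
        if len(surplus) == 0:
            break
        cur = int(rng.choice(surplus))
        # Walk along outgoing edges, reversing each traversed edge, until the
        # head lands on a vertex that is not (or no longer) a surplus donor.
        steps = 0
        while outdeg[cur] > 2:
            steps += 1
            if steps > limit:
                raise RuntimeError("path-reversal walk exceeded step limit")
            out_edges = [(e, end) for (e, end) in inc[cur] if direction[e] == end]
            e, end = out_edges[rng.integers(0, len(out_edges))]
            nxt = int(edges[e, 1 - end])
            direction[e] = 1 - direction[e]
            outdeg[cur] -= 1
            outdeg[nxt] += 1
            cur = nxt
    if np.any(outdeg != 2):
        raise RuntimeError(
            "ice-rule proton assignment failed to converge; "
            f"{int(np.sum(outdeg != 2))} oxygens with wrong donor count"
        )
    return direction


def _place_hydrogens(pos_o, edges, evecs, direction, rng):
    """Rigid-geometry hydrogen placement from the donor orientation.

    Each oxygen donates along its two outgoing H-bond directions; the two
    hydrogens are set in the plane of those directions, symmetric about
    their bisector with the rigid H-O-H angle, at the rigid O-H length.
    """
    n = len(pos_o)
    donate_dirs = [[] for _ in range(n)]
    for e, (i, j) in enumerate(edges):
        if direction[e] == 0:
            donor, d = i, evecs[e]
        else:
            donor, d = j, -evecs[e]
        donate_dirs[donor].append(d / np.linalg.norm(d))

    half = np.deg2rad(H_O_H_ANGLE_DEG) / 2.0
    h_pos = np.empty((n, 2, 3))
    for i in range(n):
        u1, u2 = donate_dirs[i]
        bis = u1 + u2
        bis /= np.linalg.norm(bis)
        perp = u1 - np.dot(u1, bis) * bis
        perp /= np.linalg.norm(perp)
        h_pos[i, 0] = pos_o[i] + O_H_BOND_LENGTH * (np.cos(half) * bis + np.sin(half) * perp)
        h_pos[i, 1] = pos_o[i] + O_H_BOND_LENGTH * (np.cos(half) * bis - np.sin(half) * perp)
    return h_pos


def build_ice_ih(replications=(8, 3, 4),
                 lattice_constants=DEFAULT_LATTICE,
                 proton_seed: int = 0) -> Structure:
    """Build a proton-disordered ice-Ih supercell.

    Parameters
    ----------
    replications : (na, nb, nc)
        Repetitions of the 8-molecule orthorhombic cell along x, y, z.
        The default (8, 3, 4) yields 768 molecules in a box of
        36.146 × 23.478 × 29.414 Å.
    lattice_constants : (a, c)
        Hexagonal lattice constants in Å; the orthorhombic cell is
        (a, √3·a, c).
    proton_seed : int
        Seed for the proton-disorder realization.  Changes hydrogen
        positions only; oxygen sites and molecule count are fixed.

    Returns
    -------
    Structure
        Atoms ordered O, H, H per molecule; covalent bonds assigned.
    """
    replications = tuple(int(r) for r in replications)
    if any(r < 1 for r in replications):
        raise ValueError("replications must be >= 1")
    a, c = lattice_constants
    if a <= 0 or c <= 0:
        raise ValueError("lattice constants must be positive")

    pos_o, box = _oxygen_lattice(replications, lattice_constants)
    edges, evecs = _neighbour_graph(pos_o, box)
    rng = np.random.default_rng(proton_seed)
    last_err = None
    for _attempt in range(8):
        try:
            direction = _orient_edges(edges, len(pos_o), rng)
            break
        except RuntimeError as err:  # pragma: no cover - retry path
            last_err = err
    else:  # pragma: no cover
        raise RuntimeError(f"ice rules unsatisfiable after retries: {last_err}")

    h_pos = _place_hydrogens(pos_o, edges, evecs, direction, rng)

    n = len(pos_o)
    species = np.array(["O", "H", "H"] * n)
    positions = np.empty((3 * n, 3))
    positions[0::3] = pos_o
    positions[1::3] = h_pos[:, 0]
    positions[2::3] = h_pos[:, 1]
    molecule = np.repeat(np.arange(n), 3)
    bonds = np.stack(
        [np.repeat(np.arange(0, 3 * n, 3), 2),
         np.arange(3 * n).reshape(n, 3)[:, 1:].ravel()],
        axis=1,
    )
    s = Structure(species, positions, molecule, bonds, box)
    return s.wrapped()


def validate_ice_rules(structure: Structure,
                       h_accept_cutoff: float = 2.4) -> dict:
    """Check the Bernal-Fowler ice rules.

    Returns a report dict with keys ``bad_covalent`` (oxygen indices whose
    covalent hydrogen count differs from 2) and ``bad_bonds`` (O-O edges
    hosting a hydrogen count different from 1).  Both empty iff the rules
    hold.  An empty structure vacuously passes.
    """
    report = {"bad_covalent": [], "bad_bonds": []}
    if structure.n_atoms == 0:
        return report
    o_idx = structure.indices("O")
    h_idx = structure.indices("H")
    box = structure.box

    # covalent rule from the bond list
    n_cov = {int(i): 0 for i in o_idx}
    for i, j in structure.bonds:
        o = int(i) if structure.species[i] == "O" else int(j)
        n_cov[o] = n_cov.get(o, 0) + 1
    report["bad_covalent"] = [
        {"oxygen": o, "n_hydrogens": c} for o, c in sorted(n_cov.items()) if c != 2
    ]

    if len(o_idx) < 2:
        return report

    pos_o = structure.positions[o_idx]
    try:
        edges, evecs = _neighbour_graph(pos_o, box)
    except ValueError:
        # irregular network: report every O-O contact unconstrained below
        edges = np.empty((0, 2), dtype=int)
        evecs = np.empty((0, 3))

    # parent oxygen of each hydrogen (from bonds)
    parent = {}
    for i, j in structure.bonds:
        if structure.species[i] == "O":
            parent[int(j)] = int(i)
        else:
            parent[int(i)] = int(j)

    # unit vector from parent oxygen to each hydrogen
    h_vec = {}
    for h in h_idx:
        p = parent.get(int(h))
        if p is None:
            continue
        v = minimum_image(structure.positions[h] - structure.positions[p], box)
        h_vec[int(h)] = v / np.linalg.norm(v)

    max_dev = np.cos(np.deg2rad(30.0))  # H counts as on-bond within 30° of the axis
    for e, (a_loc, b_loc) in enumerate(edges):
        oa, ob = int(o_idx[a_loc]), int(o_idx[b_loc])
        u = evecs[e] / np.linalg.norm(evecs[e])
        count = 0
        for h, v in h_vec.items():
            p = parent[h]
            if p == oa and np.dot(v, u) > max_dev:
                count += 1
            elif p == ob and np.dot(v, -u) > max_dev:
                count += 1
        if count != 1:
            report["bad_bonds"].append({"edge": (oa, ob), "n_hydrogens": count})
    return report


# ---------------------------------------------------------------------------
# structure I/O: PDB via gemmi, extended XYZ natively


def _to_gemmi(structure: Structure):
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*structure.box, 90.0, 90.0, 90.0)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for mol in np.unique(structure.molecule):
        res = gemmi.Residue()
        res.name = "HOH"
        res.seqid = gemmi.SeqId(int(mol) + 1, " ")
        n_h = 0
        for idx in np.flatnonzero(structure.molecule == mol):
            atom = gemmi.Atom()
            el = str(structure.species[idx])
            n_h += el == "H"
            atom.name = el if el == "O" else f"H{n_h}"
            atom.element = gemmi.Element(el)
            atom.pos = gemmi.Position(*structure.positions[idx])
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    return st


def _from_gemmi(st) -> Structure:
    species, positions, molecule = [], [], []
    model = st[0]
    mol = 0
    for chain in model:
        for res in chain:
            for atom in res:
                species.append(atom.element.name)
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                molecule.append(mol)
            mol += 1
    cell = st.cell
    box = np.array([cell.a, cell.b, cell.c])
    species = np.array(species)
    positions = np.array(positions)
    molecule = np.array(molecule)
    bonds = _infer_oh_bonds(species, positions, molecule)
    return Structure(species, positions, molecule, bonds, box)


def _infer_oh_bonds(species, positions, molecule):
    bonds = []
    for mol in np.unique(molecule):
        idx = np.flatnonzero(molecule == mol)
        o = [int(i) for i in idx if species[i] == "O"]
        h = [int(i) for i in idx if species[i] == "H"]
        if len(o) == 1:
            bonds.extend([[o[0], hi] for hi in h])
    return np.array(bonds, dtype=int).reshape(-1, 2)


_KNOWN_ELEMENTS = {"H", "C", "N", "O", "S", "P", "F", "Cl", "Na", "K", "Mg", "Ca", "Fe"}


def write_structure(structure: Structure, path, fmt: str | None = None) -> None:
    """Write a structure as PDB (with CRYST1) or extended XYZ.

    The format is inferred from the file suffix unless ``fmt`` is given.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        _to_gemmi(structure).write_pdb(str(path))
    elif fmt == "xyz":
        box = structure.box
        lattice = f"{box[0]:.6f} 0.0 0.0 0.0 {box[1]:.6f} 0.0 0.0 0.0 {box[2]:.6f}"
        with open(path, "w") as fh:
            fh.write(f"{structure.n_atoms}\n")
            fh.write(
                f'Lattice="{lattice}" Properties=species:S:1:pos:R:3:molecule:I:1\n'
            )
            for sp, pos, mol in zip(
                structure.species, structure.positions, structure.molecule
            ):
                fh.write(
                    f"{sp} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f} {mol}\n"
                )
    else:
        raise ValueError(f"unsupported structure format: {fmt!r}")


def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or extended-XYZ structure written by :func:`write_structure`."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        import gemmi

        return _from_gemmi(gemmi.read_pdb(str(path)))
    if fmt != "xyz":
        raise ValueError(f"unsupported structure format: {fmt!r}")

    with open(path) as fh:
        lines = fh.readlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ValueError(f"{path}:1: expected atom count")
    comment = lines[1] if len(lines) > 1 else ""
    box = np.ones(3)
    if 'Lattice="' in comment:
        lat = comment.split('Lattice="')[1].split('"')[0].split()
        m = np.array([float(x) for x in lat]).reshape(3, 3)
        box = np.diag(m)
    species, positions, molecule = [], [], []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected 'element x y z [molecule]'")
        el = parts[0]
        if el not in _KNOWN_ELEMENTS:
            raise ValueError(f"{path}:{ln}: unknown element symbol {el!r}")
        species.append(el)
        try:
            positions.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise ValueError(f"{path}:{ln}: malformed coordinates")
        molecule.append(int(parts[4]) if len(parts) > 4 else len(molecule))
    if len(species) != n:
        raise ValueError(f"{path}: header promised {n} atoms, found {len(species)}")
    species = np.array(species)
    positions = np.array(positions)
    molecule = np.array(molecule)
    bonds = _infer_oh_bonds(species, positions, molecule)
    return Structure(species, positions, molecule, bonds, box)
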