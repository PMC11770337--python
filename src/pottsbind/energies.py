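"""One- and two-body energy tables from a fixed adsorbed conformation.

The score decomposition needs per-residue ("one-body") and per-residue-pair
("two-body") energies that are independent of the rest of the sequence.
Two approximations make this possible for an implicit-solvent energy:

* **Side-chain coarse-graining for Born radii.**  The generalized-Born
  solvation energy is a many-body quantity because every atom descreens
  every other.  When residue *i* (or the pair *i*, *j*) is evaluated, every
  other residue's side chain is replaced by a single neutral sphere of
  radius 3 Angstrom centred at its beta carbon, so Born radii depend only
  on the fixed backbone, the slab, and the side chain(s) being scored.

* **Rotamer reduction.**  For each (residue, amino-acid) pair, candidate
  side-chain conformations from a small chi-angle library are scored and
  only the lowest one-body-energy rotamer is retained, after a discrete
  +-10 degree coordinate refinement of each chi angle (two sweeps).  The
  retained rotamer is reused for the two-body energies.

The energy itself is Coulomb + Lennard-Jones + a Still-style generalized
Born term, with a deliberately small packaged parameter set: side chains
are short pseudo-atom chains (Cbeta plus up to two beads placed by chi
dihedrals).  The pipeline is parameter-file driven, so richer parameter
sets can be dropped in without code changes.

Units: kcal/mol, Angstrom, elementary charges.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .potts import Alphabet, EnergyTables, DEFAULT_LETTERS
from .structure import SystemConformation, virtual_cbeta

__all__ = [
    "COULOMB_K",
    "ParamAtoms",
    "EnergyBreakdown",
    "ForceField",
    "RotamerLibrary",
    "EnergyModel",
    "coulomb_energy",
    "lj_energy",
    "born_radii",
    "gb_pair_energy",
    "gb_self_energy",
    "build_tables",
    "place_atom",
]

#: Coulomb constant in kcal*Angstrom/(mol*e^2)
COULOMB_K = 332.0636

CG_RADIUS = 3.0  # coarse-grained side-chain sphere radius, Angstrom


@dataclass
class ParamAtoms:
    """A set of atoms with force-field parameters as parallel arrays."""

    coords: np.ndarray       # (m, 3)
    charge: np.ndarray       # (m,) e
    eps: np.ndarray          # (m,) kcal/mol
    rmin_half: np.ndarray    # (m,) Angstrom
    gb_radius: np.ndarray    # (m,) Angstrom

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        for name in ("charge", "eps", "rmin_half", "gb_radius"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def empty(cls) -> "ParamAtoms":
        z = np.zeros((0,))
        return cls(np.zeros((0, 3)), z, z, z, z)

    @classmethod
    def concat(cls, sets: list["ParamAtoms"]) -> "ParamAtoms":
        sets = [s for s in sets if len(s)]
        if not sets:
            return cls.empty()
        return cls(
            np.vstack([s.coords for s in sets]),
            np.concatenate([s.charge for s in sets]),
            np.concatenate([s.eps for s in sets]),
            np.concatenate([s.rmin_half for s in sets]),
            np.concatenate([s.gb_radius for s in sets]),
        )


@dataclass
class EnergyBreakdown:
    elec: float
    lj: float
    gb: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.elec + self.lj + self.gb


def _cross_distances(a: ParamAtoms, b: ParamAtoms) -> np.ndarray:
    d = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=-1)
    if (d < 1e-9).any():
        raise ValueError("zero interatomic distance in energy evaluation")
    return d


def coulomb_energy(a: ParamAtoms, b: ParamAtoms, eps_in: float = 1.0,
                   scale: np.ndarray | None = None) -> float:
    """Pairwise Coulomb energy between two disjoint atom sets (no cutoff).

    ``scale`` is an optional (len(a), len(b)) per-pair factor implementing
    bonded exclusions (0 for 1-2/1-3 pairs, 0.5 for 1-4).
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0
    d = _cross_distances(a, b)
    e = COULOMB_K * np.outer(a.charge, b.charge) / (eps_in * d)
    if scale is not None:
        e = e * scale
    return float(e.sum())


def lj_energy(a: ParamAtoms, b: ParamAtoms, scale: np.ndarray | None = None) -> float:
    """12-6 Lennard-Jones with Lorentz-Berthelot combination:
    rmin_ij = rmin_half_i + rmin_half_j, eps_ij = sqrt(eps_i * eps_j)."""
    if len(a) == 0 or len(b) == 0:
        return 0.0
    d = _cross_distances(a, b)
    eps = np.sqrt(np.outer(a.eps, b.eps))
    rmin = a.rmin_half[:, None] + b.rmin_half[None, :]
    x6 = (rmin / d) ** 6
    e = eps * (x6 * x6 - 2.0 * x6)
    if scale is not None:
        e = e * scale
    return float(e.sum())


def born_radii(atoms: ParamAtoms) -> np.ndarray:
    """Effective Born radii by pairwise descreening (HCT-style integral).

    Each neighbour sphere *j* reduces the solvation of atom *i* by the
    Coulomb-field integral of 1/(4 pi r^4) over its volume outside the
    intrinsic radius of *i*.  An isolated atom keeps its intrinsic radius;
    burial strictly increases the effective radius.
    """
    m = len(atoms)
    rho = atoms.gb_radius.copy()
    if (rho <= 0).any():
        raise ValueError("non-positive intrinsic GB radius")
    inv_r = 1.0 / rho
    if m > 1:
        d = np.linalg.norm(atoms.coords[:, None, :] - atoms.coords[None, :, :], axis=-1)
        off = ~np.eye(m, dtype=bool)
        if (d[off] < 1e-9).any():
            raise ValueError("overlapping identical centers in Born radius calculation")
        rho_i = rho[:, None]
        rho_j = rho[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            U = d + rho_j
            L = np.maximum(rho_i, np.abs(d - rho_j))
            integral = 0.5 * (
                (1.0 / L - 1.0 / U)
                + (d - rho_j ** 2 / d) / 4.0 * (1.0 / U ** 2 - 1.0 / L ** 2)
                + (0.5 / d) * np.log(L / U)
            )
        active = off & (rho_i < U)   # neighbours engulfed by i's sphere contribute 0
        inv_r -= np.where(active, integral, 0.0).sum(axis=1)
    inv_r = np.maximum(inv_r, 1e-3)   # guard against extreme burial
    return 1.0 / inv_r


def _f_gb(d: np.ndarray, ra: np.ndarray, rb: np.ndarray) -> np.ndarray:
    rr = np.outer(ra, rb)
    return np.sqrt(d * d + rr * np.exp(-(d * d) / (4.0 * rr)))


def gb_pair_energy(a: ParamAtoms, b: ParamAtoms, radii_a: np.ndarray,
                   radii_b: np.ndarray, eps_in: float = 1.0,
                   eps_out: float = 78.5) -> float:
    """Still cross-term GB polarization energy between two atom sets."""
    if len(a) == 0 or len(b) == 0:
        return 0.0
    if (np.asarray(radii_a) <= 0).any() or (np.asarray(radii_b) <= 0).any():
        raise ValueError("non-positive Born radius")
    d = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=-1)
    f = _f_gb(d, np.asarray(radii_a), np.asarray(radii_b))
    e = -COULOMB_K * (1.0 / eps_in - 1.0 / eps_out) * np.outer(a.charge, b.charge) / f
    return float(e.sum())


def gb_self_energy(a: ParamAtoms, radii: np.ndarray, eps_in: float = 1.0,
                   eps_out: float = 78.5) -> float:
    """GB self (i == j) polarization energy of one atom set."""
    if len(a) == 0:
        return 0.0
    radii = np.asarray(radii)
    if (radii <= 0).any():
        raise ValueError("non-positive Born radius")
    return float(-COULOMB_K / 2.0 * (1.0 / eps_in - 1.0 / eps_out)
                 * np.sum(a.charge ** 2 / radii))


# ---------------------------------------------------------------------------
# parameter files


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("pottsbind.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


@dataclass
class ForceField:
    """Atom-type parameters plus per-amino-acid side-chain bead topology."""

    atom_types: dict            # type -> dict(charge, eps, rmin_half, gb_radius, element)
    sidechains: dict            # aa -> list of dict(bead, atom_type, charge, bond_length)
    eps_in: float = 1.0
    eps_out: float = 78.5
    one_four_scale: float = 0.5

    @classmethod
    def default(cls) -> "ForceField":
        ff = _read_packaged("forcefield.csv")
        sc = _read_packaged("sidechains.csv")
        atom_types = {
            r.atom_type: {"charge": float(r.charge), "eps": float(r.eps),
                          "rmin_half": float(r.rmin_half),
                          "gb_radius": float(r.gb_radius), "element": r.element}
            for r in ff.itertuples(index=False)
        }
        sidechains: dict[str, list] = {aa: [] for aa in DEFAULT_LETTERS}
        for r in sc.itertuples(index=False):
            sidechains[r.aa].append({"bead": r.bead, "atom_type": r.atom_type,
                                     "charge": float(r.charge),
                                     "bond_length": float(r.bond_length)})
        return cls(atom_types=atom_types, sidechains=sidechains)

    @classmethod
    def from_files(cls, forcefield_csv, sidechains_csv, **kwargs) -> "ForceField":
        ff = pd.read_csv(forcefield_csv, keep_default_na=False)
        sc = pd.read_csv(sidechains_csv, keep_default_na=False)
        atom_types = {
            r.atom_type: {"charge": float(r.charge), "eps": float(r.eps),
                          "rmin_half": float(r.rmin_half),
                          "gb_radius": float(r.gb_radius), "element": r.element}
            for r in ff.itertuples(index=False)
        }
        sidechains: dict[str, list] = {}
        for r in sc.itertuples(index=False):
            sidechains.setdefault(r.aa, []).append(
                {"bead": r.bead, "atom_type": r.atom_type,
                 "charge": float(r.charge), "bond_length": float(r.bond_length)})
        return cls(atom_types=atom_types, sidechains=sidechains, **kwargs)

    def type_params(self, atom_type: str) -> dict:
        return self.atom_types[atom_type]


@dataclass
class RotamerLibrary:
    """Chi-angle tuples per amino acid (degrees, in [-180, 180))."""

    rotamers: dict              # aa -> list of tuple of floats (possibly empty tuple)

    @classmethod
    def default(cls) -> "RotamerLibrary":
        df = _read_packaged("rotamers.csv")
        rot: dict[str, list] = {}
        for r in df.itertuples(index=False):
            chis = []
            for v in (r.chi1, r.chi2):
                if v != "" and not (isinstance(v, float) and np.isnan(v)):
                    chis.append(float(v))
            rot.setdefault(r.aa, []).append(tuple(chis))
        return cls(rotamers=rot)

    @classmethod
    def from_file(cls, path) -> "RotamerLibrary":
        df = pd.read_csv(path, keep_default_na=False)
        rot: dict[str, list] = {}
        for r in df.itertuples(index=False):
            chis = [float(v) for v in (r.chi1, r.chi2) if v != ""]
            rot.setdefault(r.aa, []).append(tuple(chis))
        return cls(rotamers=rot)

    def for_aa(self, aa: str) -> list:
        if aa not in self.rotamers:
            raise KeyError(f"amino acid {aa!r} absent from rotamer library")
        return self.rotamers[aa]


# ---------------------------------------------------------------------------
# geometry


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Internal-to-Cartesian (NeRF) placement: position *d* with given
    bond c-d, angle b-c-d, and dihedral a-b-c-d."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        # colinear reference frame: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


BACKBONE_NAMES = ("N", "CA", "C", "O")

# bond-separation counts within one residue for the chain
# N-CA, CA-C, C-O, CA-CB, CB-G1, G1-G2 (side-chain beads in file order)
_SC_BACKBONE_SEPARATION = {
    # (sidechain bead position index 0=CB,1,2) -> separation to backbone atom
    (0, "N"): 3, (0, "CA"): 2, (0, "C"): 3, (0, "O"): 4,
    (1, "N"): 4, (1, "CA"): 3, (1, "C"): 4, (1, "O"): 5,
    (2, "N"): 5, (2, "CA"): 4, (2, "C"): 5, (2, "O"): 6,
}


class EnergyModel:
    """Builds one-/two-body energies for one aligned conformation.

    The conformation provides the fixed peptide backbone (atoms N, CA, C, O
    per residue) and the plastic slab; candidate side chains are constructed
    on the backbone from the rotamer library.
    """

    def __init__(self, conf: SystemConformation, ff: ForceField | None = None,
                 library: RotamerLibrary | None = None,
                 alphabet: Alphabet | None = None,
                 chi_refine_step: float = 10.0, chi_refine_sweeps: int = 2):
        self.conf = conf
        self.ff = ff or ForceField.default()
        self.library = library or RotamerLibrary.default()
        self.alphabet = alphabet or Alphabet()
        self.chi_refine_step = chi_refine_step
        self.chi_refine_sweeps = chi_refine_sweeps
        self.n = conf.n_residues

        self._backbone_xyz: list[dict] = []
        for i in range(self.n):
            atoms = {}
            for name in BACKBONE_NAMES:
                atoms[name] = conf.atom(i, name).xyz
            self._backbone_xyz.append(atoms)

        self._plastic = self._build_plastic()
        self._backbone = self._build_backbone()
        self._cb_positions = [self._cbeta(i) for i in range(self.n)]
        # cache: (i, aa) -> dict(chis, energy, atoms, radii)
        self._selected: dict = {}

    # -- atom-set builders -------------------------------------------------

    def _params_for(self, atom_type: str, charge: float | None = None):
        p = self.ff.type_params(atom_type)
        return (p["charge"] if charge is None else charge,
                p["eps"], p["rmin_half"], p["gb_radius"])

    def _build_plastic(self) -> ParamAtoms:
        coords, q, eps, rmin, gb = [], [], [], [], []
        for a in self.conf.plastic_atoms():
            if a.element == "H":
                continue
            c0, e0, r0, g0 = self._params_for("CPE")
            coords.append(a.xyz)
            q.append(c0)
            eps.append(e0)
            rmin.append(r0)
            gb.append(g0)
        return ParamAtoms(np.array(coords), np.array(q), np.array(eps),
                          np.array(rmin), np.array(gb))

    def _build_backbone(self) -> ParamAtoms:
        type_of = {"N": "NBB", "CA": "CAB", "C": "CBB", "O": "OBB"}
        coords, q, eps, rmin, gb = [], [], [], [], []
        self._backbone_owner: list[tuple[int, str]] = []
        for i in range(self.n):
            for name in BACKBONE_NAMES:
                c0, e0, r0, g0 = self._params_for(type_of[name])
                coords.append(self._backbone_xyz[i][name])
                q.append(c0)
                eps.append(e0)
                rmin.append(r0)
                gb.append(g0)
                self._backbone_owner.append((i, name))
        return ParamAtoms(np.array(coords), np.array(q), np.array(eps),
                          np.array(rmin), np.array(gb))

    def _cbeta(self, i: int) -> np.ndarray:
        if self.conf.has_atom(i, "CB"):
            return self.conf.atom(i, "CB").xyz
        return virtual_cbeta(self.conf, i)

    def build_sidechain(self, i: int, aa: str, chis: tuple) -> ParamAtoms:
        """Construct the pseudo-atom side chain of amino acid ``aa`` at
        residue ``i`` for the given chi angles."""
        beads = self.ff.sidechains.get(aa, [])
        if not beads:
            return ParamAtoms.empty()
        bb = self._backbone_xyz[i]
        coords = [self._cb_for_build(i)]
        # bead 1 dihedral reference: N-CA-CB, bead 2: CA-CB-G1
        prev3 = (bb["N"], bb["CA"], coords[0])
        for k, bead in enumerate(beads[1:]):
            chi = chis[k] if k < len(chis) else 180.0
            pos = place_atom(prev3[0], prev3[1], prev3[2],
                             bead["bond_length"], 114.0, chi)
            coords.append(pos)
            prev3 = (prev3[1], prev3[2], pos)
        q, eps, rmin, gb = [], [], [], []
        for bead in beads:
            _, e0, r0, g0 = self._params_for(bead["atom_type"])
            q.append(bead["charge"])
            eps.append(e0)
            rmin.append(r0)
            gb.append(g0)
        return ParamAtoms(np.array(coords), np.array(q), np.array(eps),
                          np.array(rmin), np.array(gb))

    def _cb_for_build(self, i: int) -> np.ndarray:
        # side chains are always built on an ideal Cbeta so that energies
        # depend only on the backbone (the conformation may lack CB atoms)
        return virtual_cbeta(self.conf, i)

    def cg_spheres(self, exclude: tuple[int, ...]) -> ParamAtoms:
        """Neutral 3 Angstrom descreening spheres at the Cbeta of every
        residue not in ``exclude`` (LJ-inert, zero charge)."""
        coords = [self._cb_positions[i] for i in range(self.n) if i not in exclude]
        if not coords:
            return ParamAtoms.empty()
        m = len(coords)
        return ParamAtoms(np.array(coords), np.zeros(m), np.zeros(m),
                          np.full(m, CG_RADIUS), np.full(m, CG_RADIUS))

    # -- energy evaluation -------------------------------------------------

    def _context_radii(self, sc_sets: list[ParamAtoms], exclude: tuple[int, ...]):
        """Born radii for [sc..., backbone, plastic] in the coarse-grained
        context where all residues outside ``exclude`` are CG spheres."""
        cg = self.cg_spheres(exclude)
        stack = ParamAtoms.concat(sc_sets + [self._backbone, self._plastic, cg])
        radii = born_radii(stack)
        out = []
        k = 0
        for s in sc_sets:
            out.append(radii[k:k + len(s)])
            k += len(s)
        bb_radii = radii[k:k + len(self._backbone)]
        pl_radii = radii[k + len(self._backbone):k + len(self._backbone) + len(self._plastic)]
        return out, bb_radii, pl_radii

    def _bonded_scale(self, i: int, n_sc: int) -> np.ndarray:
        """Per-pair scale factors between residue i's side-chain beads and
        every backbone atom: 0 for 1-2/1-3, one_four_scale for 1-4, else 1."""
        scale = np.ones((n_sc, len(self._backbone)))
        for col, (owner, name) in enumerate(self._backbone_owner):
            if owner != i:
                continue
            for row in range(n_sc):
                sep = _SC_BACKBONE_SEPARATION[(row, name)]
                if sep <= 3:
                    scale[row, col] = 0.0
                elif sep == 4:
                    scale[row, col] = self.ff.one_four_scale
        return scale

    def one_body_breakdown(self, i: int, aa: str, chis: tuple) -> EnergyBreakdown:
        """Energy of amino acid ``aa`` at residue ``i``: interactions of its
        side chain with the plastic, the full peptide backbone (bonded
        exclusions applied for its own backbone) and itself, plus the GB
        polarization of the side chain in the coarse-grained context."""
        sc = self.build_sidechain(i, aa, chis)
        if len(sc) == 0:
            return EnergyBreakdown(0.0, 0.0, 0.0)
        (sc_radii,), bb_radii, pl_radii = self._context_radii([sc], (i,))
        scale = self._bonded_scale(i, len(sc))
        elec = (coulomb_energy(sc, self._plastic, self.ff.eps_in)
                + coulomb_energy(sc, self._backbone, self.ff.eps_in, scale))
        lj = (lj_energy(sc, self._plastic)
              + lj_energy(sc, self._backbone, scale))
        gb = (gb_pair_energy(sc, self._plastic, sc_radii, pl_radii,
                             self.ff.eps_in, self.ff.eps_out)
              + gb_pair_energy(sc, self._backbone, sc_radii, bb_radii,
                               self.ff.eps_in, self.ff.eps_out)
              + gb_self_energy(sc, sc_radii, self.ff.eps_in, self.ff.eps_out))
        # intra-side-chain pairs are all separated by <= 2 bonds -> excluded
        # from elec/LJ; their GB cross terms are included
        if len(sc) > 1:
            for p in range(len(sc)):
                for r in range(p + 1, len(sc)):
                    a = ParamAtoms(sc.coords[p], sc.charge[p], sc.eps[p],
                                   sc.rmin_half[p], sc.gb_radius[p])
                    b = ParamAtoms(sc.coords[r], sc.charge[r], sc.eps[r],
                                   sc.rmin_half[r], sc.gb_radius[r])
                    gb += gb_pair_energy(a, b, sc_radii[p:p + 1], sc_radii[r:r + 1],
                                         self.ff.eps_in, self.ff.eps_out)
        return EnergyBreakdown(elec, lj, gb)

    def select_rotamer(self, i: int, aa: str) -> tuple[tuple, float]:
        """Lowest-one-body-energy rotamer for (i, aa) with discrete chi
        refinement; deterministic tie-break by library order."""
        key = (i, aa)
        if key in self._selected:
            sel = self._selected[key]
            return sel["chis"], sel["energy"]
        best_chis, best_e = None, np.inf
        for chis in self.library.for_aa(aa):
            chis = tuple(chis)
            e = self.one_body_breakdown(i, aa, chis).total
            # coordinate-wise +-step scan, fixed number of sweeps
            cur_chis, cur_e = list(chis), e
            for _ in range(self.chi_refine_sweeps):
                for k in range(len(cur_chis)):
                    for delta in (-self.chi_refine_step, self.chi_refine_step):
                        trial = list(cur_chis)
                        trial[k] = ((trial[k] + delta + 180.0) % 360.0) - 180.0
                        te = self.one_body_breakdown(i, aa, tuple(trial)).total
                        if te < cur_e - 1e-12:
                            cur_chis, cur_e = trial, te
            if cur_e < best_e - 1e-12:
                best_chis, best_e = tuple(cur_chis), cur_e
        sc = self.build_sidechain(i, aa, best_chis)
        if len(sc):
            (sc_radii,), _, _ = self._context_radii([sc], (i,))
        else:
            sc_radii = np.zeros(0)
        self._selected[key] = {"chis": best_chis, "energy": best_e,
                               "atoms": sc, "radii": sc_radii}
        return best_chis, best_e

    def one_body_energy(self, i: int, aa: str) -> float:
        _, e = self.select_rotamer(i, aa)
        return e

    def two_body_energy(self, i: int, aa_i: str, j: int, aa_j: str) -> float:
        """Side-chain/side-chain interaction between the retained rotamers
        of (i, aa_i) and (j, aa_j); symmetric under argument swap."""
        if i == j:
            raise ValueError("two-body energy requires distinct residues")
        if i > j:
            return self.two_body_energy(j, aa_j, i, aa_i)
        self.select_rotamer(i, aa_i)
        self.select_rotamer(j, aa_j)
        si = self._selected[(i, aa_i)]
        sj = self._selected[(j, aa_j)]
        if len(si["atoms"]) == 0 or len(sj["atoms"]) == 0:
            return 0.0
        e = (coulomb_energy(si["atoms"], sj["atoms"], self.ff.eps_in)
             + lj_energy(si["atoms"], sj["atoms"])
             + gb_pair_energy(si["atoms"], sj["atoms"], si["radii"], sj["radii"],
                              self.ff.eps_in, self.ff.eps_out))
        return float(e)

    def build_tables(self, conformation_id: str | None = None) -> EnergyTables:
        """Complete one-body (n x |alphabet|) and two-body (all i<j pairs)
        tables; deterministic given the conformation and parameters."""
        A = len(self.alphabet)
        one = np.zeros((self.n, A))
        for i in range(self.n):
            for a, aa in enumerate(self.alphabet):
                one[i, a] = self.one_body_energy(i, aa)
        two = np.zeros((self.n, self.n, A, A))
        for i in range(self.n):
            for j in range(i + 1, self.n):
                for a, aa in enumerate(self.alphabet):
                    for b, ab in enumerate(self.alphabet):
                        two[i, j, a, b] = self.two_body_energy(i, aa, j, ab)
        if conformation_id is None:
            h = hashlib.sha256(np.ascontiguousarray(self.conf.coords).tobytes())
            conformation_id = h.hexdigest()[:12]
        return EnergyTables(n=self.n, alphabet=self.alphabet, one_body=one,
                            two_body=two, conformation_id=conformation_id)


def build_tables(conf: SystemConformation, ff: ForceField | None = None,
                 library: RotamerLibrary | None = None,
                 alphabet: Alphabet | None = None) -> EnergyTables:
    """Convenience wrapper: build full energy tables for a conformation."""
    return EnergyModel(conf, ff, library, alphabet).build_tables()
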