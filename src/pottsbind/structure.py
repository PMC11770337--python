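"""Peptide + plastic-slab structures and side-chain environment descriptors.

A :class:`SystemConformation` holds the atoms of one adsorbed-peptide
snapshot: a peptide (contiguous residues 0..n-1) above a plastic slab.
After :func:`align_slab_to_z` the slab's best-fit plane is normal to +z and
the surface frame is simply ``z0`` (top of the slab, the maximum z over
plastic heavy atoms) with normal (0, 0, 1).

Three per-residue descriptors characterize a side chain's geometric
environment relative to the surface:

1. the signed distance from the beta carbon to the slab top,
2. the angle between the Calpha->Cbeta vector and the surface normal,
3. the solvent-accessible surface area of the bare beta carbon (all other
   atoms of that side chain removed; probe 1.4 Angstrom).

PDB I/O goes through biotite; atoms are classified into peptide / plastic /
solvent segments from residue names.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "AtomRecord",
    "SystemConformation",
    "SurfaceFrame",
    "SideChainEnvironment",
    "BinningConfig",
    "read_structure",
    "write_structure",
    "align_slab_to_z",
    "surface_frame",
    "cbeta_distance",
    "ca_cb_angle",
    "cbeta_bare_sasa",
    "environment_descriptor",
    "shrake_rupley_sasa",
    "VDW_RADII",
    "PLASTIC_RESNAMES",
    "SOLVENT_RESNAMES",
]

PLASTIC_RESNAMES = {"PE", "PP", "PS", "PET", "SLB", "PLA"}
SOLVENT_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}

#: element -> van der Waals radius (Angstrom); "Q" is the coarse-grained
#: side-chain pseudo-sphere.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "Q": 3.00}


class StructureError(ValueError):
    """Malformed or incomplete structure content."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    residue_index: int
    residue_name: str
    segment: str               # peptide | plastic | solvent
    xyz: np.ndarray            # (3,) Angstrom
    element: str


@dataclass
class SurfaceFrame:
    z0: float                  # height of slab top, Angstrom
    normal: np.ndarray         # unit vector

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("surface normal must be a unit vector")


class SystemConformation:
    """Atoms of one peptide + slab snapshot with cached coordinate arrays."""

    def __init__(self, atoms: list[AtomRecord]):
        if not atoms:
            raise StructureError("empty structure")
        self.atoms = atoms
        segs = {a.segment for a in atoms}
        if "plastic" not in segs:
            raise StructureError("structure contains no plastic atoms")
        pep = [a for a in atoms if a.segment == "peptide"]
        if not pep:
            raise StructureError("structure contains no peptide atoms")
        res_ids = sorted({a.residue_index for a in pep})
        if res_ids != list(range(len(res_ids))):
            # renumber contiguously, preserving order
            remap = {r: k for k, r in enumerate(res_ids)}
            for a in pep:
                a.residue_index = remap[a.residue_index]
        self.n_residues = len({a.residue_index for a in pep})

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def peptide_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.segment == "peptide"]

    def plastic_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.segment == "plastic"]

    def residue_atoms(self, residue_index: int) -> list[AtomRecord]:
        return [a for a in self.atoms
                if a.segment == "peptide" and a.residue_index == residue_index]

    def atom(self, residue_index: int, name: str) -> AtomRecord:
        for a in self.residue_atoms(residue_index):
            if a.name == name:
                return a
        raise StructureError(f"residue {residue_index} has no atom {name!r}")

    def has_atom(self, residue_index: int, name: str) -> bool:
        return any(a.name == name for a in self.residue_atoms(residue_index))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SystemConformation":
        new = []
        for a in self.atoms:
            new.append(AtomRecord(a.serial, a.name, a.residue_index, a.residue_name,
                                  a.segment, rotation @ a.xyz + translation, a.element))
        return SystemConformation(new)


def _classify(res_name: str) -> str:
    rn = res_name.strip().upper()
    if rn in PLASTIC_RESNAMES:
        return "plastic"
    if rn in SOLVENT_RESNAMES:
        return "solvent"
    return "peptide"


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name[1:]
    return name[:1].upper()


def read_structure(pdb_text: str) -> SystemConformation:
    """Parse PDB text into a classified :class:`SystemConformation`."""
    try:
        f = pdb.PDBFile.read(io.StringIO(pdb_text))
        arr = f.get_structure(model=1)
    except Exception as exc:
        raise StructureError(f"PDB parse error: {exc}") from exc
    atoms: list[AtomRecord] = []
    for k in range(arr.array_length()):
        name = str(arr.atom_name[k])
        element = str(arr.element[k]).strip() or _guess_element(name)
        atoms.append(AtomRecord(
            serial=k + 1,
            name=name,
            residue_index=int(arr.res_id[k]) - 1,
            residue_name=str(arr.res_name[k]),
            segment=_classify(str(arr.res_name[k])),
            xyz=np.array(arr.coord[k], dtype=float),
            element=element.upper(),
        ))
    return SystemConformation(atoms)


def write_structure(conf: SystemConformation) -> str:
    """Serialize to PDB text (ATOM for peptide, HETATM otherwise)."""
    n = len(conf.atoms)
    arr = struc.AtomArray(n)
    # residue ids: peptide residues keep 0..n-1 (+1); others numbered after
    next_het = conf.n_residues
    het_map: dict[tuple[str, int], int] = {}
    for k, a in enumerate(conf.atoms):
        if a.segment == "peptide":
            res_id = a.residue_index + 1
        else:
            key = (a.segment, a.residue_index)
            if key not in het_map:
                het_map[key] = next_het + 1
                next_het += 1
            res_id = het_map[key]
        arr.coord[k] = a.xyz
        arr.atom_name[k] = a.name
        arr.res_id[k] = res_id
        arr.res_name[k] = a.residue_name
        arr.element[k] = a.element
        arr.chain_id[k] = "A" if a.segment == "peptide" else "B"
        arr.hetero[k] = a.segment != "peptide"
    f = pdb.PDBFile()
    f.set_structure(arr)
    out = io.StringIO()
    f.write(out)
    return out.getvalue()


def _heavy_plastic_coords(conf: SystemConformation) -> np.ndarray:
    pts = np.array([a.xyz for a in conf.plastic_atoms() if a.element != "H"])
    if pts.size == 0:
        raise StructureError("no plastic heavy atoms")
    return pts


def align_slab_to_z(conf: SystemConformation, planarity_ratio: float = 0.5) -> SystemConformation:
    """Rigidly rotate the system so the slab's best-fit plane is normal to +z
    with the peptide on the +z side.

    The slab must be approximately planar: its spread normal to the best-fit
    plane may not exceed ``planarity_ratio`` times its largest lateral spread.
    """
    pts = _heavy_plastic_coords(conf)
    center = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - center, full_matrices=False)
    normal = vt[2]  # direction of least variance
    if len(pts) >= 4 and s[0] > 1e-9 and s[2] / s[0] > planarity_ratio:
        raise StructureError("plastic slab is not approximately planar")
    pep = np.array([a.xyz for a in conf.peptide_atoms()])
    if np.dot(pep.mean(axis=0) - center, normal) < 0:
        normal = -normal
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    c = float(np.dot(normal, z))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    # rotate about the slab center so an already-aligned system is unchanged
    translation = center - rot @ center
    return conf.transformed(rot, translation)


def surface_frame(conf: SystemConformation) -> SurfaceFrame:
    """Surface frame of an aligned system: z0 = max plastic heavy-atom z."""
    pts = _heavy_plastic_coords(conf)
    return SurfaceFrame(z0=float(pts[:, 2].max()), normal=np.array([0.0, 0.0, 1.0]))


def _cbeta(conf: SystemConformation, residue_index: int,
           glycine_surrogate: bool = False) -> np.ndarray:
    if conf.has_atom(residue_index, "CB"):
        return conf.atom(residue_index, "CB").xyz
    if glycine_surrogate:
        return virtual_cbeta(conf, residue_index)
    raise StructureError(f"residue {residue_index} has no CB atom "
                         "(glycine is excluded unless glycine_surrogate=True)")


def virtual_cbeta(conf: SystemConformation, residue_index: int) -> np.ndarray:
    """Ideal tetrahedral Cbeta position built from N, CA, C (used as a
    glycine surrogate, standing in for the HA2 hydrogen direction)."""
    n = conf.atom(residue_index, "N").xyz
    ca = conf.atom(residue_index, "CA").xyz
    c = conf.atom(residue_index, "C").xyz
    b1 = n - ca
    b2 = c - ca
    b1 /= np.linalg.norm(b1)
    b2 /= np.linalg.norm(b2)
    bisector = -(b1 + b2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b2, b1)
    perp /= np.linalg.norm(perp)
    # tetrahedral direction: in the bisector/perp plane, 1.53 A bond
    direction = bisector * np.cos(np.deg2rad(54.75)) + perp * np.sin(np.deg2rad(54.75))
    return ca + 1.53 * direction


def cbeta_distance(conf: SystemConformation, residue_index: int,
                   frame: SurfaceFrame | None = None,
                   glycine_surrogate: bool = False) -> float:
    """Signed height of Cbeta above the slab top (negative = below)."""
    frame = frame or surface_frame(conf)
    return float(_cbeta(conf, residue_index, glycine_surrogate)[2] - frame.z0)


def ca_cb_angle(conf: SystemConformation, residue_index: int,
                frame: SurfaceFrame | None = None,
                glycine_surrogate: bool = False) -> float:
    """Angle (degrees, in [0, 180]) between CA->CB and the surface normal."""
    frame = frame or surface_frame(conf)
    ca = conf.atom(residue_index, "CA").xyz
    cb = _cbeta(conf, residue_index, glycine_surrogate)
    v = cb - ca
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise StructureError("CA and CB coincide")
    cosang = float(np.clip(np.dot(v / norm, frame.normal), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def shrake_rupley_sasa(centers: np.ndarray, radii: np.ndarray,
                       which: np.ndarray | None = None,
                       probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom (Angstrom^2).

    ``which`` selects the atom indices whose SASA is returned (all occluders
    in ``centers``/``radii`` are always considered).
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    sphere = _fibonacci_sphere(n_points)
    targets = np.arange(len(centers)) if which is None else np.asarray(which)
    out = np.zeros(len(targets))
    for t, i in enumerate(targets):
        pts = centers[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(centers)):
            if j == i:
                continue
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        out[t] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return out


def cbeta_bare_sasa(conf: SystemConformation, residue_index: int,
                    probe: float = 1.4, n_points: int = 960,
                    glycine_surrogate: bool = False) -> float:
    """SASA of the beta carbon with the rest of that side chain removed.

    All atoms of other residues and of the slab are retained as occluders.
    """
    backbone_names = {"N", "CA", "C", "O", "H", "HA", "OXT"}
    centers, radii = [], []
    target_idx = None
    if not conf.has_atom(residue_index, "CB") and glycine_surrogate:
        cb_xyz = virtual_cbeta(conf, residue_index)
        centers.append(cb_xyz)
        radii.append(VDW_RADII["C"])
        target_idx = 0
    for a in conf.atoms:
        if a.segment == "solvent":
            continue
        if a.segment == "peptide" and a.residue_index == residue_index:
            if a.name == "CB":
                target_idx = len(centers)
            elif a.name not in backbone_names:
                continue  # strip the rest of this side chain
        centers.append(a.xyz)
        radii.append(VDW_RADII.get(a.element, 1.7))
    if target_idx is None:
        raise StructureError(f"residue {residue_index} has no CB atom")
    sasa = shrake_rupley_sasa(np.array(centers), np.array(radii),
                              which=np.array([target_idx]),
                              probe=probe, n_points=n_points)
    return float(sasa[0])


@dataclass
class BinningConfig:
    """Half-open [lo, hi) bin edges for the three environment descriptors."""

    distance_edges: tuple = (-np.inf, 0.0, 2.0, 4.0, 6.0, 8.0, np.inf)
    angle_edges: tuple = (0.0, 60.0, 120.0, 180.0 + 1e-9)
    sasa_edges: tuple = (0.0, 40.0, 80.0, np.inf)

    def bin_of(self, distance: float, angle: float, sasa: float) -> tuple[int, int, int]:
        d = int(np.searchsorted(self.distance_edges, distance, side="right")) - 1
        a = int(np.searchsorted(self.angle_edges, angle, side="right")) - 1
        s = int(np.searchsorted(self.sasa_edges, sasa, side="right")) - 1
        return (d, a, s)


@dataclass
class SideChainEnvironment:
    residue_index: int
    distance: float            # Angstrom, signed
    angle: float               # degrees in [0, 180]
    sasa: float                # Angstrom^2
    bin: tuple[int, int, int]


def environment_descriptor(conf: SystemConformation, residue_index: int,
                           binning: BinningConfig | None = None,
                           frame: SurfaceFrame | None = None,
                           glycine_surrogate: bool = False) -> SideChainEnvironment:
    binning = binning or BinningConfig()
    frame = frame or surface_frame(conf)
    d = cbeta_distance(conf, residue_index, frame, glycine_surrogate)
    ang = ca_cb_angle(conf, residue_index, frame, glycine_surrogate)
    sasa = cbeta_bare_sasa(conf, residue_index, glycine_surrogate=glycine_surrogate)
    return SideChainEnvironment(residue_index=residue_index, distance=d,
                                angle=ang, sasa=sasa,
                                bin=binning.bin_of(d, ang, sasa))
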