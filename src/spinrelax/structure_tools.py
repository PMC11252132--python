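"""Geometry and structure-based predictors from PDB coordinate files.

Extracts amide N–H unit vectors (placing the amide hydrogens geometrically
when absent), backbone-nitrogen B-factor statistics, side-chain dihedrals,
Cα distances and ILV methyl–methyl contact maps, and provides two
structure-based predictors of overall tumbling:

* :func:`bead_model_tensor` — rigid-body rotational diffusion tensor of
  identical spherical beads placed at the Cα positions, with pairwise
  hydrodynamic interaction at the Rotne–Prager–Yamakawa level.  Only the
  anisotropy and the symmetry-axis orientation are meaningful; the absolute
  scale depends on the solvent viscosity.
* :func:`empirical_tauc` — linear molecular-weight rule with a
  water-viscosity temperature factor.

PDB parsing is delegated to gemmi; internal indexing is 0-based, author
residue numbers are used at every interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .spin_physics import DiffusionTensor

__all__ = [
    "StructureModel",
    "SpinGeometry",
    "load_structure",
    "load_ensemble_models",
    "place_amide_hydrogens",
    "nh_vectors",
    "backbone_bfactor_stats",
    "chi_angle",
    "ca_distance",
    "methyl_contact_map",
    "bead_model_tensor",
    "empirical_tauc",
    "dihedral",
    "water_viscosity",
    "CHI_ATOMS",
]

NH_BOND_LENGTH = 1.02  # Å, amide N–H

#: Atom quadruples defining χ1/χ2 per residue type (IUPAC).
CHI_ATOMS: dict[tuple[str, int], tuple[str, str, str, str]] = {
    ("TRP", 1): ("N", "CA", "CB", "CG"),
    ("TRP", 2): ("CA", "CB", "CG", "CD1"),
    ("TYR", 1): ("N", "CA", "CB", "CG"),
    ("TYR", 2): ("CA", "CB", "CG", "CD1"),
    ("PHE", 1): ("N", "CA", "CB", "CG"),
    ("PHE", 2): ("CA", "CB", "CG", "CD1"),
    ("LEU", 1): ("N", "CA", "CB", "CG"),
    ("LEU", 2): ("CA", "CB", "CG", "CD1"),
    ("ILE", 1): ("N", "CA", "CB", "CG1"),
    ("ILE", 2): ("CA", "CB", "CG1", "CD1"),
    ("VAL", 1): ("N", "CA", "CB", "CG1"),
    ("MET", 1): ("N", "CA", "CB", "CG"),
    ("MET", 2): ("CA", "CB", "CG", "SD"),
    ("HIS", 1): ("N", "CA", "CB", "CG"),
    ("HIS", 2): ("CA", "CB", "CG", "ND1"),
}

#: ILV methyl carbon names.
METHYL_CARBONS: dict[str, tuple[str, ...]] = {
    "ILE": ("CD1", "CG2"),
    "LEU": ("CD1", "CD2"),
    "VAL": ("CG1", "CG2"),
}


@dataclass
class Residue:
    """One residue: name, author number, atoms as name → (xyz, B-factor)."""

    name: str
    number: int
    chain: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    bfactors: dict[str, float] = field(default_factory=dict)

    def pos(self, atom: str) -> np.ndarray:
        try:
            return self.atoms[atom]
        except KeyError:
            raise KeyError(
                f"atom {atom!r} missing in {self.name}{self.number}"
            ) from None


@dataclass
class StructureModel:
    """Ordered residues of one coordinate model."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for r in self.residues:
            if r.chain in last and r.number <= last[r.chain]:
                raise ValueError(
                    f"residue numbering not strictly increasing in chain {r.chain}"
                )
            last[r.chain] = r.number

    def __len__(self) -> int:
        return len(self.residues)

    def by_number(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise KeyError(f"no residue numbered {number}")

    def ca_coordinates(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues if "CA" in r.atoms])


@dataclass
class SpinGeometry:
    """Per-residue NH unit vectors, backbone-N B-factors, and flags."""

    residues: np.ndarray  # author numbers
    vectors: np.ndarray  # (n, 3) unit vectors N→H
    n_bfactors: np.ndarray  # backbone N B-factors (Å²)
    flags: list[str]  # '' | 'proline' | 'missing'

    def __post_init__(self) -> None:
        ok = self.vectors[np.array([f == "" for f in self.flags], dtype=bool)]
        if len(ok) and np.any(np.abs(np.linalg.norm(ok, axis=1) - 1.0) > 1e-6):
            raise ValueError("stored NH vectors must be unit-norm")

    def usable(self) -> "SpinGeometry":
        """Subset with a valid NH vector (non-proline, atoms present)."""
        mask = np.array([f == "" for f in self.flags], dtype=bool)
        return SpinGeometry(
            residues=self.residues[mask],
            vectors=self.vectors[mask],
            n_bfactors=self.n_bfactors[mask],
            flags=[""] * int(mask.sum()),
        )


def _model_to_residues(model: gemmi.Model) -> list[Residue]:
    out: list[Residue] = []
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            rec = Residue(name=res.name, number=res.seqid.num, chain=chain.name)
            for atom in res:
                # keep the highest-occupancy altloc per atom name
                if atom.name in rec.atoms and atom.occ <= rec.bfactors.get(
                    "_occ_" + atom.name, 0.0
                ):
                    continue
                rec.atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
                rec.bfactors[atom.name] = atom.b_iso
                rec.bfactors["_occ_" + atom.name] = atom.occ
            if rec.atoms:
                if not np.all(np.isfinite(np.array(list(rec.atoms.values())))):
                    raise ValueError("non-finite coordinates in structure")
                out.append(rec)
    return out


def load_structure(path: str | Path) -> StructureModel:
    """Read the first model of a PDB file as a :class:`StructureModel`."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    residues = _model_to_residues(st[0])
    if not residues:
        raise ValueError(f"{path}: no protein atoms found")
    return StructureModel(residues)


def load_ensemble_models(path: str | Path) -> list[StructureModel]:
    """Read every model of a multi-model PDB file."""
    st = gemmi.read_structure(str(path))
    models = [StructureModel(_model_to_residues(m)) for m in st]
    models = [m for m in models if len(m)]
    if not models:
        raise ValueError(f"{path}: no protein atoms found")
    return models


def place_amide_hydrogens(model: StructureModel) -> StructureModel:
    """Add backbone amide hydrogens on the external C(i−1)–N–CA bisector.

    H is placed in the C(i−1), N, CA plane, 1.02 Å from N, bisecting the
    angle external to C(i−1)–N–CA.  Prolines and chain N-termini are
    skipped; residues with missing backbone atoms are left untouched.
    Deterministic: identical input gives bit-identical output.
    """
    prev_by_chain: dict[str, Residue] = {}
    for res in model.residues:
        prev = prev_by_chain.get(res.chain)
        chain_break = prev is None or res.number != prev.number + 1
        prev_by_chain[res.chain] = res
        if res.name == "PRO" or chain_break:
            continue
        if "H" in res.atoms:
            continue
        if "N" not in res.atoms or "CA" not in res.atoms or "C" not in prev.atoms:
            continue
        n = res.atoms["N"]
        u1 = n - prev.atoms["C"]
        u2 = n - res.atoms["CA"]
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        norm = np.linalg.norm(bis)
        if norm < 1e-9:  # pathological straight angle
            continue
        res.atoms["H"] = n + NH_BOND_LENGTH * bis / norm
        res.bfactors["H"] = res.bfactors.get("N", 0.0)
    return model


def nh_vectors(model: StructureModel) -> SpinGeometry:
    """Unit N→H vectors, backbone-N B-factors and per-residue flags."""
    numbers, vectors, bfs, flags = [], [], [], []
    for res in model.residues:
        numbers.append(res.number)
        bfs.append(res.bfactors.get("N", math.nan))
        if res.name == "PRO":
            vectors.append(np.zeros(3))
            flags.append("proline")
        elif "N" in res.atoms and "H" in res.atoms:
            v = res.atoms["H"] - res.atoms["N"]
            vectors.append(v / np.linalg.norm(v))
            flags.append("")
        else:
            vectors.append(np.zeros(3))
            flags.append("missing")
    return SpinGeometry(
        residues=np.array(numbers),
        vectors=np.array(vectors),
        n_bfactors=np.array(bfs),
        flags=flags,
    )


def backbone_bfactor_stats(model: StructureModel) -> tuple[int, float, float]:
    """(count, mean, median) of backbone-nitrogen B-factors (Å²)."""
    bs = [r.bfactors["N"] for r in model.residues if "N" in r.atoms]
    if not bs:
        raise ValueError("no backbone nitrogen atoms in model")
    arr = np.array(bs)
    return len(arr), float(arr.mean()), float(np.median(arr))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees, in (−180, 180]) of four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def chi_angle(model: StructureModel, residue: int, index: int) -> float:
    """Side-chain dihedral χ1 or χ2 (IUPAC-signed degrees)."""
    res = model.by_number(residue)
    key = (res.name, index)
    if key not in CHI_ATOMS:
        raise KeyError(f"chi{index} not defined for residue type {res.name}")
    names = CHI_ATOMS[key]
    pts = [res.pos(a) for a in names]
    return dihedral(*pts)


def ca_distance(model: StructureModel, res_a: int, res_b: int) -> float:
    """Euclidean Cα–Cα distance (Å)."""
    a = model.by_number(res_a).pos("CA")
    b = model.by_number(res_b).pos("CA")
    return float(np.linalg.norm(a - b))


def methyl_contact_map(
    model: StructureModel, cutoff: float = 7.0, domain_boundary: int = 574
) -> list[tuple[tuple[int, str], tuple[int, str], float, str]]:
    """ILV methyl-carbon pairs within ``cutoff`` Å, labelled intra/inter-domain.

    Residues with author number ≤ ``domain_boundary`` belong to the first
    domain.  Methyls of the same residue are not paired with each other.
    """
    methyls: list[tuple[int, str, np.ndarray]] = []
    for res in model.residues:
        for name in METHYL_CARBONS.get(res.name, ()):
            if name in res.atoms:
                methyls.append((res.number, name, res.atoms[name]))
    contacts = []
    for i in range(len(methyls)):
        for j in range(i + 1, len(methyls)):
            ri, ni, pi = methyls[i]
            rj, nj, pj = methyls[j]
            if ri == rj:
                continue
            dist = float(np.linalg.norm(pi - pj))
            if dist <= cutoff:
                same = (ri <= domain_boundary) == (rj <= domain_boundary)
                contacts.append(
                    ((ri, ni), (rj, nj), dist, "intra" if same else "inter")
                )
    return contacts


# ---------------------------------------------------------------------------
# hydrodynamics


def _skew(r: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -r[2], r[1]], [r[2], 0.0, -r[0]], [-r[1], r[0], 0.0]]
    )


def _rpy_mobility(coords: np.ndarray, a: float, eta: float) -> np.ndarray:
    """3N×3N Rotne–Prager–Yamakawa translational mobility matrix.

    Uses the standard overlap-corrected form for bead separations < 2a, so
    consecutive Cα beads (3.8 Å apart) are handled correctly.
    """
    n = len(coords)
    M = np.zeros((3 * n, 3 * n))
    self_mob = 1.0 / (6.0 * math.pi * eta * a)
    eye = np.eye(3)
    for i in range(n):
        M[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = self_mob * eye
        for j in range(i + 1, n):
            rij = coords[j] - coords[i]
            r = float(np.linalg.norm(rij))
            rr = np.outer(rij, rij) / (r * r)
            if r >= 2.0 * a:
                c1 = 1.0 + 2.0 * a * a / (3.0 * r * r)
                c2 = 1.0 - 2.0 * a * a / (r * r)
                block = (c1 * eye + c2 * rr) / (8.0 * math.pi * eta * r)
            else:
                c1 = 1.0 - 9.0 * r / (32.0 * a)
                c2 = 3.0 * r / (32.0 * a)
                block = self_mob * (c1 * eye + c2 * rr)
            M[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            M[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
    return M


def bead_model_tensor(
    model_or_coords: StructureModel | np.ndarray,
    bead_radius: float = 5.0,
    temperature: float = 298.0,
    viscosity: float | None = None,
) -> DiffusionTensor:
    """Rigid-bead rotational diffusion tensor at Cα positions.

    Builds the grand (6×6) resistance matrix of a rigid assembly of
    identical beads with Rotne–Prager–Yamakawa pairwise hydrodynamic
    interaction and extracts the rotational diffusion block of its inverse
    (which is origin-independent).  The tensor is symmetrised, diagonalised
    and reduced to axial symmetry: the parallel component is the eigenvalue
    most separated from the other two, the perpendicular component their
    mean.  Shape, not absolute magnitude, is the meaningful output.
    """
    if isinstance(model_or_coords, StructureModel):
        coords = model_or_coords.ca_coordinates()
    else:
        coords = np.asarray(model_or_coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least 3 beads")
    # degenerate (collinear) geometry check via the gyration tensor rank
    centred = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise ValueError("degenerate bead geometry")
    eta = viscosity if viscosity is not None else water_viscosity(temperature)
    a_m = bead_radius * 1e-10
    xyz = centred * 1e-10
    M = _rpy_mobility(xyz, a_m, eta)
    zeta = np.linalg.inv(M)
    n = len(xyz)
    S = np.array([_skew(r) for r in xyz])
    Z = zeta.reshape(n, 3, n, 3)
    # resistance blocks at the centroid; D_rr of the 6x6 inverse is
    # origin-independent so the centroid is as good as any origin.
    # Bead velocity under rigid motion: u_j = v - S(r_j) ω, force
    # F_i = Σ_j ζ_ij u_j, torque T = Σ_i S(r_i) F_i.
    Xi_tt = np.einsum("iajb->ab", Z)
    Xi_tr = -np.einsum("iajb,jbc->ac", Z, S)
    Xi_rt = np.einsum("iab,ibjc->ac", S, Z)
    Xi_rr = -np.einsum("iab,ibjc,jcd->ad", S, Z, S)
    grand = np.block([[Xi_tt, Xi_tr], [Xi_rt, Xi_rr]])
    D_grand = 1.380649e-23 * temperature * np.linalg.inv(grand)
    Drr = D_grand[3:, 3:]
    Drr = 0.5 * (Drr + Drr.T)
    evals, evecs = np.linalg.eigh(Drr)
    # unique axis: the eigenvalue farthest from the mean of the other two
    seps = [abs(evals[k] - 0.5 * (evals.sum() - evals[k])) for k in range(3)]
    k_par = int(np.argmax(seps))
    Dpar = float(evals[k_par])
    Dperp = float(0.5 * (evals.sum() - evals[k_par]))
    ax = evecs[:, k_par]
    if ax[2] < 0:
        ax = -ax
    beta = math.degrees(math.acos(np.clip(ax[2], -1.0, 1.0)))
    alpha = math.degrees(math.atan2(ax[1], ax[0])) % 360.0
    return DiffusionTensor(Dperp=Dperp, Dpar=Dpar, alpha=alpha, beta=beta).canonicalized()


def water_viscosity(temperature: float) -> float:
    """Dynamic viscosity of water (Pa·s), Vogel-type empirical fit.

    Valid over roughly 273–373 K; raises outside that range.
    """
    if not (250.0 < temperature < 400.0):
        raise ValueError("non-physical temperature for liquid water")
    return 2.414e-5 * 10.0 ** (247.8 / (temperature - 140.0))


def empirical_tauc(
    molecular_weight_kda: float,
    temperature: float = 298.0,
    coefficient: float = 0.61,
) -> float:
    """Empirical overall correlation time from molecular weight, in ns.

    τC = coefficient · MW · (η_w(T)/η_w(298 K)) · (298/T).  The default
    coefficient of 0.61 ns/kDa is calibrated for a compact globular fold at
    298 K; halving or doubling MW scales τC accordingly, so a
    monomer/dimer pair maps to a factor-two difference in τC.
    """
    if molecular_weight_kda < 0:
        raise ValueError("molecular weight must be non-negative")
    visc_factor = water_viscosity(temperature) / water_viscosity(298.0)
    return coefficient * molecular_weight_kda * visc_factor * (298.0 / temperature)
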