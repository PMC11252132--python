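"""Stage 3: Cartesian PCA of conformational ensembles and rotamer states.

Multi-model structures (e.g. structure-prediction ensembles, with
per-residue confidence written in the B-factor column) are superposed on a
rigid domain core, decomposed by covariance PCA of the flattened Cartesian
coordinates of a configurable atom selection, and clustered into discrete
side-chain rotamer states from two probe dihedrals (a χ2 and a χ1).

Two canonical selections are supported by :class:`PCAConfig`:
a backbone-wide analysis (N, Cα, C, O of a residue range plus configured
side chains) and a focused analysis of all heavy atoms of two short
stretches around the probe residues.  State boundaries are fixed circular
midpoints between the configured rotamer anchors (nearest-anchor
assignment on the circle), not a data-driven clustering — deterministic by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from scipy.spatial.transform import Rotation

from .structure_tools import CHI_ATOMS, StructureModel, dihedral, load_ensemble_models

__all__ = [
    "Ensemble",
    "PCAConfig",
    "PCAResult",
    "StateAssignment",
    "RotamerProbe",
    "align_ensemble",
    "run_pca",
    "pc_extreme_structures",
    "assign_states",
    "plddt_summary",
    "detect_multimodal_chi2",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Ensemble:
    """M conformations sharing one atom inventory.

    ``atoms`` is a frame with one row per atom (columns: residue, resname,
    name); ``coords`` has shape (M, A, 3) in Å.  Per-residue confidence
    (pLDDT, 0–100) is taken from the B-factor column when
    ``plddt_from_bfactor`` is set — the structure-prediction convention.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    bfactors: np.ndarray | None = None  # (M, A)
    ptm: np.ndarray | None = None  # (M,)
    plddt_from_bfactor: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (M, A, 3)")
        if self.n_models < 2:
            raise ValueError("an ensemble needs at least 2 models")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords and atom inventory disagree")
        if self.plddt_from_bfactor and self.bfactors is not None:
            if np.any((self.bfactors < 0) | (self.bfactors > 100)):
                raise ValueError("pLDDT values must lie in [0, 100]")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def atom_index(self, residue: int, name: str) -> int:
        sel = self.atoms.index[
            (self.atoms["residue"] == residue) & (self.atoms["name"] == name)
        ]
        if len(sel) != 1:
            raise KeyError(f"atom {name!r} of residue {residue} not found")
        return int(sel[0])

    def select(
        self,
        residues: Sequence[int] | None = None,
        names: Sequence[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Indices of atoms matching residue and/or atom-name filters."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if residues is not None:
            mask &= self.atoms["residue"].isin(list(residues)).to_numpy()
        if names is not None:
            mask &= self.atoms["name"].isin(list(names)).to_numpy()
        if heavy_only:
            mask &= ~self.atoms["name"].str.startswith("H").to_numpy()
        return np.flatnonzero(mask)

    def residue_plddt(self, residue: int) -> np.ndarray:
        """Per-model confidence of one residue (from its CA B-factor)."""
        if self.bfactors is None:
            raise ValueError("ensemble carries no confidence values")
        return self.bfactors[:, self.atom_index(residue, "CA")]

    def model_dihedral(self, model: int, residue: int, chi: int) -> float:
        row = self.atoms[self.atoms["residue"] == residue]
        if row.empty:
            raise KeyError(f"residue {residue} not in ensemble")
        resname = row["resname"].iloc[0]
        names = CHI_ATOMS[(resname, chi)]
        pts = [self.coords[model, self.atom_index(residue, a)] for a in names]
        return dihedral(*pts)

    @classmethod
    def from_models(
        cls, models: list[StructureModel], plddt_from_bfactor: bool = False
    ) -> "Ensemble":
        ref = models[0]
        inventory = [
            (r.number, r.name, a) for r in ref.residues for a in r.atoms
            if not a.startswith("_")
        ]
        atoms = pd.DataFrame(inventory, columns=["residue", "resname", "name"])
        coords = np.empty((len(models), len(inventory), 3))
        bfs = np.zeros((len(models), len(inventory)))
        for m, model in enumerate(models):
            res_map = {r.number: r for r in model.residues}
            for a, (num, _resname, name) in enumerate(inventory):
                try:
                    res = res_map[num]
                    coords[m, a] = res.atoms[name]
                    bfs[m, a] = res.bfactors.get(name, 0.0)
                except KeyError:
                    raise ValueError(
                        "all ensemble models must share one atom inventory "
                        f"(model {m} lacks {name} of residue {num})"
                    ) from None
        return cls(
            atoms=atoms,
            coords=coords,
            bfactors=bfs,
            plddt_from_bfactor=plddt_from_bfactor,
        )

    @classmethod
    def from_pdb(cls, path: str | Path, plddt_from_bfactor: bool = False) -> "Ensemble":
        return cls.from_models(
            load_ensemble_models(path), plddt_from_bfactor=plddt_from_bfactor
        )

    def to_pdb(self, path: str | Path) -> None:
        """Write as a multi-model PDB file (B column = stored values)."""
        st = gemmi.Structure()
        for m in range(self.n_models):
            model = gemmi.Model(m + 1)
            chain = gemmi.Chain("A")
            current = None
            for a, row in enumerate(self.atoms.itertuples()):
                if current is None or current.seqid.num != row.residue:
                    current = gemmi.Residue()
                    current.name = row.resname
                    current.seqid = gemmi.SeqId(int(row.residue), " ")
                    chain.add_residue(current)
                    current = chain[-1]
                atom = gemmi.Atom()
                atom.name = row.name
                x, y, z = self.coords[m, a]
                atom.pos = gemmi.Position(x, y, z)
                atom.element = gemmi.Element(row.name[0])
                atom.occ = 1.0
                atom.b_iso = float(self.bfactors[m, a]) if self.bfactors is not None else 0.0
                current.add_atom(atom)
            model.add_chain(chain)
            st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


@dataclass
class PCAConfig:
    """Atom selections for superposition and analysis.

    Defaults follow the two-domain analysis this package was built around:
    alignment on the Cα atoms of three rigid stretches of the first domain
    (344–467, 484–500, 510–562); analysis atoms are either the backbone
    atoms of a residue range plus configured side chains ("backbone"
    flavour) or all heavy atoms of short stretches ("focused" flavour).
    """

    alignment_stretches: tuple = ((344, 467), (484, 500), (510, 562))
    analysis_stretches: tuple = ((344, 717),)
    analysis_backbone_only: bool = True
    sidechain_residues: tuple = ()
    n_components: int = 10

    def alignment_residues(self) -> list[int]:
        return [r for lo, hi in self.alignment_stretches for r in range(lo, hi + 1)]

    def analysis_indices(self, ensemble: Ensemble) -> np.ndarray:
        res = [r for lo, hi in self.analysis_stretches for r in range(lo, hi + 1)]
        if self.analysis_backbone_only:
            idx = ensemble.select(residues=res, names=BACKBONE_ATOMS)
            if self.sidechain_residues:
                side = ensemble.select(residues=self.sidechain_residues, heavy_only=True)
                side = np.setdiff1d(
                    side, ensemble.select(names=BACKBONE_ATOMS), assume_unique=False
                )
                idx = np.union1d(idx, side)
        else:
            idx = ensemble.select(residues=res, heavy_only=True)
        if len(idx) == 0:
            raise ValueError("analysis atom selection is empty")
        return idx


@dataclass
class PCAResult:
    """Orthonormal loadings, per-model scores and variance fractions."""

    loadings: np.ndarray  # (K, 3*Asel)
    scores: np.ndarray  # (M, K)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray  # (3*Asel,)
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(len(self.loadings)), atol=1e-8):
            raise ValueError("loadings must be orthonormal")


@dataclass
class RotamerProbe:
    """A probe dihedral with its two rotamer anchor angles (degrees)."""

    residue: int
    chi: int
    anchors: tuple[float, float]


@dataclass
class StateAssignment:
    """Per-model rotamer-state labels and population fractions."""

    labels: list[str]
    chi_a: np.ndarray
    chi_b: np.ndarray
    populations: dict[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.populations.values()) - 1.0) > 1e-12:
            raise ValueError("state populations must sum to 1")
        if len(self.labels) != len(self.chi_a):
            raise ValueError("every model must be labelled")


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation/translation of ``mobile`` onto ``target``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.as_matrix(), mc, tc


def align_ensemble(ensemble: Ensemble, cfg: PCAConfig, passes: int = 2) -> Ensemble:
    """Superpose every model onto the iteratively refined mean structure.

    The least-squares rigid fit uses the Cα atoms of the alignment
    stretches; the mean is recomputed after each pass (2 passes are enough
    for convergence to ~1e-9 on rigid-body ensembles).  Idempotent.
    """
    idx = ensemble.select(residues=cfg.alignment_residues(), names=["CA"])
    if len(idx) < 3:
        raise ValueError("alignment selection needs at least 3 CA atoms")
    coords = ensemble.coords.copy()
    reference = coords[0, idx]
    for _ in range(passes):
        for m in range(len(coords)):
            R, mc, tc = _kabsch(coords[m, idx], reference)
            coords[m] = (coords[m] - mc) @ R.T + tc
        reference = coords[:, idx].mean(axis=0)
    return Ensemble(
        atoms=ensemble.atoms,
        coords=coords,
        bfactors=ensemble.bfactors,
        ptm=ensemble.ptm,
        plddt_from_bfactor=ensemble.plddt_from_bfactor,
    )


def run_pca(ensemble: Ensemble, cfg: PCAConfig) -> PCAResult:
    """Mean-centred covariance PCA of the flattened analysis coordinates.

    No mass weighting and no variance scaling: components are directions in
    plain Cartesian coordinate space, so loadings can be inverse-transformed
    into structures directly.
    """
    idx = cfg.analysis_indices(ensemble)
    X = ensemble.coords[:, idx, :].reshape(ensemble.n_models, -1)
    k = min(cfg.n_components, ensemble.n_models - 1, X.shape[1])
    if k < 1:
        raise ValueError("fewer models than requested components")
    pca = PCA(n_components=k, svd_solver="full")
    with np.errstate(invalid="ignore"):
        scores = pca.fit_transform(X)
        evr = pca.explained_variance_ratio_
    # a degenerate (all-identical) ensemble has zero total variance
    evr = np.nan_to_num(evr, nan=0.0)
    return PCAResult(
        loadings=pca.components_,
        scores=scores,
        explained_variance_ratio=evr,
        mean=pca.mean_,
        atom_indices=idx,
    )


def pc_extreme_structures(
    result: PCAResult, component: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates at the observed extremes of one component.

    Returns (low, high): the mean structure displaced along the component
    loading by the minimum and maximum observed score, reshaped to
    (A_sel, 3).  Projecting the returned structures back recovers the
    min/max scores exactly (linear algebra, not refit).
    """
    if not (0 <= component < len(result.loadings)):
        raise IndexError(f"component {component} out of range")
    s = result.scores[:, component]
    lo = result.mean + s.min() * result.loadings[component]
    hi = result.mean + s.max() * result.loadings[component]
    return lo.reshape(-1, 3), hi.reshape(-1, 3)


def _circular_distance(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def assign_states(
    ensemble: Ensemble,
    probe_a: RotamerProbe = RotamerProbe(residue=580, chi=2, anchors=(80.0, -100.0)),
    probe_b: RotamerProbe = RotamerProbe(residue=657, chi=1, anchors=(-93.0, 57.0)),
    state_names: tuple[str, str, str, str] = ("I", "II", "III", "IV"),
) -> StateAssignment:
    """Assign each model to one of four rotamer states.

    The two probe dihedrals are thresholded circularly: each angle is
    assigned to its nearest anchor on the circle (equivalent to fixed
    boundaries at the circular midpoints of the anchors, so −179° and
    +179° land in the same class).  With the default probes — χ2 of the
    tryptophan gate anchored at +80° (outward) / −100° (inward) and χ1 of
    the partner tyrosine at −93° / +57° — the four states are
    I (out, −93), II (out, +57), III (in, −93), IV (in, +57).
    """
    M = ensemble.n_models
    chi_a = np.array([ensemble.model_dihedral(m, probe_a.residue, probe_a.chi) for m in range(M)])
    chi_b = np.array([ensemble.model_dihedral(m, probe_b.residue, probe_b.chi) for m in range(M)])
    labels = []
    for a, b in zip(chi_a, chi_b):
        a_first = _circular_distance(a, probe_a.anchors[0]) <= _circular_distance(
            a, probe_a.anchors[1]
        )
        b_first = _circular_distance(b, probe_b.anchors[0]) <= _circular_distance(
            b, probe_b.anchors[1]
        )
        if a_first:
            labels.append(state_names[0] if b_first else state_names[1])
        else:
            labels.append(state_names[2] if b_first else state_names[3])
    pops = {s: labels.count(s) / M for s in state_names}
    return StateAssignment(labels=labels, chi_a=chi_a, chi_b=chi_b, populations=pops)


def plddt_summary(
    ensemble: Ensemble, residues: int | Sequence[int]
) -> pd.DataFrame:
    """Min/max/mean confidence per residue over all models.

    For a single residue the returned frame also carries the per-model
    values in ``attrs['per_model']`` so they can be joined to a
    :class:`StateAssignment` for per-state confidence comparison.
    """
    single = isinstance(residues, (int, np.integer))
    res_list = [int(residues)] if single else [int(r) for r in residues]
    rows = []
    per_model = None
    for r in res_list:
        vals = ensemble.residue_plddt(r)
        rows.append((r, float(vals.min()), float(vals.max()), float(vals.mean())))
        if single:
            per_model = vals
    out = pd.DataFrame(rows, columns=["residue", "min", "max", "mean"]).set_index(
        "residue"
    )
    if per_model is not None:
        out.attrs["per_model"] = per_model
    return out


def detect_multimodal_chi2(
    ensemble: Ensemble, min_minor_fraction: float = 0.05
) -> list[int]:
    """Residues whose χ2 distribution over the ensemble is clearly bimodal.

    A helper for choosing the side-chain residues of the backbone-flavour
    PCA selection: for every residue type with a defined χ2, the circular
    angles are split at their circular mean ±90° and the residue is
    reported when the minor mode holds at least ``min_minor_fraction`` of
    the models and the two mode centres are ≥ 60° apart.
    """
    out = []
    for residue, grp in ensemble.atoms.groupby("residue"):
        resname = grp["resname"].iloc[0]
        if (resname, 2) not in CHI_ATOMS:
            continue
        needed = set(CHI_ATOMS[(resname, 2)])
        if not needed <= set(grp["name"]):
            continue
        angles = np.array(
            [ensemble.model_dihedral(m, int(residue), 2) for m in range(ensemble.n_models)]
        )
        rad = np.radians(angles)
        mean_dir = math.degrees(math.atan2(np.sin(rad).sum(), np.cos(rad).sum()))
        near = np.array([_circular_distance(a, mean_dir) <= 90.0 for a in angles])
        minor = min(near.mean(), 1.0 - near.mean())
        if minor < min_minor_fraction:
            continue
        c1 = angles[near]
        c2 = angles[~near]
        if len(c1) and len(c2):
            m1 = math.degrees(math.atan2(np.sin(np.radians(c1)).sum(), np.cos(np.radians(c1)).sum()))
            m2 = math.degrees(math.atan2(np.sin(np.radians(c2)).sum(), np.cos(np.radians(c2)).sum()))
            if _circular_distance(m1, m2) >= 60.0:
                out.append(int(residue))
    return out
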