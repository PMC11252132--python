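"""Synthetic-data generators with known ground truth for every pipeline stage.

Relaxation data are generated from the same forward model the analysis
inverts: an axially symmetric diffusion tensor plus the Woessner spectral
density gives per-residue noiseless R1, R2, NOE and η_xy, from which decay
curves, saturated/reference pairs and TROSY/anti-TROSY pairs are
synthesised; Gaussian noise is applied last and exchange contributions can
be injected into R2 for chosen residues.

Conformational ensembles are a deliberately minimal toy: a two-domain
backbone polymer whose second domain rotates about a hinge, with two
four-atom side-chain probes (a tryptophan-like χ2 and a tyrosine-like χ1)
drawn from a four-state rotamer distribution, and a coupling coefficient
that correlates the hinge angle with the first probe's rotamer.  It
reproduces the statistical structure PCA consumes (a dominant hinge mode
coupled to a discrete flip), not molecular realism — no sterics, no
chemistry.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rates_io import DecaySeries, IntensityPair, NOEPair, RelaxationTable
from .spin_physics import (
    DiffusionTensor,
    FieldContext,
    expand_axial,
    jw_aniso,
    make_field_context,
    predict_rates,
)
from .ensemble_pca import Ensemble

__all__ = [
    "RelaxationSimSpec",
    "EnsembleSimSpec",
    "simulate_vectors",
    "simulate_decay",
    "simulate_relaxation_dataset",
    "simulate_ensemble",
    "R1_DELAYS_900",
    "R2_DELAYS_900",
]

#: Longitudinal relaxation delay schedule (s) used at 900 MHz.
R1_DELAYS_900 = (0.08, 0.16, 0.32, 0.48, 0.72, 0.88, 1.12, 1.36, 1.76, 2.24, 2.4)
#: Transverse schedule (s); repeated entries are measured twice.
R2_DELAYS_900 = (0.0058, 0.0115, 0.0115, 0.0173, 0.0230, 0.0230, 0.0288, 0.0346, 0.0346, 0.0403, 0.0403)

# Table-1-like defaults: the full-protein axially symmetric tensor of a
# ~43 kDa two-domain monomer tumbling at ~26.5 ns.
DEFAULT_TRUTH = DiffusionTensor(Dperp=0.56e7, Dpar=0.77e7, alpha=11.0, beta=59.0)


@dataclass
class RelaxationSimSpec:
    """Ground truth and acquisition layout for a relaxation simulation."""

    tensor: DiffusionTensor = field(default_factory=lambda: DEFAULT_TRUTH)
    S2: float = 0.88
    fields_mhz: tuple = (900.0,)
    n_vectors: int = 116
    vectors: np.ndarray | None = None  # overrides n_vectors when given
    noise: Mapping[str, float] = field(
        default_factory=lambda: {
            "R1": 0.02,
            "R2": 0.02,
            "NOE": 0.02,
            "eta_xy": 0.05,
            "volume": 0.01,
        }
    )
    rex_injection: Mapping[int, float] = field(default_factory=dict)
    ccr_delay_s: float = 0.010
    amplitude: float = 100.0
    intensity_drift: float = 0.0  # optional monotone amplitude decay, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.noise.values()):
            raise ValueError("noise fractions must be non-negative")


@dataclass
class EnsembleSimSpec:
    """Layout of the toy two-domain hinge/rotamer ensemble."""

    n_models: int = 2000
    n_residues_a: int = 30
    n_residues_b: int = 30
    # the hinge flip is a discrete two-state mode: cluster separation is
    # large against the within-cluster spread, so the sign of the hinge
    # (and hence of the leading PCA score) is unambiguous per model
    hinge_mean_deg: float = 10.0
    hinge_sd_deg: float = 1.2
    state_fractions: tuple = (0.555, 0.083, 0.350, 0.011)
    coupling: float = 1.0
    coord_noise: float = 0.1  # Å
    chi_sd_deg: float = 8.0
    chi_a_anchors: tuple = (80.0, -100.0)
    chi_b_anchors: tuple = (-93.0, 57.0)
    plddt_state_means: tuple = (92.0, 90.0, 80.0, 78.0)
    plddt_sd: float = 2.0
    plddt_other: float = 85.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("need at least 2 models")
        # rounded published-style population tables may sum to 0.999;
        # tolerate small rounding and renormalise at draw time
        if abs(sum(self.state_fractions) - 1.0) > 0.01 or any(
            f < 0 for f in self.state_fractions
        ):
            raise ValueError("state fractions must be non-negative and sum to ~1")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")

    @property
    def probe_a_residue(self) -> int:
        return self.n_residues_a + 3

    @property
    def probe_b_residue(self) -> int:
        return self.n_residues_a + self.n_residues_b - 5


def simulate_vectors(n: int, scheme: str = "fibonacci", seed: int = 0) -> np.ndarray:
    """Unit vectors spread over the sphere.

    'fibonacci' is deterministic and near-uniform; 'uniform' draws i.i.d.
    directions from the seeded generator.
    """
    if n < 1:
        raise ValueError("need at least one vector")
    if scheme == "fibonacci":
        i = np.arange(n)
        golden = (1.0 + math.sqrt(5.0)) / 2.0
        z = 1.0 - (2.0 * i + 1.0) / n
        phi = 2.0 * math.pi * i / golden
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
        return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    if scheme == "uniform":
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    raise ValueError(f"unknown scheme {scheme!r}")


def simulate_decay(
    rate: float,
    delays: Sequence[float],
    noise_fraction: float = 0.0,
    seed: int = 0,
    residue: int = 0,
    amplitude: float = 100.0,
    drift: float = 0.0,
) -> DecaySeries:
    """A·exp(−R·t) sampled at ``delays`` with relative Gaussian noise.

    ``drift`` models slow sample degradation as a monotone amplitude loss
    applied in acquisition order: the last acquired point is attenuated by
    the full fraction (e.g. 0.25 for a 25 % signal loss over the series).
    Off by default.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(delays, dtype=float)
    clean = amplitude * np.exp(-rate * t)
    if drift > 0 and len(t) > 1:
        clean = clean * (1.0 - drift * np.arange(len(t)) / (len(t) - 1))
    sigma = max(noise_fraction * amplitude, 1e-12 * amplitude)
    noisy = clean + (rng.normal(scale=sigma, size=len(t)) if noise_fraction > 0 else 0.0)
    return DecaySeries(
        residue=residue, delays=t, volumes=noisy, sigmas=np.full(len(t), sigma)
    )


def _noiseless_rates(
    spec: RelaxationSimSpec, fc: FieldContext, vectors: np.ndarray
) -> pd.DataFrame:
    rows = []
    for i, v in enumerate(vectors):
        exp = expand_axial(spec.tensor, v, S2=spec.S2)
        R1, R2, noe, eta = predict_rates(lambda w, e=exp: jw_aniso(e, w), fc)
        rows.append((i + 1, R1, R2, noe, eta))
    return pd.DataFrame(
        rows, columns=["residue", "R1", "R2", "NOE", "eta_xy"]
    ).set_index("residue")


def simulate_relaxation_dataset(
    spec: RelaxationSimSpec,
) -> tuple[dict[float, RelaxationTable], dict[str, list[DecaySeries]], list[NOEPair], dict[float, list[IntensityPair]]]:
    """Forward-model a complete relaxation dataset.

    Returns ``(tables, decays, noe_pairs, ccr_pairs)``:

    * ``tables`` — one :class:`RelaxationTable` per field, rates carrying
      Gaussian noise (σ columns = noise fraction × value) and any injected
      Rex added to R2;
    * ``decays`` — R1/R2 decay series (keys 'R1', 'R2') at the first field
      whose fitted rates reproduce the table values at zero noise;
    * ``noe_pairs`` — saturated/reference pairs;
    * ``ccr_pairs`` — TROSY/anti-TROSY pairs at Δ=0 and the CCR delay.
    """
    rng = np.random.default_rng(spec.seed)
    vectors = (
        np.asarray(spec.vectors, dtype=float)
        if spec.vectors is not None
        else simulate_vectors(spec.n_vectors)
    )
    tables: dict[float, RelaxationTable] = {}
    decays: dict[str, list[DecaySeries]] = {"R1": [], "R2": []}
    noe_pairs: list[NOEPair] = []
    ccr_pairs: dict[float, list[IntensityPair]] = {0.0: [], spec.ccr_delay_s: []}

    for fi, mhz in enumerate(spec.fields_mhz):
        fc = make_field_context(mhz)
        clean = _noiseless_rates(spec, fc, vectors)
        for res, rex in spec.rex_injection.items():
            if res in clean.index:
                clean.loc[res, "R2"] += rex
        noisy = clean.copy()
        for col in ("R1", "R2", "NOE", "eta_xy"):
            frac = spec.noise.get(col, 0.0)
            err = np.abs(clean[col].to_numpy()) * max(frac, 1e-12)
            if frac > 0:
                noisy[col] = clean[col] + rng.normal(scale=err)
            noisy[col + "_err"] = err
        tables[mhz] = RelaxationTable(
            noisy,
            field_mhz=mhz,
            provenance={"generator": "synthetic", "seed": str(spec.seed)},
        )

        if fi == 0:
            vol_noise = spec.noise.get("volume", 0.0)
            for res in clean.index:
                seed_r1 = int(rng.integers(0, 2**31 - 1))
                seed_r2 = int(rng.integers(0, 2**31 - 1))
                decays["R1"].append(
                    simulate_decay(
                        float(clean.loc[res, "R1"]), R1_DELAYS_900, vol_noise,
                        seed=seed_r1, residue=int(res), amplitude=spec.amplitude,
                        drift=spec.intensity_drift,
                    )
                )
                decays["R2"].append(
                    simulate_decay(
                        float(clean.loc[res, "R2"]), R2_DELAYS_900, vol_noise,
                        seed=seed_r2, residue=int(res), amplitude=spec.amplitude,
                        drift=spec.intensity_drift,
                    )
                )
                noe = float(clean.loc[res, "NOE"])
                sig = max(vol_noise * spec.amplitude, 1e-12)
                noe_pairs.append(
                    NOEPair(
                        residue=int(res),
                        Isat=noe * spec.amplitude + (rng.normal(scale=sig) if vol_noise else 0.0),
                        Iref=spec.amplitude + (rng.normal(scale=sig) if vol_noise else 0.0),
                        sigma_sat=sig,
                        sigma_ref=sig,
                    )
                )
                eta = float(clean.loc[res, "eta_xy"])
                R2v = float(clean.loc[res, "R2"])
                for delta in (0.0, spec.ccr_delay_s):
                    ia = spec.amplitude * math.exp(-(R2v - eta) * delta)
                    ib = spec.amplitude * math.exp(-(R2v + eta) * delta)
                    if vol_noise:
                        ia += rng.normal(scale=sig)
                        ib += rng.normal(scale=sig)
                    ccr_pairs[delta].append(
                        IntensityPair(residue=int(res), Ialpha=ia, Ibeta=ib, Delta=delta)
                    )
    return tables, decays, noe_pairs, ccr_pairs


# ---------------------------------------------------------------------------
# toy ensemble


def _rotation_about_y(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _place_dihedral_atom(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
    length: float, angle_deg: float, chi_deg: float,
) -> np.ndarray:
    """Fourth atom at (length, bond angle, dihedral) from three anchors."""
    b1 = p1 - p0
    b2 = p2 - p1
    bc = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    chi = math.radians(chi_deg)
    d = (
        -bc * math.cos(ang)
        + math.sin(ang) * (math.cos(chi) * m - math.sin(chi) * n)
    )
    return p2 + length * d


def simulate_ensemble(spec: EnsembleSimSpec) -> Ensemble:
    """Generate the toy hinge/rotamer ensemble.

    Domain A (residues 1..nA) is fixed; domain B (nA+1..nA+nB) is rotated
    about the y-axis through the hinge point at the end of domain A by a
    per-model angle.  Each model draws a rotamer state from
    ``state_fractions``; the tryptophan-like probe's χ2 and the
    tyrosine-like probe's χ1 are drawn around the state's anchors.  With
    ``coupling`` = 1 the hinge-angle sign is fully determined by the first
    probe's rotamer (outward ↔ positive), with 0 it is independent.
    Per-residue confidence is written as a pLDDT-style value: the first
    probe residue gets a state-dependent mean, every other residue a flat
    background.
    """
    rng = np.random.default_rng(spec.seed)
    nA, nB = spec.n_residues_a, spec.n_residues_b
    spacing = 3.8

    def backbone(num: int, origin: np.ndarray, resname: str) -> dict[str, np.ndarray]:
        # zig-zag pseudo-backbone: N and C flank CA so dihedral probes and
        # CA-based alignment both have the atoms they need
        ca = origin
        return {
            "N": ca + np.array([-1.2, 0.8, 0.0]),
            "CA": ca,
            "C": ca + np.array([1.2, 0.8, 0.0]),
        }

    # state draw per model
    p = np.asarray(spec.state_fractions, dtype=float)
    states = rng.choice(4, size=spec.n_models, p=p / p.sum())
    outward = states < 2  # states I, II have the first probe outward
    sign = np.where(outward, 1.0, -1.0)
    random_sign = rng.choice([1.0, -1.0], size=spec.n_models)
    use_coupled = rng.random(spec.n_models) < spec.coupling
    hinge_sign = np.where(use_coupled, sign, random_sign)
    hinge = hinge_sign * np.abs(
        rng.normal(spec.hinge_mean_deg, spec.hinge_sd_deg, size=spec.n_models)
    )

    chi_a_anchor = np.where(outward, spec.chi_a_anchors[0], spec.chi_a_anchors[1])
    b_first = (states == 0) | (states == 2)  # states I, III share the first χ1 anchor
    chi_b_anchor = np.where(b_first, spec.chi_b_anchors[0], spec.chi_b_anchors[1])
    chi_a = chi_a_anchor + rng.normal(scale=spec.chi_sd_deg, size=spec.n_models)
    chi_b = chi_b_anchor + rng.normal(scale=spec.chi_sd_deg, size=spec.n_models)

    hinge_point = np.array([nA * spacing, 0.0, 0.0])
    atoms_rows: list[tuple[int, str, str]] = []
    base_atoms: list[tuple[int, str, np.ndarray, bool]] = []  # (res, name, pos, in_domain_b)
    for i in range(1, nA + nB + 1):
        in_b = i > nA
        resname = "GLY"
        if i == spec.probe_a_residue:
            resname = "TRP"
        elif i == spec.probe_b_residue:
            resname = "TYR"
        origin = np.array([(i - 1) * spacing, 2.0 * (i % 2), 0.0])
        for name, pos in backbone(i, origin, resname).items():
            atoms_rows.append((i, resname, name))
            base_atoms.append((i, name, pos, in_b))
        if resname in ("TRP", "TYR"):
            # CB off the backbone plane; CG/CD1 are placed per model
            cb = origin + np.array([0.0, -0.9, 1.2])
            atoms_rows.append((i, resname, "CB"))
            base_atoms.append((i, "CB", cb, in_b))
            for extra in ("CG",) + (("CD1",) if resname == "TRP" else ()):
                atoms_rows.append((i, resname, extra))
                base_atoms.append((i, extra, np.zeros(3), in_b))

    atoms = pd.DataFrame(atoms_rows, columns=["residue", "resname", "name"])
    A = len(atoms)
    coords = np.empty((spec.n_models, A, 3))
    bfactors = np.empty((spec.n_models, A))

    col = {(r, n): k for k, (r, n, _, _) in enumerate(base_atoms)}
    ra, rb = spec.probe_a_residue, spec.probe_b_residue

    for m in range(spec.n_models):
        pos = np.array([p for (_, _, p, _) in base_atoms])
        # per-model probe side chains (before the hinge rotation so they
        # ride rigidly with domain B)
        # TRP: χ2 over CA-CB-CG-CD1; χ1 fixed at a reference value
        n_a, ca_a, cb_a = (pos[col[(ra, x)]] for x in ("N", "CA", "CB"))
        cg_a = _place_dihedral_atom(n_a, ca_a, cb_a, 1.52, 114.0, -60.0)
        pos[col[(ra, "CG")]] = cg_a
        cd1_a = _place_dihedral_atom(ca_a, cb_a, cg_a, 1.43, 127.0, float(chi_a[m]))
        pos[col[(ra, "CD1")]] = cd1_a
        # TYR: χ1 over N-CA-CB-CG
        n_b, ca_b, cb_b = (pos[col[(rb, x)]] for x in ("N", "CA", "CB"))
        cg_b = _place_dihedral_atom(n_b, ca_b, cb_b, 1.52, 114.0, float(chi_b[m]))
        pos[col[(rb, "CG")]] = cg_b

        R = _rotation_about_y(float(hinge[m]))
        in_b_mask = np.array([b for (_, _, _, b) in base_atoms])
        pos[in_b_mask] = (pos[in_b_mask] - hinge_point) @ R.T + hinge_point
        if spec.coord_noise > 0:
            pos = pos + rng.normal(scale=spec.coord_noise, size=pos.shape)
        coords[m] = pos

        plddt = np.full(A, spec.plddt_other)
        probe_val = spec.plddt_state_means[states[m]] + rng.normal(scale=spec.plddt_sd)
        res_col = atoms["residue"].to_numpy()
        plddt[res_col == ra] = np.clip(probe_val, 0.0, 100.0)
        bfactors[m] = np.clip(plddt, 0.0, 100.0)

    ens = Ensemble(
        atoms=atoms,
        coords=coords,
        bfactors=bfactors,
        ptm=np.full(spec.n_models, 0.9),
        plddt_from_bfactor=True,
    )
    ens.atoms.attrs["true_states"] = states
    ens.atoms.attrs["true_hinge_deg"] = hinge
    return ens
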