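"""Synthetic inputs: backbones from internal coordinates and CV trajectories.

Everything here is generated programmatically and deterministically from a
seed — no downloads.  Backbone coordinates are grown atom by atom (NeRF
placement) from prescribed phi/psi/omega torsions and fixed standard
peptide stereochemistry, so that recomputing dihedrals from the built
coordinates recovers the prescribed values to numerical precision.  The
two-state trajectory generator emulates the switching structure of a
folding/unfolding simulation: a two-state Markov chain over conformational
states with Gaussian dihedral noise within each state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from foldcv.constants import (
    ANGLE_CA_C_N,
    ANGLE_C_N_CA,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_CA_C,
    BOND_N_CA,
)
from foldcv.errors import StructureError
from foldcv.structure_io import BackboneChain, DihedralRecord, Residue

__all__ = [
    "InternalCoordSpec",
    "StateParams",
    "build_backbone",
    "dihedral_records",
    "random_dihedrals",
    "two_state_cv_trajectory",
    "trajectory_to_chains",
    "write_pdb",
    "wrap_angle",
]


def wrap_angle(angle):
    """Wrap degrees to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -np.mod(-a + 180.0, 360.0) + 180.0  # maps to (-180, 180]
    if np.ndim(angle) == 0:
        return float(out)
    return out


@dataclass
class InternalCoordSpec:
    """Per-residue torsions plus backbone stereochemistry for the builder.

    ``phi[0]`` and the last residue's psi/omega are ignored (those torsions
    do not exist on a chain).  Lengths in Angstrom, angles in degrees.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    bond_n_ca: float = BOND_N_CA
    bond_ca_c: float = BOND_CA_C
    bond_c_n: float = BOND_C_N
    angle_n_ca_c: float = ANGLE_N_CA_C
    angle_ca_c_n: float = ANGLE_CA_C_N
    angle_c_n_ca: float = ANGLE_C_N_CA
    resname: str = "ALA"
    chain_id: str = "A"

    def __post_init__(self):
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        n = self.phi.size
        if self.psi.size != n or self.omega.size != n:
            raise StructureError("phi, psi, omega must have equal length")
        if n < 2:
            raise StructureError("need at least 2 residues")
        for v in (self.bond_n_ca, self.bond_ca_c, self.bond_c_n):
            if v <= 0:
                raise StructureError("bond lengths must be positive")
        for v in (self.angle_n_ca_c, self.angle_ca_c_n, self.angle_c_n_ca):
            if not 0.0 < v < 180.0:
                raise StructureError("bond angles must lie strictly in (0, 180)")

    def __len__(self) -> int:
        return int(self.phi.size)


def _place(a, b, c, r, theta_deg, tau_deg):
    """NeRF atom placement: bond length r to c, angle theta at c, torsion tau."""
    theta = math.radians(theta_deg)
    tau = math.radians(tau_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    # IUPAC sign convention: positive torsion is clockwise viewed b -> c
    return c + (
        -r * math.cos(theta) * bc
        + r * math.sin(theta) * math.cos(tau) * m
        - r * math.sin(theta) * math.sin(tau) * n
    )


def build_backbone(spec: InternalCoordSpec) -> BackboneChain:
    """Grow N/CA/C coordinates from prescribed internal coordinates.

    The first residue is placed canonically (N at the origin, CA on +x, C
    in the xy-plane); each further atom is placed by its bond length, bond
    angle and the prescribed torsion.  Deterministic.
    """
    n_res = len(spec)
    coords = np.empty((3 * n_res, 3))
    coords[0] = (0.0, 0.0, 0.0)
    coords[1] = (spec.bond_n_ca, 0.0, 0.0)
    ang = math.radians(spec.angle_n_ca_c)
    coords[2] = coords[1] + spec.bond_ca_c * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )
    for k in range(1, n_res):
        i = 3 * k
        n_prev, ca_prev, c_prev = coords[i - 3], coords[i - 2], coords[i - 1]
        coords[i] = _place(
            n_prev, ca_prev, c_prev, spec.bond_c_n, spec.angle_ca_c_n, spec.psi[k - 1]
        )
        coords[i + 1] = _place(
            ca_prev, c_prev, coords[i], spec.bond_n_ca, spec.angle_c_n_ca,
            spec.omega[k - 1],
        )
        coords[i + 2] = _place(
            c_prev, coords[i], coords[i + 1], spec.bond_ca_c, spec.angle_n_ca_c,
            spec.phi[k],
        )
    residues = [
        Residue(
            resnum=k + 1,
            resname=spec.resname,
            n=coords[3 * k],
            ca=coords[3 * k + 1],
            c=coords[3 * k + 2],
        )
        for k in range(n_res)
    ]
    return BackboneChain(chain_id=spec.chain_id, residues=residues)


def dihedral_records(phi, psi, omega) -> list[DihedralRecord]:
    """Dihedral records with the terminal undefined-angle pattern."""
    n = len(phi)
    recs = []
    for k in range(n):
        recs.append(
            DihedralRecord(
                index=k + 1,
                resnum=k + 1,
                resname="ALA",
                phi=float(phi[k]) if k > 0 else math.nan,
                psi=float(psi[k]) if k < n - 1 else math.nan,
                omega_prev=float(omega[k - 1]) if k > 0 else math.nan,
                omega_next=float(omega[k]) if k < n - 1 else math.nan,
            )
        )
    return recs


def random_dihedrals(
    n_res: int,
    n_sets: int,
    seed: int,
    omega_jitter: float = 10.0,
) -> list[list[DihedralRecord]]:
    """Random dihedral configurations for block-vs-full comparisons.

    phi and psi are uniform on (-180, 180]; omega is 180 plus uniform
    jitter in +-``omega_jitter`` degrees.  Deterministic given the seed.
    """
    if n_res < 3:
        raise ValueError("need n_res >= 3 for any interior residue")
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        phi = wrap_angle(rng.uniform(-180.0, 180.0, n_res))
        psi = wrap_angle(rng.uniform(-180.0, 180.0, n_res))
        omega = wrap_angle(180.0 + rng.uniform(-omega_jitter, omega_jitter, n_res))
        sets.append(dihedral_records(phi, psi, omega))
    return sets


@dataclass(frozen=True)
class StateParams:
    """Dihedral distribution of one conformational state."""

    phi_mean: float
    psi_mean: float
    phi_sd: float = 10.0
    psi_sd: float = 10.0
    omega_mean: float = 180.0
    omega_sd: float = 3.0


#: Convenience states: ideal alpha-helix and extended-strand conformations
#: at the survey mean angles of the H and E categories.
HELIX_STATE = StateParams(phi_mean=-64.70, psi_mean=-39.56)
EXTENDED_STATE = StateParams(phi_mean=-110.89, psi_mean=122.38)


def two_state_cv_trajectory(
    n_frames: int,
    state_a: StateParams = HELIX_STATE,
    state_b: StateParams = EXTENDED_STATE,
    switch_prob: float | tuple[float, float] = 0.05,
    n_res: int = 12,
    seed: int = 0,
    start_state: int = 0,
) -> tuple[list[list[DihedralRecord]], np.ndarray]:
    """Two-state Markov dihedral trajectory.

    Each frame the chain either stays in its state or switches with the
    given probability (a scalar, or (p_ab, p_ba)); within a state every
    residue's dihedrals are Gaussian around the state means, wrapped to
    (-180, 180].  Returns the per-frame dihedral records and the state
    index array.
    """
    if np.isscalar(switch_prob):
        p_ab = p_ba = float(switch_prob)
    else:
        p_ab, p_ba = (float(p) for p in switch_prob)
    for p in (p_ab, p_ba):
        if not 0.0 <= p <= 1.0:
            raise ValueError("switch probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    states = np.empty(n_frames, dtype=int)
    frames = []
    state = int(start_state)
    for f in range(n_frames):
        states[f] = state
        sp = (state_a, state_b)[state]
        phi = wrap_angle(rng.normal(sp.phi_mean, sp.phi_sd, n_res))
        psi = wrap_angle(rng.normal(sp.psi_mean, sp.psi_sd, n_res))
        omega = wrap_angle(rng.normal(sp.omega_mean, sp.omega_sd, n_res))
        frames.append(dihedral_records(phi, psi, omega))
        p = p_ab if state == 0 else p_ba
        if rng.random() < p:
            state = 1 - state
    return frames, states


def trajectory_to_chains(frames) -> list[BackboneChain]:
    """Build coordinates for each frame of a dihedral trajectory."""
    chains = []
    for recs in frames:
        phi = np.array([0.0 if math.isnan(r.phi) else r.phi for r in recs])
        psi = np.array([0.0 if math.isnan(r.psi) else r.psi for r in recs])
        omega = np.array(
            [180.0 if math.isnan(r.omega_next) else r.omega_next for r in recs]
        )
        chains.append(build_backbone(InternalCoordSpec(phi=phi, psi=psi, omega=omega)))
    return chains


def write_pdb(models, path) -> None:
    """Write backbone chains as a (multi-model) PDB file.

    ``models`` is a BackboneChain (one model), a list of BackboneChain (a
    trajectory: one single-chain model per entry), or a list of lists of
    BackboneChain (one entry per model, several chains each).
    """
    if isinstance(models, BackboneChain):
        models = [[models]]
    elif models and isinstance(models[0], BackboneChain):
        models = [[c] for c in models] if len(models) > 1 else [models]
    multi = len(models) > 1
    serial = 0
    lines = []
    for mi, chains in enumerate(models, 1):
        if isinstance(chains, BackboneChain):
            chains = [chains]
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 0
        for chain in chains:
            for res in chain.residues:
                for name, xyz in (("N", res.n), ("CA", res.ca), ("C", res.c)):
                    if xyz is None:
                        continue
                    serial += 1
                    lines.append(
                        f"ATOM  {serial:5d}  {name:<3s} {res.resname:>3s} "
                        f"{chain.chain_id:1s}{res.resnum:4d}    "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          "
                        f"{name[0]:>2s}"
                    )
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
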