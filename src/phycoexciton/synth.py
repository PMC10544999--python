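"""Synthetic data generators.

Everything the analysis modules consume can be generated here without any
quantum chemistry or molecular dynamics: nested site-energy ensembles with
known slow (inter-frame) and fast (intra-trajectory, Ornstein-Uhlenbeck)
disorder, toy bilin backbones with prescribed torsions, and small exciton
fixtures.

The ensemble defaults mirror the dual-protocol sampling layout this package
analyzes: 34 starting frames, 25 snapshots per short trajectory (850 nested
samples per pigment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import biotite.structure as struc

from .disorder import FrameEnsemble, Protocol
from .exciton import ExcitonSystem, PigmentSite, build_system
from .structure import BilinTopology, StructureModel, StructureError


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Site-energy ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OUParams:
    """Statistical model of one pigment's site-energy fluctuations.

    mean_energy : stationary mean in cm^-1
    sigma_slow : sd of the per-frame baselines (static disorder), cm^-1
    sigma_fast : stationary sd of the intra-trajectory OU process, cm^-1
    tau_c : OU correlation time, fs
    dt : snapshot spacing, fs
    """

    mean_energy: float
    sigma_slow: float = 0.0
    sigma_fast: float = 0.0
    tau_c: float = 20.0
    dt: float = 20.0

    def __post_init__(self):
        if self.sigma_slow < 0 or self.sigma_fast < 0:
            raise SynthError("disorder widths must be non-negative")
        if self.tau_c <= 0 or self.dt <= 0:
            raise SynthError("tau_c and dt must be positive")


@dataclass(frozen=True)
class EnsembleSpec:
    """Sampling layout: n_frames starting frames x n_snapshots per trajectory."""

    n_frames: int = 34
    n_snapshots: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1 or self.n_snapshots < 1:
            raise SynthError("frame and snapshot counts must be positive")

    @property
    def total_samples(self) -> int:
        return self.n_frames * self.n_snapshots


def gen_site_energy_ensemble(
    params: dict[str, OUParams], spec: EnsembleSpec = EnsembleSpec(),
    rng: np.random.Generator | None = None,
) -> tuple[FrameEnsemble, FrameEnsemble]:
    """Generate matched MD-OPT and MD-BOMD views of one synthetic ensemble.

    Per pigment: frame baselines are drawn Gaussian(mean, sigma_slow); within
    each frame an exact-discretization OU path with stationary sd sigma_fast
    and correlation time tau_c is sampled every ``dt`` fs.  The MD-OPT view
    holds the baselines (n_frames values), the MD-BOMD view all snapshots
    (n_frames * n_snapshots values).  Reproducible under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    opt_rows, bomd_rows = [], []
    for pigment_id in sorted(params):
        p = params[pigment_id]
        baselines = p.mean_energy + p.sigma_slow * rng.standard_normal(spec.n_frames)
        rho = np.exp(-p.dt / p.tau_c)
        for frame, base in enumerate(baselines):
            opt_rows.append((pigment_id, frame, np.nan, base))
            x = p.sigma_fast * rng.standard_normal()
            for snap in range(spec.n_snapshots):
                bomd_rows.append((pigment_id, frame, snap, base + x))
                x = rho * x + p.sigma_fast * np.sqrt(1.0 - rho**2) * rng.standard_normal()
    cols = ["pigment_id", "frame", "snapshot", "energy_cm1"]
    opt = FrameEnsemble(Protocol.MD_OPT, pd.DataFrame(opt_rows, columns=cols))
    bomd = FrameEnsemble(Protocol.MD_BOMD, pd.DataFrame(bomd_rows, columns=cols))
    return opt, bomd


# ---------------------------------------------------------------------------
# Toy bilin geometries
# ---------------------------------------------------------------------------

#: backbone bond length (Angstrom) and bond angle (degrees) of toy chains
TOY_BOND_LENGTH = 1.40
TOY_BOND_ANGLE = 120.0


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of the next chain atom from three predecessors."""
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    if abs(np.sin(theta)) < 1e-9:
        raise StructureError("collinear bond angle: torsion degenerate")
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise StructureError("collinear predecessors: torsion degenerate")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        -bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def toy_chain_topology(n_torsions: int, res_name: str = "BLN") -> BilinTopology:
    """Topology whose quadruples are consecutive atoms of a toy chain."""
    atoms = [f"X{i+1}" for i in range(n_torsions + 3)]
    quads = {
        f"tau{j+1}": tuple(atoms[j : j + 4]) for j in range(n_torsions)
    }
    return BilinTopology(res_name, quads)


def gen_bilin_geometry(
    torsions, topology: BilinTopology | None = None,
    bond_angles=None, min_distance: float = 1.0,
) -> tuple[StructureModel, BilinTopology]:
    """Build a chain whose measured torsions equal the request (to 1e-6 deg).

    Atoms are laid out by natural extension reference frames with fixed bond
    length/angle; sterically infeasible requests (any non-bonded pair closer
    than ``min_distance`` Angstrom) and collinear bond angles are rejected.
    """
    torsions = np.asarray(torsions, dtype=float)
    n = len(torsions)
    if topology is None:
        topology = toy_chain_topology(n)
    names = topology.torsion_names
    if len(names) != n:
        raise SynthError(
            f"{n} torsions requested but topology defines {len(names)}"
        )
    if bond_angles is None:
        bond_angles = np.full(n, TOY_BOND_ANGLE)
    bond_angles = np.asarray(bond_angles, dtype=float)

    # ordered unique atoms along the chain (consecutive quadruples overlap by 3)
    chain_atoms = list(topology.quadruples[names[0]])
    for name in names[1:]:
        quad = topology.quadruples[name]
        if quad[:3] != tuple(chain_atoms[-3:]):
            raise SynthError(
                "topology quadruples must be consecutive along one chain for "
                "geometry generation; use toy_chain_topology"
            )
        chain_atoms.append(quad[3])

    r = TOY_BOND_LENGTH
    coords = np.zeros((len(chain_atoms), 3))
    coords[1] = (r, 0.0, 0.0)
    theta0 = np.radians(TOY_BOND_ANGLE)
    coords[2] = coords[1] + r * np.array([-np.cos(theta0), np.sin(theta0), 0.0])
    for j in range(n):
        coords[j + 3] = _place_atom(
            coords[j], coords[j + 1], coords[j + 2], r, bond_angles[j], torsions[j]
        )

    # steric feasibility: all pairs separated by >= 3 bonds
    for i in range(len(coords)):
        for j in range(i + 3, len(coords)):
            if np.linalg.norm(coords[i] - coords[j]) < min_distance:
                raise SynthError(
                    f"infeasible torsion set: atoms {chain_atoms[i]} and "
                    f"{chain_atoms[j]} clash"
                )

    atoms = struc.AtomArray(len(chain_atoms))
    atoms.coord = coords
    atoms.chain_id[:] = "A"
    atoms.res_id[:] = 1
    atoms.res_name[:] = topology.res_name
    atoms.atom_name[:] = chain_atoms
    atoms.element[:] = "C"
    atoms.hetero[:] = True
    # AtomArray coordinates are float32; keep a float64 frame so measured
    # torsions reproduce the request to well below 1e-6 degrees
    return StructureModel(atoms=atoms, frames=coords[None]), topology


# ---------------------------------------------------------------------------
# Exciton fixtures
# ---------------------------------------------------------------------------

def gen_dimer_fixture(
    gap: float = 0.0, coupling: float = 238.0, geometry: str = "parallel",
    mean_energy: float = 15000.0, separation: float = 10.0,
) -> ExcitonSystem:
    """Two-site fixture with a chosen dipole geometry.

    geometries: ``parallel`` (H-aggregate couplet), ``chiral`` (perpendicular
    dipoles offset along z, giving a bisignate CD couplet), ``uncoupled``
    (parallel dipoles, coupling forced to zero).
    """
    if geometry == "parallel":
        d1, d2 = (1.0, 0.0, 0.0), (1.0, 0.0, 0.0)
    elif geometry == "chiral":
        d1, d2 = (1.0, 0.0, 0.0), (0.0, 1.0, 0.0)
    elif geometry == "uncoupled":
        d1, d2 = (1.0, 0.0, 0.0), (1.0, 0.0, 0.0)
        coupling = 0.0
    else:
        raise SynthError(f"unknown dimer geometry {geometry!r}")
    sites = [
        PigmentSite("site_1", mean_energy - 0.5 * gap, d1, (0.0, 0.0, 0.0)),
        PigmentSite("site_2", mean_energy + 0.5 * gap, d2, (0.0, 0.0, separation)),
    ]
    return build_system(sites, [[0.0, coupling], [coupling, 0.0]])


def gen_pc645_like_system() -> ExcitonSystem:
    """Synthetic eight-pigment closed-antenna fixture.

    Composition mirrors a closed phycocyanin (2 DBV + 2 MBV + 4 PCB) with a
    strongly coupled central DBV pair (238 cm^-1) and a weak 16 cm^-1
    peripheral contact; energies, dipoles and geometry are invented but
    plausible.  Deterministic.
    """
    layout = [
        # id, type, chain, energy, dipole direction, center
        ("DBV_50/61B", "DBV", "B", 16900.0, (1.0, 0.1, 0.0), (0.0, 0.0, 0.0)),
        ("DBV_50/61D", "DBV", "D", 16950.0, (0.2, 1.0, 0.3), (4.0, 3.0, 1.0)),
        ("MBV_19A", "MBV", "A", 15800.0, (0.8, -0.5, 0.2), (18.0, 5.0, -6.0)),
        ("MBV_19C", "MBV", "C", 15850.0, (-0.4, 0.9, 0.1), (-17.0, -4.0, 7.0)),
        ("PCB_82B", "PCB", "B", 16150.0, (0.6, 0.6, -0.5), (10.0, -12.0, 3.0)),
        ("PCB_82D", "PCB", "D", 16100.0, (-0.7, 0.4, 0.6), (-9.0, 13.0, -2.0)),
        ("PCB_158B", "PCB", "B", 16350.0, (0.1, -0.8, 0.6), (22.0, 14.0, 9.0)),
        ("PCB_158D", "PCB", "D", 16300.0, (0.9, 0.3, -0.3), (-21.0, -15.0, -8.0)),
    ]
    sites = []
    for sid, btype, chain, energy, direction, center in layout:
        d = np.asarray(direction, float)
        d = 12.8 * d / np.linalg.norm(d)  # ~bilin-sized dipole in Debye
        sites.append(PigmentSite(sid, energy, tuple(d), center, btype, chain))
    n = len(sites)
    V = np.zeros((n, n))
    V[0, 1] = 238.0                      # central strongly coupled pair
    V[2, 6] = 16.0                       # weak peripheral contact
    weak = {(0, 4): 35.0, (1, 5): -32.0, (0, 2): 21.0, (1, 3): -19.0,
            (4, 6): 12.0, (5, 7): -11.0, (2, 4): 9.0, (3, 5): 8.0}
    for (i, j), v in weak.items():
        V[i, j] = v
    V = V + V.T
    return build_system(sites, V)


def gen_random_system(
    n_sites: int, rng: np.random.Generator,
    energy_center: float = 15500.0, energy_spread: float = 400.0,
    coupling_scale: float = 100.0, box: float = 30.0,
) -> ExcitonSystem:
    """Random N-site system for property tests (dipoles, centers, couplings)."""
    energies = energy_center + energy_spread * rng.standard_normal(n_sites)
    dipoles = rng.normal(size=(n_sites, 3))
    centers = box * rng.random((n_sites, 3))
    V = coupling_scale * rng.standard_normal((n_sites, n_sites))
    V = 0.5 * (V + V.T)
    np.fill_diagonal(V, 0.0)
    sites = [
        PigmentSite(f"site_{i+1}", float(energies[i]), tuple(dipoles[i]),
                    tuple(centers[i]))
        for i in range(n_sites)
    ]
    return build_system(sites, V)
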