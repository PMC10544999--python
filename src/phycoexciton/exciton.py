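"""Frenkel exciton Hamiltonian: assembly, diagonalization and state properties.

The Hamiltonian of N interacting chromophores is built from site excitation
energies ``eps_n`` (diagonal, cm^-1) and electronic couplings ``V_nm``
(off-diagonal, cm^-1).  Diagonalization yields exciton states
``|k> = sum_n C_nk |n>`` with energies ``eps_k``, from which per-state dipole
strengths, rotational strengths (point-dipole exciton CD) and inverse
participation ratios are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

BILIN_TYPES = ("PCB", "DBV", "MBV", "PEB")

#: maximum tolerated asymmetry (cm^-1) before an input coupling matrix is rejected
SYMMETRY_TOLERANCE = 1e-6


class ExcitonError(ValueError):
    """Raised on invalid exciton-system input."""


@dataclass(frozen=True)
class PigmentSite:
    """A single chromophore site.

    Parameters
    ----------
    site_id : unique label, e.g. ``"DBV_50/61B"``.
    bilin_type : one of ``PCB, DBV, MBV, PEB`` (or any label for toy systems).
    energy : site excitation energy in cm^-1.
    dipole : transition dipole vector in Debye.
    center : pigment center in Angstrom (used for rotational strengths).
    chain : chain label.
    """

    site_id: str
    energy: float
    dipole: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bilin_type: str = "PCB"
    chain: str = ""

    def __post_init__(self):
        if not np.isfinite(self.energy):
            raise ExcitonError(f"non-finite energy for site {self.site_id!r}")
        object.__setattr__(self, "dipole", tuple(float(x) for x in self.dipole))
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))


@dataclass(frozen=True)
class ExcitonSystem:
    """Validated multichromophoric system: sites plus symmetric coupling matrix."""

    sites: tuple[PigmentSite, ...]
    couplings: np.ndarray  # (N, N) cm^-1, symmetric, zero diagonal

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.sites], dtype=float)

    @property
    def dipoles(self) -> np.ndarray:
        return np.array([s.dipole for s in self.sites], dtype=float)

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.sites], dtype=float)

    def hamiltonian(self) -> np.ndarray:
        """Dense N x N Hamiltonian in cm^-1."""
        return np.diag(self.energies) + self.couplings

    def with_energies(self, energies: Sequence[float]) -> "ExcitonSystem":
        """Copy of the system with replaced site energies (couplings untouched)."""
        energies = np.asarray(energies, dtype=float)
        if energies.shape != (self.n_sites,):
            raise ExcitonError("energy vector length does not match system size")
        sites = tuple(
            PigmentSite(s.site_id, float(e), s.dipole, s.center, s.bilin_type, s.chain)
            for s, e in zip(self.sites, energies)
        )
        return ExcitonSystem(sites=sites, couplings=self.couplings)

    def with_couplings_scaled(self, factor: float) -> "ExcitonSystem":
        return ExcitonSystem(sites=self.sites, couplings=self.couplings * factor)


@dataclass(frozen=True)
class ExcitonStates:
    """Result of diagonalizing an :class:`ExcitonSystem`.

    ``coefficients[:, k]`` holds the site amplitudes ``C_nk`` of state k.
    States are sorted by ascending energy; degenerate pairs are ordered by
    descending dipole strength so output is reproducible.
    """

    energies: np.ndarray              # (N,) cm^-1, ascending
    coefficients: np.ndarray          # (N, N), orthonormal columns
    dipole_strengths: np.ndarray      # (N,) Debye^2
    rotational_strengths: np.ndarray  # (N,) Debye^2 * Angstrom (unit prefactor)
    participation: np.ndarray         # (N,) inverse participation ratio, in [1, N]
    exciton_dipoles: np.ndarray = field(default=None)  # (N, 3) Debye

    @property
    def n_states(self) -> int:
        return len(self.energies)


def build_system(sites: Sequence[PigmentSite], couplings) -> ExcitonSystem:
    """Validate sites and couplings and assemble an :class:`ExcitonSystem`.

    Nearly-symmetric matrices (max asymmetry < ``SYMMETRY_TOLERANCE`` cm^-1)
    are symmetrized; anything worse is rejected.  The diagonal is forced to
    exactly zero (site energies live on the sites, not in the matrix).
    """
    sites = tuple(sites)
    if len(sites) < 1:
        raise ExcitonError("need at least one site")
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ExcitonError(f"duplicate site_id(s): {dupes}")

    V = np.array(couplings, dtype=float)
    n = len(sites)
    if V.shape != (n, n):
        raise ExcitonError(
            f"coupling matrix shape {V.shape} does not match {n} sites"
        )
    asym = np.max(np.abs(V - V.T)) if n > 1 else 0.0
    if asym >= SYMMETRY_TOLERANCE:
        raise ExcitonError(
            f"coupling matrix is not symmetric (max asymmetry {asym:.3g} cm^-1)"
        )
    V = 0.5 * (V + V.T)
    np.fill_diagonal(V, 0.0)
    V.flags.writeable = False
    return ExcitonSystem(sites=sites, couplings=V)


def diagonalize(system: ExcitonSystem) -> ExcitonStates:
    """Diagonalize the exciton Hamiltonian and attach state properties.

    Sign convention: the largest-magnitude coefficient of each state is made
    positive.  Degenerate eigenvalues are ordered by descending dipole
    strength.
    """
    H = system.hamiltonian()
    evals, evecs = np.linalg.eigh(H)  # ascending

    # fix signs
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]

    mu = system.dipoles
    exc_mu = evecs.T @ mu                       # (N, 3)
    D = np.einsum("ki,ki->k", exc_mu, exc_mu)   # |mu_k|^2

    # break degenerate ties by descending D_k
    order = np.lexsort((-D, np.round(evals, 9)))
    evals, evecs, exc_mu, D = evals[order], evecs[:, order], exc_mu[order], D[order]

    R = _rotational_strengths(evecs, system)
    ipr = participation_ratio(evecs)

    return ExcitonStates(
        energies=evals,
        coefficients=evecs,
        dipole_strengths=D,
        rotational_strengths=R,
        participation=ipr,
        exciton_dipoles=exc_mu,
    )


def dipole_strengths(states: ExcitonStates, system: ExcitonSystem) -> np.ndarray:
    """Per-state dipole strengths D_k = |sum_n C_nk mu_n|^2 in Debye^2."""
    exc_mu = states.coefficients.T @ system.dipoles
    return np.einsum("ki,ki->k", exc_mu, exc_mu)


def _rotational_strengths(coefficients: np.ndarray, system: ExcitonSystem) -> np.ndarray:
    """Point-dipole exciton rotational strengths, unit prefactor.

    R_k = sum_{n<m} C_nk C_mk (R_nm . (mu_n x mu_m)),  R_nm = r_n - r_m.
    The pairwise scalar is antisymmetric-free under n<->m, so sum_k R_k = 0
    follows from orthonormality of the coefficients.
    """
    mu = system.dipoles
    r = system.centers
    n = system.n_sites
    cross = np.cross(mu[:, None, :], mu[None, :, :])        # (n, n, 3)
    sep = r[:, None, :] - r[None, :, :]                     # (n, n, 3)
    pair = np.einsum("nmi,nmi->nm", sep, cross)             # (n, n)
    iu = np.triu_indices(n, k=1)
    R = np.empty(coefficients.shape[1])
    for k in range(coefficients.shape[1]):
        c = coefficients[:, k]
        R[k] = np.sum(c[iu[0]] * c[iu[1]] * pair[iu])
    return R


def rotational_strengths(states: ExcitonStates, system: ExcitonSystem) -> np.ndarray:
    """Per-state rotational strengths (Debye^2 * Angstrom, unit prefactor)."""
    if system.centers is None:
        raise ExcitonError("pigment centers are required for rotational strengths")
    return _rotational_strengths(states.coefficients, system)


def participation_ratio(coefficients: np.ndarray) -> np.ndarray:
    """Inverse participation ratio per state: (sum_n C_nk^4)^-1, in [1, N]."""
    c = np.asarray(coefficients)
    return 1.0 / np.sum(c**4, axis=0)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def system_to_dict(system: ExcitonSystem) -> dict:
    return {
        "sites": [
            {
                "id": s.site_id,
                "type": s.bilin_type,
                "energy_cm1": s.energy,
                "dipole_D": list(s.dipole),
                "center_A": list(s.center),
                "chain": s.chain,
            }
            for s in system.sites
        ],
        "couplings_cm1": [list(map(float, row)) for row in system.couplings],
    }


def system_from_dict(data: dict) -> ExcitonSystem:
    sites = [
        PigmentSite(
            site_id=d["id"],
            energy=float(d["energy_cm1"]),
            dipole=tuple(d.get("dipole_D", (0, 0, 0))),
            center=tuple(d.get("center_A", (0, 0, 0))),
            bilin_type=d.get("type", "PCB"),
            chain=d.get("chain", ""),
        )
        for d in data["sites"]
    ]
    return build_system(sites, np.array(data["couplings_cm1"], dtype=float))


def write_system(system: ExcitonSystem, path) -> None:
    Path(path).write_text(json.dumps(system_to_dict(system), indent=1))


def read_system(path) -> ExcitonSystem:
    return system_from_dict(json.loads(Path(path).read_text()))


def write_system_csv(system: ExcitonSystem, sites_path, couplings_path) -> None:
    """CSV alternative: a sites table plus a square coupling table."""
    import pandas as pd

    pd.DataFrame([
        {
            "id": s.site_id, "type": s.bilin_type, "chain": s.chain,
            "energy_cm1": s.energy,
            "dipole_x_D": s.dipole[0], "dipole_y_D": s.dipole[1], "dipole_z_D": s.dipole[2],
            "center_x_A": s.center[0], "center_y_A": s.center[1], "center_z_A": s.center[2],
        }
        for s in system.sites
    ]).to_csv(sites_path, index=False)
    ids = [s.site_id for s in system.sites]
    pd.DataFrame(system.couplings, index=ids, columns=ids).to_csv(couplings_path)


def read_system_csv(sites_path, couplings_path) -> ExcitonSystem:
    import pandas as pd

    sites_df = pd.read_csv(sites_path)
    sites = [
        PigmentSite(
            site_id=row["id"], energy=float(row["energy_cm1"]),
            dipole=(row["dipole_x_D"], row["dipole_y_D"], row["dipole_z_D"]),
            center=(row["center_x_A"], row["center_y_A"], row["center_z_A"]),
            bilin_type=row.get("type", "PCB"), chain=str(row.get("chain", "") or ""),
        )
        for _, row in sites_df.iterrows()
    ]
    coup = pd.read_csv(couplings_path, index_col=0)
    ids = [s.site_id for s in sites]
    if list(coup.index) != ids or list(coup.columns) != ids:
        raise ExcitonError("coupling table labels do not match the sites table")
    return build_system(sites, coup.to_numpy(dtype=float))
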