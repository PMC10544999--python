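"""Structural analysis of bilin pigments and phycobiliprotein chains.

Covers the inter-ring torsions tau1..tau6 of the linear tetrapyrroles (with
circular statistics for frame ensembles), per-atom/per-residue RMSF after
least-squares superposition, and the rigid-body rotation angle relating the
two alpha-beta protomers of open vs closed complexes.

Torsions are reported on the branch (-90, 270] degrees: near-anti bridges
come out around 170..200 instead of wrapping at +-180, matching how twisted
bilin backbones are usually tabulated.

PDB reading is backed by biotite; each bilin ligand's torsion atom quadruples
ship as an editable JSON table (``data/bilin_topology.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

#: lower branch edge in degrees; angles are mapped to (BRANCH_MIN, BRANCH_MIN + 360]
BRANCH_MIN = -90.0


def to_branch(angle_deg):
    """Map angle(s) in degrees onto the branch (-90, 270]."""
    a = np.asarray(angle_deg, dtype=float)
    out = np.mod(a - BRANCH_MIN, 360.0) + BRANCH_MIN
    out = np.where(np.isclose(out, BRANCH_MIN), BRANCH_MIN + 360.0, out)
    return float(out) if np.isscalar(angle_deg) or out.ndim == 0 else out


def dihedral_angle(p0, p1, p2, p3) -> float:
    """IUPAC signed dihedral in degrees, mapped to the (-90, 270] branch."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm = np.linalg.norm
    if norm(n1) < 1e-8 * norm(b0) * norm(b1) or norm(n2) < 1e-8 * norm(b1) * norm(b2):
        raise StructureError("collinear atom triple: dihedral undefined")
    m1 = np.cross(n1, b1 / norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return to_branch(np.degrees(np.arctan2(y, x)))


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid fit: returns (R, t) with R @ mobile.T + t ~ reference.

    Proper rotation (det +1) via SVD sign correction.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def rotation_angle_from_matrix(R: np.ndarray) -> float:
    """Rotation angle in degrees from the matrix trace, in [0, 180]."""
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_theta)))


def circular_mean_sd(angles_deg) -> tuple[float, float]:
    """Circular mean (on the (-90, 270] branch) and circular sd in degrees.

    sd is sqrt(-2 ln Rbar) converted to degrees; it reduces to the linear sd
    for narrow distributions and is immune to the branch cut.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise StructureError("no angles")
    z = np.exp(1j * a)
    mean = np.angle(np.mean(z))
    rbar = np.abs(np.mean(z))
    rbar = min(rbar, 1.0)
    sd = np.sqrt(max(-2.0 * np.log(rbar), 0.0)) if rbar > 0 else np.inf
    return to_branch(np.degrees(mean)), float(np.degrees(sd))


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Atom table plus one or more coordinate frames.

    ``atoms`` is a biotite AtomArray (first frame's coordinates); ``frames``
    is a (n_frames, n_atoms, 3) array sharing the atom ordering.
    """

    atoms: struc.AtomArray
    frames: np.ndarray | None = None

    def __post_init__(self):
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=float)
            if self.frames.ndim != 3 or self.frames.shape[1] != len(self.atoms):
                raise StructureError("frames must be (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return 1 if self.frames is None else len(self.frames)

    def ligands(self, names=("CYC", "DBV", "MBV", "PEB")) -> list[tuple[str, int, str]]:
        """(chain, residue number, residue name) of each bilin ligand."""
        a = self.atoms
        mask = np.isin(a.res_name, list(names))
        out = []
        seen = set()
        for ch, ri, rn in zip(a.chain_id[mask], a.res_id[mask], a.res_name[mask]):
            key = (str(ch), int(ri), str(rn))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return sorted(out)

    def ligand_counts(self, names=("CYC", "DBV", "MBV", "PEB")) -> dict:
        counts: dict[str, int] = {}
        for _, _, rn in self.ligands(names):
            counts[rn] = counts.get(rn, 0) + 1
        return counts

    def select(self, chain=None, res_id=None, res_name=None, atom_names=None) -> np.ndarray:
        a = self.atoms
        mask = np.ones(len(a), dtype=bool)
        if chain is not None:
            mask &= a.chain_id == chain
        if res_id is not None:
            mask &= a.res_id == res_id
        if res_name is not None:
            mask &= a.res_name == res_name
        if atom_names is not None:
            mask &= np.isin(a.atom_name, list(atom_names))
        return np.where(mask)[0]

    def coords(self, frame: int = 0) -> np.ndarray:
        if self.frames is None:
            if frame != 0:
                raise StructureError("single-frame structure")
            return self.atoms.coord
        return self.frames[frame]

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        a = self.atoms.copy()
        a.coord = a.coord @ R.T + t
        frames = None if self.frames is None else self.frames @ R.T + t
        return StructureModel(atoms=a, frames=frames)


def read_structure(path, model: int | None = None) -> StructureModel:
    """Read a PDB file; multi-MODEL files become trajectory frames.

    Malformed coordinate records are reported with their line number.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        count = pdb.get_model_count()
        if model is not None or count == 1:
            atoms = pdb.get_structure(model=model or 1)
            return StructureModel(atoms=atoms)
        stack = pdb.get_structure()
        template = stack[0]
        return StructureModel(atoms=template, frames=stack.coord)
    except Exception as exc:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    raise StructureError(
                        f"{path}: malformed coordinate record at line {lineno}: {line!r}"
                    ) from exc
        raise StructureError(f"{path}: could not parse PDB file: {exc}") from exc


def write_structure(model: StructureModel, path) -> None:
    pdb = PDBFile()
    if model.frames is None or model.n_frames == 1:
        pdb.set_structure(model.atoms)
    else:
        stack = struc.from_template(model.atoms, model.frames)
        pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Torsion topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BilinTopology:
    """Ordered torsion-name -> atom-quadruple table for one ligand type."""

    res_name: str
    quadruples: dict[str, tuple[str, str, str, str]]

    def __post_init__(self):
        object.__setattr__(
            self, "quadruples",
            {k: tuple(v) for k, v in self.quadruples.items()},
        )
        for name, quad in self.quadruples.items():
            if len(quad) != 4 or len(set(quad)) != 4:
                raise StructureError(f"{self.res_name}/{name}: need 4 distinct atoms")
        names = self.torsion_names
        # the two torsions of one methine bridge share the three bridge atoms
        for i in range(0, len(names) - 1, 2):
            a, b = self.quadruples[names[i]], self.quadruples[names[i + 1]]
            if a[1:] != b[:3]:
                raise StructureError(
                    f"{self.res_name}: {names[i]}/{names[i+1]} do not share the "
                    "inter-ring bridge atoms"
                )

    @property
    def torsion_names(self) -> list[str]:
        return sorted(self.quadruples, key=lambda s: int(s.replace("tau", "")))


def default_topologies() -> dict[str, BilinTopology]:
    """Shipped topology table (editable JSON in package data)."""
    text = resources.files("phycoexciton").joinpath("data/bilin_topology.json").read_text()
    raw = json.loads(text)
    return {name: BilinTopology(name, quads) for name, quads in raw.items()}


def load_topologies(path) -> dict[str, BilinTopology]:
    raw = json.loads(Path(path).read_text())
    return {name: BilinTopology(name, quads) for name, quads in raw.items()}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def torsion(
    model: StructureModel, quadruple, chain=None, res_id=None, res_name=None,
    frame: int = 0,
) -> float:
    """Dihedral (degrees, (-90, 270] branch) over a named atom quadruple."""
    idx = []
    for name in quadruple:
        sel = model.select(chain=chain, res_id=res_id, res_name=res_name,
                           atom_names=[name])
        if len(sel) != 1:
            raise StructureError(
                f"atom {name!r} matched {len(sel)} times "
                f"(chain={chain}, res_id={res_id}, res_name={res_name})"
            )
        idx.append(sel[0])
    xyz = model.coords(frame)
    return dihedral_angle(*(xyz[i] for i in idx))


def ligand_torsions(
    model: StructureModel, topology: BilinTopology, chain=None, res_id=None,
    frame: int = 0,
) -> dict[str, float]:
    """All tabulated torsions of one bilin ligand."""
    return {
        name: torsion(model, quad, chain=chain, res_id=res_id,
                      res_name=topology.res_name, frame=frame)
        for name, quad in topology.quadruples.items()
    }


@dataclass(frozen=True)
class TorsionSeries:
    """Per-frame torsions of one pigment plus circular statistics."""

    pigment_id: str
    torsion_names: tuple[str, ...]
    angles: np.ndarray          # (n_frames, n_torsions), degrees on the branch
    mean: np.ndarray            # circular mean per torsion
    sd: np.ndarray              # circular sd per torsion

    def summary(self) -> str:
        parts = [
            f"{n}={m:.0f} +/- {s:.0f}"
            for n, m, s in zip(self.torsion_names, self.mean, self.sd)
        ]
        return f"{self.pigment_id}: " + ", ".join(parts)


def torsion_stats(
    model: StructureModel, topology: BilinTopology, chain=None, res_id=None,
    pigment_id: str | None = None,
) -> TorsionSeries:
    """Circular mean/sd of each torsion over all frames of a trajectory."""
    names = tuple(topology.torsion_names)
    angles = np.empty((model.n_frames, len(names)))
    for f in range(model.n_frames):
        for j, name in enumerate(names):
            angles[f, j] = torsion(model, topology.quadruples[name], chain=chain,
                                   res_id=res_id, res_name=topology.res_name, frame=f)
    stats = [circular_mean_sd(angles[:, j]) for j in range(len(names))]
    return TorsionSeries(
        pigment_id=pigment_id or f"{topology.res_name}_{chain}{res_id}",
        torsion_names=names,
        angles=angles,
        mean=np.array([m for m, _ in stats]),
        sd=np.array([s for _, s in stats]),
    )


def ligand_near_residue(
    model: StructureModel, res_name: str, chain: str, res_id: int,
    atom_name: str = "SG",
) -> tuple[str, int]:
    """Ligand instance of ``res_name`` closest to a given residue atom.

    Used to resolve e.g. "the MBV bonded to Cys19 of chain A": returns the
    (chain, residue number) of the nearest matching ligand.
    """
    anchor = model.select(chain=chain, res_id=res_id, atom_names=[atom_name])
    if len(anchor) != 1:
        raise StructureError(
            f"anchor atom {atom_name!r} of {chain}/{res_id} matched {len(anchor)} atoms"
        )
    anchor_xyz = model.atoms.coord[anchor[0]]
    best, best_d = None, np.inf
    for lig_chain, lig_res, lig_name in model.ligands(names=(res_name,)):
        sel = model.select(chain=lig_chain, res_id=lig_res, res_name=lig_name)
        d = float(np.min(np.linalg.norm(model.atoms.coord[sel] - anchor_xyz, axis=1)))
        if d < best_d:
            best, best_d = (lig_chain, lig_res), d
    if best is None:
        raise StructureError(f"no {res_name!r} ligand in structure")
    return best


def superpose_frames(frames: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Least-squares superpose every frame onto the iteratively refined mean."""
    frames = np.array(frames, dtype=float)
    if len(frames) < 2:
        raise StructureError("need at least two frames")
    reference = frames[0]
    for _ in range(n_iter):
        aligned = np.empty_like(frames)
        for i, fr in enumerate(frames):
            R, t = kabsch(fr, reference)
            aligned[i] = fr @ R.T + t
        reference = aligned.mean(axis=0)
        frames = aligned
    return frames


def rmsf(model: StructureModel, selection: np.ndarray | None = None) -> np.ndarray:
    """Per-atom RMSF (Angstrom) after superposition on the mean structure.

    RMSF_i = sqrt(<|x_i - <x_i>|^2>) over frames; invariant under any global
    rigid motion applied to individual frames.
    """
    if model.frames is None or model.n_frames < 2:
        raise StructureError("RMSF needs at least two frames")
    coords = model.frames if selection is None else model.frames[:, selection, :]
    aligned = superpose_frames(coords)
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))


def rmsf_per_residue(model: StructureModel, chain: str) -> "pd.DataFrame":
    """C-alpha RMSF per residue of one chain."""
    import pandas as pd

    sel = model.select(chain=chain, atom_names=["CA"])
    if len(sel) == 0:
        raise StructureError(f"no C-alpha atoms in chain {chain!r}")
    values = rmsf(model, sel)
    return pd.DataFrame({
        "chain": chain,
        "res_id": model.atoms.res_id[sel],
        "rmsf_A": values,
    })


def _matched_ca(ref: StructureModel, mob: StructureModel, chain_pairs):
    """Coordinates of C-alpha atoms shared (by residue number) between models."""
    ref_xyz, mob_xyz = [], []
    for ref_chain, mob_chain in chain_pairs:
        r_sel = ref.select(chain=ref_chain, atom_names=["CA"])
        m_sel = mob.select(chain=mob_chain, atom_names=["CA"])
        r_ids = {int(i): k for i, k in zip(ref.atoms.res_id[r_sel], r_sel)}
        m_ids = {int(i): k for i, k in zip(mob.atoms.res_id[m_sel], m_sel)}
        common = sorted(set(r_ids) & set(m_ids))
        if not common:
            raise StructureError(
                f"no shared residues between chains {ref_chain!r} and {mob_chain!r}"
            )
        ref_xyz.append(ref.atoms.coord[[r_ids[i] for i in common]])
        mob_xyz.append(mob.atoms.coord[[m_ids[i] for i in common]])
    return np.concatenate(ref_xyz), np.concatenate(mob_xyz)


def protomer_rotation_angle(
    reference: StructureModel,
    mobile: StructureModel,
    protomer1_pairs,
    protomer2_pairs,
) -> float:
    """Rotation angle (degrees) relating the second protomers after the first
    protomers are superposed.

    ``protomer1_pairs`` / ``protomer2_pairs`` are sequences of
    ``(reference_chain, mobile_chain)`` pairs; C-alpha atoms are matched by
    residue number within each chain pair.  Identical arrangements give 0.
    """
    ref1, mob1 = _matched_ca(reference, mobile, protomer1_pairs)
    R1, t1 = kabsch(mob1, ref1)
    mobile_fit = mobile.transformed(R1, t1)
    ref2, mob2 = _matched_ca(reference, mobile_fit, protomer2_pairs)
    R2, _ = kabsch(mob2, ref2)
    return rotation_angle_from_matrix(R2)
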