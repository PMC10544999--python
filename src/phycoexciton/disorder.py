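"""Site-energy ensembles, static-disorder estimators and disorder averaging.

Two estimators mirror the two sampling protocols:

* ``disorder_from_opt`` -- sample standard deviation over the per-frame
  optimized energies (one value per starting frame).
* ``disorder_from_bomd`` -- standard deviation across per-trajectory means
  (each trajectory mean taken over its snapshots).  With fast intra-trajectory
  fluctuations of width sigma_f this estimator is inflated to
  ``sqrt(sigma_slow^2 + sigma_f^2 / n_snapshots)``.

Monte-Carlo static disorder: independent Gaussian perturbations of the site
energies (couplings untouched), spectra averaged over realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .exciton import ExcitonSystem
from .lineshape import SpectrumResult, homogeneous_spectra


class DisorderError(ValueError):
    pass


class Protocol(str, Enum):
    MD = "MD"
    CRYSTAL_OPT = "Crystal-OPT"
    MD_OPT = "MD-OPT"
    MD_BOMD = "MD-BOMD"


@dataclass(frozen=True)
class FrameEnsemble:
    """Nested per-pigment site-energy samples (long format).

    ``data`` has columns ``pigment_id, frame, snapshot, energy_cm1``;
    ``snapshot`` is NaN for flat (per-frame) protocols.
    """

    protocol: Protocol
    data: pd.DataFrame

    def __post_init__(self):
        required = {"pigment_id", "frame", "energy_cm1"}
        if not required.issubset(self.data.columns):
            raise DisorderError(f"ensemble table must have columns {sorted(required)}")
        if "snapshot" not in self.data.columns:
            df = self.data.copy()
            df["snapshot"] = np.nan
            object.__setattr__(self, "data", df)
        counts = self.data.groupby("pigment_id").size()
        if counts.nunique() > 1:
            raise DisorderError(
                "ragged ensemble: sample counts differ across pigments "
                f"({dict(counts)})"
            )

    @property
    def pigments(self) -> list[str]:
        return sorted(self.data["pigment_id"].unique())

    @property
    def n_samples_per_pigment(self) -> int:
        return int(self.data.groupby("pigment_id").size().iloc[0])

    def energies(self, pigment_id: str) -> np.ndarray:
        sub = self.data[self.data["pigment_id"] == pigment_id]
        return sub["energy_cm1"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df.insert(0, "protocol", self.protocol.value)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrameEnsemble":
        df = pd.read_csv(path)
        protocols = df["protocol"].unique()
        if len(protocols) != 1:
            raise DisorderError(f"mixed protocols in {path}: {protocols}")
        proto = Protocol(protocols[0])
        return cls(protocol=proto, data=df.drop(columns=["protocol"]))


@dataclass(frozen=True)
class DisorderModel:
    """Gaussian static disorder: per-site (or common) sigma in cm^-1."""

    sigma: float | np.ndarray
    n_realizations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.sigma) < 0):
            raise DisorderError("sigma must be non-negative")
        if self.n_realizations < 1:
            raise DisorderError("need at least one realization")


@dataclass(frozen=True)
class SiteStatistics:
    """Per-pigment mean / sample sd (ddof=1) / count for one protocol."""

    protocol: Protocol
    table: pd.DataFrame  # columns: pigment_id, mean_cm1, sd_cm1, count

    def mean(self, pigment_id: str) -> float:
        return float(self.table.set_index("pigment_id").loc[pigment_id, "mean_cm1"])

    def sd(self, pigment_id: str) -> float:
        return float(self.table.set_index("pigment_id").loc[pigment_id, "sd_cm1"])


def ensemble_site_statistics(ensemble: FrameEnsemble) -> SiteStatistics:
    """Mean and sample sd per pigment over all samples (nested sets flattened)."""
    if len(ensemble.data) == 0:
        raise DisorderError("empty ensemble")
    grouped = ensemble.data.groupby("pigment_id")["energy_cm1"]
    table = pd.DataFrame({
        "pigment_id": grouped.mean().index,
        "mean_cm1": grouped.mean().to_numpy(),
        "sd_cm1": grouped.std(ddof=1).fillna(0.0).to_numpy(),
        "count": grouped.size().to_numpy(),
    })
    return SiteStatistics(protocol=ensemble.protocol, table=table)


def disorder_from_opt(ensemble: FrameEnsemble) -> pd.Series:
    """Static disorder as the sample sd over per-frame optimized energies."""
    if ensemble.protocol is not Protocol.MD_OPT:
        raise DisorderError(
            f"disorder_from_opt requires an MD-OPT ensemble, got {ensemble.protocol.value}"
        )
    out = ensemble.data.groupby("pigment_id")["energy_cm1"].std(ddof=1)
    return out.fillna(0.0).rename("sigma_cm1")


def disorder_from_bomd(ensemble: FrameEnsemble) -> pd.Series:
    """Static disorder as the sd across per-trajectory mean energies.

    Each of the starting frames carries one short trajectory; the mean over
    its snapshots retains a residual fast-fluctuation variance of
    sigma_fast^2 / n_snapshots, so this estimator is biased upward for short
    runs.
    """
    if ensemble.protocol is not Protocol.MD_BOMD:
        raise DisorderError(
            f"disorder_from_bomd requires an MD-BOMD ensemble, got {ensemble.protocol.value}"
        )
    means = ensemble.data.groupby(["pigment_id", "frame"])["energy_cm1"].mean()
    out = means.groupby("pigment_id").std(ddof=1)
    return out.fillna(0.0).rename("sigma_cm1")


# ---------------------------------------------------------------------------
# Monte-Carlo disorder
# ---------------------------------------------------------------------------

def sample_realizations(
    system: ExcitonSystem, model: DisorderModel, rng: np.random.Generator | None = None,
):
    """Yield systems with independently Gaussian-perturbed site energies."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    sigma = np.broadcast_to(np.asarray(model.sigma, dtype=float), (system.n_sites,))
    base = system.energies
    for _ in range(model.n_realizations):
        yield system.with_energies(base + rng.normal(0.0, 1.0, system.n_sites) * sigma)


def disorder_averaged_spectrum(
    system: ExcitonSystem,
    model: DisorderModel,
    lineshapes,
    theory: str = "modified_redfield",
    temperature: float = 300.0,
    wavenumber_grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SpectrumResult:
    """OD/CD/FLU averaged over Gaussian site-energy realizations.

    Deterministic for a fixed model seed (or caller-provided generator).  For
    a monomer this converges to the homogeneous spectrum convolved with a
    Gaussian of width sigma.
    """
    from .lineshape import default_wavenumber_grid

    if wavenumber_grid is None:
        margin = 3000.0 + 4.0 * float(np.max(model.sigma))
        wavenumber_grid = default_wavenumber_grid(system, margin=margin)
    acc = {"od": 0.0, "cd": 0.0, "flu": 0.0}
    n = 0
    for realization in sample_realizations(system, model, rng):
        res = homogeneous_spectra(
            realization, lineshapes, theory=theory, temperature=temperature,
            wavenumber_grid=wavenumber_grid,
        )
        for name, arr in res.channels().items():
            acc[name] = acc[name] + arr
        n += 1
    return SpectrumResult(
        wavenumber=np.asarray(wavenumber_grid, float),
        od=acc["od"] / n, cd=acc["cd"] / n, flu=acc["flu"] / n,
        metadata={
            "theory": theory, "temperature_K": temperature,
            "sigma_cm1": float(np.max(model.sigma)), "n_realizations": n,
            "seed": model.seed,
        },
    )


# ---------------------------------------------------------------------------
# Peak alignment
# ---------------------------------------------------------------------------

#: smoothing kernel width used before peak detection, cm^-1
PEAK_SMOOTHING_CM1 = 30.0
#: local maxima below this fraction of the global maximum are ignored
PEAK_THRESHOLD = 0.05


def find_peaks(result_grid: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Positions of local maxima above 5% of the global max, after smoothing."""
    grid = np.asarray(result_grid, float)
    y = np.asarray(intensity, float)
    step = float(np.median(np.diff(grid)))
    smooth = gaussian_filter1d(y, PEAK_SMOOTHING_CM1 / step, mode="nearest")
    interior = np.arange(1, len(grid) - 1)
    is_max = (smooth[interior] > smooth[interior - 1]) & (smooth[interior] >= smooth[interior + 1])
    idx = interior[is_max]
    idx = idx[smooth[idx] >= PEAK_THRESHOLD * smooth.max()]
    return grid[idx]


def fit_uniform_shift(simulated: SpectrumResult, reference_peaks, channel: str = "od") -> float:
    """Rigid shift minimizing squared peak-position deviations.

    The least-squares solution for a single shift is the mean of the per-peak
    offsets (reference minus simulated, both sorted ascending).
    """
    ref = np.sort(np.asarray(reference_peaks, dtype=float))
    sim = np.sort(find_peaks(simulated.wavenumber, simulated.channels()[channel]))
    if len(sim) != len(ref):
        raise DisorderError(
            f"peak count mismatch: detected {len(sim)} simulated peaks "
            f"({sim.round(1)}) vs {len(ref)} reference peaks"
        )
    return float(np.mean(ref - sim))
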