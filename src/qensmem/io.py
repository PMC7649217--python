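"""File formats and run configuration.

Spectra and resolution kernels travel as TSV with commented headers
(``# Q=...``, ``# bin=...``); trajectories as columnar text
(time, molecule, x, y); sequences as raw strings or single-record FASTA;
run configuration as YAML with a strict schema (unknown keys rejected).
All writers round-trip losslessly through their readers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .instrument import ResolutionKernel, Spectrum, Trajectory
from .models import EnergyGrid

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_kernel",
    "write_kernel",
    "read_trajectory",
    "write_trajectory",
    "read_sequence",
    "RunConfig",
    "load_config",
]


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# Q={spec.Q!r}\n")
        fh.write(f"# bin={spec.grid.bin_width!r}\n")
        fh.write("# columns: omega_ueV\tintensity\tuncertainty\n")
        for om, inten, unc in zip(spec.grid.omega, spec.intensity, spec.uncertainty):
            fh.write(f"{float(om)!r}\t{float(inten)!r}\t{float(unc)!r}\n")


def _read_columnar(path: Path, n_cols: int) -> tuple[dict, np.ndarray]:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    header[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return header, np.array(rows)


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    header, data = _read_columnar(path, 3)
    if "Q" not in header:
        raise ValueError(f"{path}: missing '# Q=' header line")
    return Spectrum(
        Q=float(header["Q"]),
        grid=EnergyGrid(data[:, 0]),
        intensity=data[:, 1],
        uncertainty=data[:, 2],
    )


def write_kernel(kernel: ResolutionKernel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fwhm={kernel.fwhm!r}\n")
        fh.write(f"# gaussian_sd={kernel.gaussian_sd!r}\n")
        fh.write(f"# bin={kernel.grid.bin_width!r}\n")
        fh.write("# columns: omega_ueV\tresponse\n")
        for om, val in zip(kernel.grid.omega, kernel.values):
            fh.write(f"{float(om)!r}\t{float(val)!r}\n")


def read_kernel(path: str | Path) -> ResolutionKernel:
    path = Path(path)
    header, data = _read_columnar(path, 2)

    def _opt(key: str) -> float | None:
        val = header.get(key, "None")
        return None if val == "None" else float(val)

    return ResolutionKernel(
        grid=EnergyGrid(data[:, 0]),
        values=data[:, 1],
        fwhm=_opt("fwhm"),
        gaussian_sd=_opt("gaussian_sd"),
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    n_mol, n_frames, _ = traj.positions.shape
    mol = np.repeat(np.arange(n_mol), n_frames)
    t = np.tile(traj.times, n_mol)
    xy = traj.positions.reshape(-1, 2)
    df = pd.DataFrame(
        {"time_ns": t, "molecule": mol, "x_A": xy[:, 0], "y_A": xy[:, 1]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    required = {"time_ns", "molecule", "x_A", "y_A"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    mols = np.sort(df["molecule"].unique())
    times = np.sort(df.loc[df["molecule"] == mols[0], "time_ns"].to_numpy())
    positions = np.empty((mols.size, times.size, 2))
    for i, m in enumerate(mols):
        sub = df[df["molecule"] == m].sort_values("time_ns")
        if sub.shape[0] != times.size:
            raise ValueError(f"{path}: molecules do not share a common time base")
        positions[i, :, 0] = sub["x_A"].to_numpy()
        positions[i, :, 1] = sub["y_A"].to_numpy()
    return Trajectory(times=times, positions=positions)


def read_sequence(source: str | Path) -> str:
    """Peptide sequence from a raw string or a single-record FASTA file."""
    path = Path(source)
    if path.exists():
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"{path}: expected exactly one FASTA record")
        return str(records[0].seq)
    return str(source)


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic analysis run.

    Physical quantities carry unit suffixes in their names; all randomness
    derives from the single ``seed``.
    """

    scenario: str = "pure_lipid"
    mode: str = "diffusion"
    Q_set: list[float] = field(default_factory=lambda: [0.29, 0.44, 0.57, 0.78, 0.95])
    omega_max_ueV: float = 30.0
    bin_ueV: float = 0.1
    resolution_fwhm_ueV: float = 0.75
    counts: int = 1_000_000
    D_lipid_cm2_per_s: float = 21e-8
    v0_lipid_m_per_s: float = 0.27
    D_peptide_cm2_per_s: float = 0.5e-8
    p: float = 0.2
    p_deuterated: float = 0.492
    influenced_fraction: float = 0.8
    D_free_cm2_per_s: float = 21e-8
    cycles: int = 100_000
    adapt_every: int = 10_000
    target_accept: float = 0.66
    thin: int = 1
    seed: int = 1
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in {"pure_lipid", "lipid_peptide", "extended"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.mode not in {"diffusion", "flow"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.counts <= 0 or self.cycles <= 0:
            raise ValueError("counts and cycles must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
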