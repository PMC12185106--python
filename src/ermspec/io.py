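"""Matrix and coordinate readers/writers, run configuration, and fixtures.

Interchange conventions: covariance/activity matrices are headerless
comma-separated CSV (row-major, full precision) or HDF5 datasets named
"C", "activity", "coords", "sigma2"; labeled coordinate tables are TSV
with a header line.  All randomness flows from a single seed through
named substreams so multi-step runs are reproducible end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .erm import FunctionalSpace, VarianceModel, make_erm
from .kernels import KernelSpec


@dataclass
class RunConfig:
    """Serializable configuration of a command-line run."""

    command: str = ""
    input_path: str | None = None
    output_dir: str = "."
    kernel: dict = field(default_factory=lambda: KernelSpec().to_dict())
    space: dict = field(default_factory=lambda: {"d": 2, "L": 10.0, "N": 1024})
    variance: dict = field(default_factory=lambda: {"kind": "unit"})
    scheme: str = "rsap"
    n_levels: int = 3
    q0: float = 0.01
    n_repeats: int = 20
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator so modules sharing one seed stay independent.

    The stream key is a stable digest of the name (process-independent,
    unlike the builtin string hash).
    """
    import zlib

    root = np.random.SeedSequence(seed)
    child = np.random.SeedSequence(
        entropy=root.entropy,
        spawn_key=(zlib.crc32(name.encode()) % 2**31,))
    return np.random.default_rng(child)


def read_matrix(path: str | Path, format: str | None = None,
                role: str = "generic", dataset: str = "C") -> np.ndarray:
    """Read a matrix from headerless CSV or HDF5.

    ``role="covariance"`` additionally enforces squareness and symmetry to
    1e-8.  CSV files with a header row, ragged rows, or NaNs are rejected
    with the offending location.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            M = np.asarray(f[dataset])
    elif format == "csv":
        rows = []
        with open(path) as f:
            for ln, line in enumerate(f, start=1):
                if not line.strip():
                    continue
                parts = line.strip().split(",")
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as e:
                    raise ValueError(
                        f"{path}:{ln}: non-numeric entry (a header row?): {e}")
                if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                    raise ValueError(
                        f"{path}:{ln}: ragged row ({len(rows[-1])} vs "
                        f"{len(rows[0])} columns)")
        M = np.asarray(rows, dtype=float)
    else:
        raise ValueError("format must be 'csv' or 'hdf5'")
    bad = np.argwhere(~np.isfinite(M))
    if len(bad):
        i, j = bad[0]
        raise ValueError(f"{path}: non-finite entry at row {i}, column {j}")
    if role == "covariance":
        if M.shape[0] != M.shape[1]:
            raise ValueError(
                f"{path}: covariance must be square, got {M.shape}")
        if not np.allclose(M, M.T, atol=1e-8):
            raise ValueError(f"{path}: covariance is not symmetric to 1e-8")
    return M


def write_matrix(M: np.ndarray, path: str | Path, format: str | None = None,
                 dataset: str = "C") -> None:
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if format == "hdf5":
        with h5py.File(path, "a") as f:
            if dataset in f:
                del f[dataset]
            f.create_dataset(dataset, data=np.asarray(M))
    elif format == "csv":
        with open(path, "w") as f:
            for row in np.atleast_2d(M):
                f.write(",".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError("format must be 'csv' or 'hdf5'")


def write_manifest(path: str | Path, config: RunConfig, **extra) -> None:
    """JSON run manifest: config, package version, extra diagnostics."""
    from . import __version__

    payload = {"config": asdict(config), "version": __version__, **extra}
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


FIXTURES = ("erm_default", "erm_highdensity", "joint_coords", "rnn", "wishart")


def make_fixture(name: str, seed: int = 0, out_dir: str | Path = ".",
                 **overrides) -> Path:
    """Write a named HDF5 fixture and return its path.

    ``erm_default`` is the reference intermediate-density ERM
    (N=1024, d=2, L=10, rho=10.24, mu=0.5, eps=0.03125);
    ``erm_highdensity`` is the high-density counterpart
    (N=4096, rho=256, mu and d configurable).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.h5"
    if name == "erm_default":
        space = FunctionalSpace(d=2, L=10.0, N=overrides.get("N", 1024))
        kern = KernelSpec("tpdf", mu=overrides.get("mu", 0.5), epsilon=0.03125)
        erm = make_erm(space, kern, VarianceModel(kind="unit"), seed=seed)
        with h5py.File(path, "w") as f:
            f["C"] = erm.C
            f["coords"] = erm.coords
            f["sigma2"] = erm.sigma2
    elif name == "erm_highdensity":
        d = overrides.get("d", 2)
        mu = overrides.get("mu", 0.5)
        N = overrides.get("N", 4096)
        space = FunctionalSpace.from_density(d=d, N=N, rho=overrides.get("rho", 256.0))
        kern = KernelSpec("tpdf", mu=mu, epsilon=0.03125)
        erm = make_erm(space, kern, VarianceModel(kind="unit"), seed=seed)
        with h5py.File(path, "w") as f:
            f["C"] = erm.C
            f["coords"] = erm.coords
            f["sigma2"] = erm.sigma2
    elif name == "joint_coords":
        from .nullmodels_cca import synth_joint_coords

        jc = synth_joint_coords(overrides.get("N", 1024),
                                overrides.get("R_CCA", 0.335), seed=seed)
        with h5py.File(path, "w") as f:
            f["anat"] = jc.anat
            f["func"] = jc.func
    elif name == "rnn":
        from .nullmodels_cca import rnn_covariance

        C = rnn_covariance(overrides.get("N", 1024), overrides.get("g", 0.95),
                           seed=seed)
        with h5py.File(path, "w") as f:
            f["C"] = C
    elif name == "wishart":
        from .nullmodels_cca import wishart_cov

        C = wishart_cov(overrides.get("N", 1024), overrides.get("T", 7200), seed)
        with h5py.File(path, "w") as f:
            f["C"] = C
    else:
        raise ValueError(f"unknown fixture {name!r}; options: {FIXTURES}")
    return path
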