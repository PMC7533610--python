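"""Orchestration: dataset generation, splitting, training, online prediction.

The offline phase samples the four-parameter failure space, simulates the
closed loop for every draw, featurizes the SAP/PAP windows, and trains the
inverse network.  The online path maps a single (SAP, PAP) pair through the
network and re-simulates the 0D model with the predicted parameters to
recover the full hemodynamic state.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .circulation_model import CirculationParameters, SimulationOutput, simulate
from .failure_space import (LVSystolicParameters, ParameterRanges,
                            PARAMETER_NAMES, apply_parameters, sample_parameters)
from .fourier_features import (DEFAULT_M, PressureSignal, dfft_coefficients,
                               featurize_simulation)
from .inverse_network import TrainedNetwork, TrainingConfig, train
from .evaluation import extract_hemodynamics, HemodynamicSummary

log = logging.getLogger(__name__)


@dataclass
class DatasetSpec:
    """Size, splits, featurization and simulation protocol of one dataset."""

    n_samples: int = 10_000
    test_fraction: float = 0.05   # of the total
    train_fraction: float = 0.80  # of the non-test remainder
    seed: int = 0
    M: int = DEFAULT_M
    n_t: int = 220
    window: float = 2.2
    duration: float = 20.0
    dt: float = 0.002
    transient: float = 10.0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        if not (0.0 < self.test_fraction < 1.0 and 0.0 < self.train_fraction < 1.0):
            raise ValueError("split fractions must lie strictly in (0, 1)")

    def split_sizes(self) -> tuple[int, int, int]:
        """(n_train, n_val, n_test) with test drawn from the total first."""
        n_test = round(self.test_fraction * self.n_samples)
        rest = self.n_samples - n_test
        n_train = round(self.train_fraction * rest)
        return n_train, rest - n_train, n_test


@dataclass
class Dataset:
    X: xr.DataArray               # (sample, signal, coefficient)
    Y: np.ndarray                 # (sample, 4), physical units
    splits: dict[str, np.ndarray]  # train/val/test index sets
    metadata: dict = field(default_factory=dict)
    steady: np.ndarray | None = None

    def features(self, split: str) -> np.ndarray:
        idx = self.splits[split]
        return self.X.values[idx].reshape(len(idx), -1)

    def targets(self, split: str) -> np.ndarray:
        return self.Y[self.splits[split]]


def split_dataset(n_samples: int, spec: DatasetSpec) -> dict[str, np.ndarray]:
    """Random disjoint exhaustive train/val/test assignment under the seed."""
    if n_samples != spec.n_samples:
        raise ValueError("sample count inconsistent with spec")
    n_train, n_val, n_test = spec.split_sizes()
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("degenerate split: every subset must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB10C]))
    perm = rng.permutation(n_samples)
    return {
        "test": np.sort(perm[:n_test]),
        "train": np.sort(perm[n_test:n_test + n_train]),
        "val": np.sort(perm[n_test + n_train:]),
    }


def _config_hash(base: CirculationParameters, ranges: ParameterRanges,
                 spec: DatasetSpec) -> str:
    blob = json.dumps({"model": base.to_dict(),
                       "ranges": {n: getattr(ranges, n) for n in PARAMETER_NAMES},
                       "spec": asdict(spec)}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_sample(y: LVSystolicParameters, base: CirculationParameters,
                    spec: DatasetSpec) -> tuple[np.ndarray, bool]:
    """One forward simulation -> concatenated (SAP, PAP) feature row."""
    out = simulate(apply_parameters(base, y), spec.duration, spec.dt,
                   spec.transient)
    f_sap, f_pap = featurize_simulation(out, spec.window, spec.n_t, spec.M)
    return np.concatenate([f_sap.coefficients, f_pap.coefficients]), out.steady_state_reached


def generate_dataset(spec: DatasetSpec, base: CirculationParameters,
                     ranges: ParameterRanges, cache_path: str | None = None,
                     progress: bool = False) -> Dataset:
    """Sample -> simulate -> featurize the full dataset.

    With ``cache_path`` (a CSV file), finished samples are appended as they
    complete and are reused on a re-run with identical configuration, making
    generation resumable.  A failure rate above 0.1% aborts.
    """
    ys = sample_parameters(spec.n_samples, ranges, spec.seed)
    n_coeff = 2 * spec.M + 1
    cfg_hash = _config_hash(base, ranges, spec)

    cached: dict[int, np.ndarray] = {}
    if cache_path and os.path.exists(cache_path):
        df = pd.read_csv(cache_path, float_precision="round_trip")
        if not df.empty and (df["config_hash"].iloc[0] != cfg_hash):
            raise ValueError("cache was generated under a different configuration")
        for _, row in df.iterrows():
            cached[int(row["sample"])] = row.drop(["sample", "config_hash"]).to_numpy(float)
        log.info("resuming: %d cached samples", len(cached))

    feat_cols = ([f"sap_{c}" for c in _coeff_names(spec.M)]
                 + [f"pap_{c}" for c in _coeff_names(spec.M)])
    rows = np.empty((spec.n_samples, 2 * n_coeff))
    steady = np.zeros(spec.n_samples, dtype=bool)
    failures: list[int] = []
    fh = None
    if cache_path:
        new_file = not os.path.exists(cache_path)
        fh = open(cache_path, "a")
        if new_file:
            fh.write(",".join(["sample", "config_hash"] + feat_cols + ["steady"]) + "\n")

    try:
        for i, y in enumerate(ys):
            if i in cached:
                row = cached[i]
                rows[i] = row[:-1]
                steady[i] = bool(row[-1])
                continue
            try:
                rows[i], steady[i] = simulate_sample(y, base, spec)
            except (FloatingPointError, ValueError) as exc:
                failures.append(i)
                log.warning("sample %d failed: %s (y=%s)", i, exc, y)
                rows[i] = np.nan
                continue
            if fh is not None:
                vals = ",".join(f"{float(v):.17g}" for v in rows[i])
                fh.write(f"{i},{cfg_hash},{vals},{int(steady[i])}\n")
                fh.flush()
            if progress and (i + 1) % 100 == 0:
                log.info("generated %d/%d samples", i + 1, spec.n_samples)
    finally:
        if fh is not None:
            fh.close()

    if len(failures) > 0.001 * spec.n_samples:
        raise RuntimeError(
            f"{len(failures)} simulation failures (> 0.1%): indices {failures[:10]}")

    omega = 2.0 * np.pi / spec.window
    names = _coeff_names(spec.M)
    X = xr.DataArray(
        rows.reshape(spec.n_samples, 2, n_coeff),
        dims=("sample", "signal", "coefficient"),
        coords={"signal": ["sap", "pap"], "coefficient": names},
        attrs={"M": spec.M, "omega": omega, "n_t": spec.n_t,
               "window": spec.window, "signal_order": "sap,pap"},
    )
    Y = np.array([y.to_array() for y in ys])
    splits = split_dataset(spec.n_samples, spec)
    metadata = {"seed": spec.seed, "config_hash": cfg_hash,
                "version": __version__, "spec": asdict(spec),
                "n_failures": len(failures)}
    return Dataset(X=X, Y=Y, splits=splits, metadata=metadata, steady=steady)


def _coeff_names(M: int) -> list[str]:
    return [f"a{j}" for j in range(M + 1)] + [f"b{j}" for j in range(1, M + 1)]


def save_dataset(ds: Dataset, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    M = int(ds.X.attrs["M"])
    cols = ([f"sap_{c}" for c in _coeff_names(M)]
            + [f"pap_{c}" for c in _coeff_names(M)])
    feat = pd.DataFrame(ds.X.values.reshape(len(ds.Y), -1), columns=cols)
    # %.17g round-trips IEEE doubles exactly through the CSV
    feat.to_csv(os.path.join(directory, "features.csv"),
                index_label="sample", float_format="%.17g")
    pd.DataFrame(ds.Y, columns=list(PARAMETER_NAMES)).to_csv(
        os.path.join(directory, "targets.csv"), index_label="sample",
        float_format="%.17g")
    with open(os.path.join(directory, "splits.json"), "w") as f:
        json.dump({k: v.tolist() for k, v in ds.splits.items()}, f)
    manifest = dict(ds.metadata)
    manifest["tensor_attrs"] = {k: (v if isinstance(v, str) else float(v))
                                for k, v in ds.X.attrs.items()}
    with open(os.path.join(directory, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)


def load_dataset(directory: str) -> Dataset:
    feat = pd.read_csv(os.path.join(directory, "features.csv"),
                       index_col="sample", float_precision="round_trip")
    targ = pd.read_csv(os.path.join(directory, "targets.csv"),
                       index_col="sample", float_precision="round_trip")
    with open(os.path.join(directory, "splits.json")) as f:
        splits = {k: np.asarray(v, dtype=int) for k, v in json.load(f).items()}
    with open(os.path.join(directory, "manifest.json")) as f:
        manifest = json.load(f)
    attrs = manifest.pop("tensor_attrs")
    M = int(attrs["M"])
    n = len(feat)
    X = xr.DataArray(
        feat.to_numpy().reshape(n, 2, 2 * M + 1),
        dims=("sample", "signal", "coefficient"),
        coords={"signal": ["sap", "pap"], "coefficient": _coeff_names(M)},
        attrs=attrs,
    )
    return Dataset(X=X, Y=targ.to_numpy(), splits=splits, metadata=manifest)


def train_on_dataset(ds: Dataset, ranges: ParameterRanges,
                     cfg: TrainingConfig | None = None,
                     architecture=None) -> TrainedNetwork:
    return train(ds.features("train"), ds.targets("train"),
                 ds.features("val"), ds.targets("val"),
                 ranges, cfg, architecture)


def predict_online(sap: PressureSignal, pap: PressureSignal,
                   net: TrainedNetwork, base: CirculationParameters,
                   spec: DatasetSpec | None = None
                   ) -> tuple[LVSystolicParameters, HemodynamicSummary, SimulationOutput]:
    """The online path: signals -> features -> parameters -> re-simulation."""
    spec = spec or DatasetSpec()
    for name, sig in (("sap", sap), ("pap", pap)):
        if sig.n_t != spec.n_t or not np.isclose(sig.window, spec.window):
            raise ValueError(
                f"{name} grid mismatch: expected n_t={spec.n_t} over "
                f"{spec.window}s, got n_t={sig.n_t} over {sig.window}s")
    x = np.concatenate([dfft_coefficients(sap, spec.M).coefficients,
                        dfft_coefficients(pap, spec.M).coefficients])
    y_hat = LVSystolicParameters.from_array(net.forward(x))
    out = simulate(apply_parameters(base, y_hat), spec.duration, spec.dt,
                   spec.transient)
    return y_hat, extract_hemodynamics(out), out
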