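"""Closing the loop: hemodynamic extraction, error statistics, sensitivity.

The 12 clinical variables are extracted from the steady portion of a
simulation; closed-loop evaluation re-simulates the model with exact and
network-predicted parameter sets and accumulates per-variable error
statistics; the sensitivity analysis perturbs each LV parameter about its
range midpoint and summarizes the induced output spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circulation_model import CirculationParameters, SimulationOutput, simulate
from .failure_space import (LVSystolicParameters, ParameterRanges,
                            PARAMETER_NAMES, apply_parameters)

log = logging.getLogger(__name__)

VARIABLES = ("msap", "ssap", "dsap", "mpap", "spap", "dpap",
             "hr", "lvef", "lvedv", "lvesv", "ci", "pcwp")

DEFAULT_BSA = 2.0  # m^2


@dataclass(frozen=True)
class HemodynamicSummary:
    """The 12 scalar clinical variables of one steady simulation."""

    msap: float   # mean systemic arterial pressure, mmHg
    ssap: float   # systolic ", mmHg
    dsap: float   # diastolic ", mmHg
    mpap: float   # mean pulmonary arterial pressure, mmHg
    spap: float   # mmHg
    dpap: float   # mmHg
    hr: float     # 1/min
    lvef: float   # %
    lvedv: float  # ml
    lvesv: float  # ml
    ci: float     # l/min/m^2
    pcwp: float   # mmHg

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in VARIABLES])

    def to_dict(self) -> dict:
        return {v: float(getattr(self, v)) for v in VARIABLES}


def extract_hemodynamics(out: SimulationOutput, bsa: float = DEFAULT_BSA
                         ) -> HemodynamicSummary:
    """Summarize the analysis window of a simulation.

    Mean pressures are time averages; systolic/diastolic values are per-beat
    extrema averaged across beats; LVEDV/LVESV are per-beat extrema of the
    LV volume; HR is 60 over the mean regulated period; CI uses the
    configured body surface area; PCWP is the time-averaged left-atrial
    pressure (the standard 0D surrogate).
    """
    s = out.analysis_slice
    beats = out.beat_starts[(out.beat_starts >= s.start)
                            & (out.beat_starts < s.stop)]
    if len(beats) < 4:  # need >= 3 complete beats in the window
        raise ValueError("fewer than 3 complete beats in the analysis window")

    def per_beat(series, fn):
        return float(np.mean([fn(series[b0:b1])
                              for b0, b1 in zip(beats[:-1], beats[1:])]))

    msap = float(np.mean(out.sap[s]))
    mpap = float(np.mean(out.pap[s]))
    ssap = per_beat(out.sap, np.max)
    dsap = per_beat(out.sap, np.min)
    spap = per_beat(out.pap, np.max)
    dpap = per_beat(out.pap, np.min)
    lvedv = per_beat(out.v_lv, np.max)
    lvesv = per_beat(out.v_lv, np.min)
    hr = 60.0 / float(np.mean(out.t_heart[s]))
    lvef = 100.0 * (lvedv - lvesv) / lvedv
    ci = hr * (lvedv - lvesv) / 1000.0 / bsa
    pcwp = float(np.mean(out.p_la[s]))
    return HemodynamicSummary(msap, ssap, dsap, mpap, spap, dpap,
                              hr, lvef, lvedv, lvesv, ci, pcwp)


@dataclass
class ErrorStatistics:
    """Per-variable summary of exact vs predicted hemodynamics.

    ``table`` rows are statistics, columns the 12 variables: min/max/mean/sd
    of exact and predicted values, the mean absolute error, its relative
    counterpart (normalized by the exact value), the error SD and the normal
    95% CI of the mean error.
    """

    table: pd.DataFrame
    n: int
    n_failed: int = 0

    @property
    def mean_relative_error(self) -> pd.Series:
        return self.table.loc["mean_rel_err"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def error_statistics(exact: np.ndarray, predicted: np.ndarray,
                     n_failed: int = 0) -> ErrorStatistics:
    """Table-1-style statistics from (n, 12) exact/predicted arrays."""
    exact = np.asarray(exact, float)
    predicted = np.asarray(predicted, float)
    if exact.shape != predicted.shape or exact.ndim != 2:
        raise ValueError("exact and predicted must be matching (n, k) arrays")
    err = np.abs(exact - predicted)
    n = len(exact)
    rows = {
        "exact_min": exact.min(0), "exact_max": exact.max(0),
        "exact_mean": exact.mean(0), "exact_sd": exact.std(0, ddof=1),
        "pred_min": predicted.min(0), "pred_max": predicted.max(0),
        "pred_mean": predicted.mean(0), "pred_sd": predicted.std(0, ddof=1),
        "mean_err": err.mean(0),
        "mean_rel_err": (err / np.abs(exact)).mean(0),
        "err_sd": err.std(0, ddof=1),
    }
    half = 1.96 * rows["err_sd"] / np.sqrt(n)
    rows["err_ci_low"] = rows["mean_err"] - half
    rows["err_ci_up"] = rows["mean_err"] + half
    table = pd.DataFrame(rows, index=list(VARIABLES)).T
    return ErrorStatistics(table=table, n=n, n_failed=n_failed)


def closed_loop_evaluation(x_test: np.ndarray,
                           y_test: np.ndarray,
                           net,
                           base: CirculationParameters,
                           duration: float = 20.0, dt: float = 0.002,
                           transient: float = 10.0,
                           bsa: float = DEFAULT_BSA) -> ErrorStatistics:
    """Re-simulate with exact and predicted parameters and compare.

    For each test sample the model is run twice — with the true 4-vector and
    with the network's prediction from the sample's Fourier features — and
    the 12 hemodynamic variables of both runs enter the statistics.
    Simulation failures are logged and excluded (counted in ``n_failed``).
    """
    y_pred = net.predict_batch(x_test)
    exact_rows, pred_rows = [], []
    n_failed = 0
    for i, (ye, yp) in enumerate(zip(np.asarray(y_test, float), y_pred)):
        try:
            out_e = simulate(apply_parameters(base, LVSystolicParameters.from_array(ye)),
                             duration, dt, transient)
            out_p = simulate(apply_parameters(base, LVSystolicParameters.from_array(yp)),
                             duration, dt, transient)
            exact_rows.append(extract_hemodynamics(out_e, bsa).to_array())
            pred_rows.append(extract_hemodynamics(out_p, bsa).to_array())
        except (FloatingPointError, ValueError) as exc:
            n_failed += 1
            log.warning("sample %d excluded: %s (y_exact=%s)", i, exc, ye)
    if not exact_rows:
        raise RuntimeError("no test sample simulated successfully")
    return error_statistics(np.array(exact_rows), np.array(pred_rows), n_failed)


def sensitivity_analysis(base: CirculationParameters, ranges: ParameterRanges,
                         n_runs: int = 100, epsilon: float = 0.01,
                         seed: int = 0, duration: float = 20.0,
                         dt: float = 0.002, transient: float = 10.0,
                         bsa: float = DEFAULT_BSA) -> dict[str, pd.DataFrame]:
    """Output spread under small perturbations of each LV parameter.

    For each parameter P in turn, n_runs values P = P_mean (1 + eps N(0,1))
    are simulated with the other three held at their midpoints; the returned
    tables give min/max/mean/SD of the 12 variables per parameter.  Draws
    that leave the physical domain are resampled (logged).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    rng = np.random.default_rng(seed)
    mean = ranges.mean.to_array()
    results: dict[str, pd.DataFrame] = {}
    for k, name in enumerate(PARAMETER_NAMES):
        rows = []
        for _ in range(n_runs):
            y = mean.copy()
            for _attempt in range(100):
                val = mean[k] * (1.0 + epsilon * rng.standard_normal())
                if val > 0:
                    break
                log.warning("resampling non-physical draw for %s", name)
            y[k] = val
            out = simulate(apply_parameters(base, LVSystolicParameters.from_array(y)),
                           duration, dt, transient)
            rows.append(extract_hemodynamics(out, bsa).to_array())
        arr = np.array(rows)
        results[name] = pd.DataFrame(
            {"min": arr.min(0), "max": arr.max(0), "mean": arr.mean(0),
             "sd": arr.std(0, ddof=1)},
            index=list(VARIABLES)).T
    return results


def sensitivity_table(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack the per-parameter summaries into one tidy table."""
    frames = []
    for name, df in results.items():
        d = df.copy()
        d.insert(0, "parameter", name)
        d.insert(1, "statistic", d.index)
        frames.append(d.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)
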