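"""The four-parameter space of LV systolic function.

Degrees of systolic failure are represented by the 4-vector
(E_max,lv, E_max_lv,0, G_Emax,lv, k_E,lv): reference end-systolic elastance,
elastance in absence of autoregulation, baroreflex contractility gain, and
EDPVR steepness.  Parameter sets are drawn independently and uniformly over
configured admissible ranges spanning normal physiology through severe
heart failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circulation_model import CirculationParameters, load_default_config

PARAMETER_NAMES = ("emax_lv", "emax_lv0", "g_emax_lv", "ke_lv")


@dataclass(frozen=True)
class LVSystolicParameters:
    """y = [E_max,lv, E_max_lv,0, G_Emax,lv, k_E,lv]."""

    emax_lv: float    # mmHg/ml
    emax_lv0: float   # mmHg/ml
    g_emax_lv: float  # mmHg/ml/(spikes/s)
    ke_lv: float      # 1/ml

    def __post_init__(self) -> None:
        if min(self.emax_lv, self.emax_lv0, self.g_emax_lv, self.ke_lv) <= 0:
            raise ValueError("all LV systolic parameters must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([self.emax_lv, self.emax_lv0, self.g_emax_lv, self.ke_lv])

    @classmethod
    def from_array(cls, a) -> "LVSystolicParameters":
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class ParameterRanges:
    """Per-parameter (lower, upper) bounds; P_mean = (P_min + P_max) / 2."""

    emax_lv: tuple[float, float]
    emax_lv0: tuple[float, float]
    g_emax_lv: tuple[float, float]
    ke_lv: tuple[float, float]

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid range for {name}: need lower <= upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in PARAMETER_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in PARAMETER_NAMES])

    @property
    def mean(self) -> LVSystolicParameters:
        return LVSystolicParameters.from_array(0.5 * (self.lower + self.upper))

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "ParameterRanges":
        if cfg is None:
            cfg = load_default_config()
        r = cfg["ranges"]
        return cls(**{n: tuple(float(v) for v in r[n]) for n in PARAMETER_NAMES})


def default_ranges() -> ParameterRanges:
    return ParameterRanges.from_config()


def sample_parameters(n: int, ranges: ParameterRanges, seed: int
                      ) -> list[LVSystolicParameters]:
    """``n`` independent uniform draws over the admissible ranges.

    Reproducible under a fixed seed; each sample index owns a spawned
    sub-stream so datasets can be regenerated per-index (or in parallel)
    without changing the draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = ranges.lower, ranges.upper
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for ss in children:
        u = np.random.default_rng(ss).random(4)
        out.append(LVSystolicParameters.from_array(lo + u * (hi - lo)))
    return out


def apply_parameters(base: CirculationParameters, y: LVSystolicParameters
                     ) -> CirculationParameters:
    """Return a copy of ``base`` with exactly the four LV slots replaced."""
    p = base.copy()
    p.left_ventricle.emax = y.emax_lv
    p.left_ventricle.emax0 = y.emax_lv0
    p.left_ventricle.ke = y.ke_lv
    p.baroreflex.effectors["emax_lv"].gain = y.g_emax_lv
    return p


def extract_parameters(p: CirculationParameters) -> LVSystolicParameters:
    """Inverse of :func:`apply_parameters` on the four-parameter subspace."""
    return LVSystolicParameters(
        emax_lv=p.left_ventricle.emax,
        emax_lv0=p.left_ventricle.emax0,
        g_emax_lv=p.baroreflex.effectors["emax_lv"].gain,
        ke_lv=p.left_ventricle.ke,
    )
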