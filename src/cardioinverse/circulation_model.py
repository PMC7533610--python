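"""Closed-loop 0D model of the systemic and pulmonary circulations.

Four heart chambers (passive atria, time-varying-elastance ventricles with
ideal valves), RLC/RC vascular compartments, and carotid-baroreflex
autoregulation of heart period, ventricular contractility, venous unstressed
volumes and peripheral resistances.  Deterministic fixed-step RK4 integration;
blood volume is conserved by construction (volumes are the states).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import _kernel as K


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CompartmentParameters:
    """R (mmHg*s/ml), C (ml/mmHg), L (mmHg*s^2/ml, arterial only), Vu (ml)."""

    R: float
    C: float
    Vu: float = 0.0
    L: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("compliance must be positive")
        if self.R < 0 or self.L < 0 or self.Vu < 0:
            raise ValueError("R, L, Vu must be non-negative")


@dataclass
class VentricleParameters:
    """Time-varying-elastance ventricle with exponential EDPVR."""

    emax0: float          # elastance in absence of autoregulation (mmHg/ml)
    p0: float             # diastolic pressure scale (mmHg)
    ke: float             # EDPVR steepness (1/ml)
    vu: float             # unstressed volume (ml)
    kr: float             # ejection resistance per unit isovolumic pressure
    emax: float = 0.0     # reference elastance (LV only; 0 = unused)
    emax_norm: float = 1.0

    def __post_init__(self) -> None:
        if self.emax0 <= 0 or self.ke <= 0 or self.p0 < 0:
            raise ValueError("require emax0 > 0, ke > 0, p0 >= 0")


@dataclass
class HeartTiming:
    t0: float = 0.58
    t_min: float = 0.4
    t_max: float = 1.0     # period ceiling: heart rate floor 60/min
    tsys0: float = 0.5
    ksys: float = 0.075


@dataclass
class EffectorParameters:
    gain: float
    delay: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.delay < 0:
            raise ValueError("require tau > 0 and delay >= 0")


@dataclass
class BaroreflexParameters:
    # afferent sigmoid
    p_n: float = 92.0
    k_a: float = 11.758
    f_min: float = 2.52
    f_max: float = 47.78
    tau_z: float = 6.37
    tau_p: float = 2.076
    # sympathetic efferent
    f_es_inf: float = 2.10
    f_es_0: float = 16.11
    k_es: float = 0.0675
    f_es_min: float = 2.66
    # vagal efferent
    f_ev_0: float = 3.2
    f_ev_inf: float = 6.3
    f_ab_0: float = 25.0
    k_ev: float = 7.06
    # effectors
    effectors: dict[str, EffectorParameters] = field(default_factory=dict)


COMPARTMENT_NAMES = (
    "systemic_arteries",
    "splanchnic_peripheral",
    "extrasplanchnic_peripheral",
    "splanchnic_venous",
    "extrasplanchnic_venous",
    "pulmonary_arteries",
    "pulmonary_peripheral",
    "pulmonary_veins",
    "left_atrium",
    "right_atrium",
)

EFFECTOR_NAMES = (
    "emax_lv", "emax_rv", "r_sp", "r_ep", "vu_sv", "vu_ev",
    "period_sym", "period_vagal",
)


@dataclass
class CirculationParameters:
    compartments: dict[str, CompartmentParameters]
    left_ventricle: VentricleParameters
    right_ventricle: VentricleParameters
    timing: HeartTiming
    baroreflex: BaroreflexParameters
    total_blood_volume: float = 5300.0

    def __post_init__(self) -> None:
        missing = set(COMPARTMENT_NAMES) - set(self.compartments)
        if missing:
            raise ValueError(f"missing compartments: {sorted(missing)}")
        missing_eff = set(EFFECTOR_NAMES) - set(self.baroreflex.effectors)
        if missing_eff:
            raise ValueError(f"missing effectors: {sorted(missing_eff)}")
        vu_sum = sum(c.Vu for c in self.compartments.values())
        vu_sum += self.left_ventricle.vu + self.right_ventricle.vu
        if self.total_blood_volume <= vu_sum:
            raise ValueError("total blood volume must exceed summed unstressed volumes")

    def copy(self) -> "CirculationParameters":
        return copy.deepcopy(self)

    # -- config round trip ---------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "CirculationParameters":
        comps = {
            name: CompartmentParameters(**vals)
            for name, vals in cfg["compartments"].items()
        }
        lv = VentricleParameters(**cfg["left_ventricle"])
        rv = VentricleParameters(**cfg["right_ventricle"])
        timing = HeartTiming(**cfg["timing"])
        bcfg = cfg["baroreflex"]
        baro = BaroreflexParameters(
            **bcfg["afferent"],
            **bcfg["sympathetic"],
            **bcfg["vagal"],
            effectors={
                name: EffectorParameters(**vals)
                for name, vals in bcfg["effectors"].items()
            },
        )
        return cls(
            compartments=comps,
            left_ventricle=lv,
            right_ventricle=rv,
            timing=timing,
            baroreflex=baro,
            total_blood_volume=cfg["total_blood_volume"],
        )

    def to_dict(self) -> dict:
        b = self.baroreflex
        return {
            "total_blood_volume": self.total_blood_volume,
            "compartments": {
                name: {k: v for k, v in vars(c).items() if not (k == "L" and v == 0.0)}
                for name, c in self.compartments.items()
            },
            "left_ventricle": dict(vars(self.left_ventricle)),
            "right_ventricle": {
                k: v for k, v in vars(self.right_ventricle).items()
                if k not in ("emax", "emax_norm")
            },
            "timing": dict(vars(self.timing)),
            "baroreflex": {
                "afferent": {"p_n": b.p_n, "k_a": b.k_a, "f_min": b.f_min,
                             "f_max": b.f_max, "tau_z": b.tau_z, "tau_p": b.tau_p},
                "sympathetic": {"f_es_inf": b.f_es_inf, "f_es_0": b.f_es_0,
                                "k_es": b.k_es, "f_es_min": b.f_es_min},
                "vagal": {"f_ev_0": b.f_ev_0, "f_ev_inf": b.f_ev_inf,
                          "f_ab_0": b.f_ab_0, "k_ev": b.k_ev},
                "effectors": {
                    name: dict(vars(e)) for name, e in b.effectors.items()
                },
            },
        }


def default_parameters() -> CirculationParameters:
    """The packaged default parameter set."""
    return CirculationParameters.from_dict(load_default_config()["model"])


def load_default_config() -> dict:
    with resources.files("cardioinverse.data").joinpath("default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path: Optional[str] = None) -> dict:
    """Load a YAML config; defaults to the packaged one."""
    if path is None:
        return load_default_config()
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# packing for the compiled kernel
# ---------------------------------------------------------------------------

def pack_parameters(p: CirculationParameters) -> np.ndarray:
    a = np.zeros(K.N_PARAMS)
    c = p.compartments

    def put(name, i_r, i_c, i_vu, i_l=None):
        comp = c[name]
        a[i_r], a[i_c], a[i_vu] = comp.R, comp.C, comp.Vu
        if i_l is not None:
            a[i_l] = comp.L

    put("systemic_arteries", K.R_SA, K.C_SA, K.VU_SA, K.L_SA)
    put("splanchnic_peripheral", K.R_SP0, K.C_SP, K.VU_SP)
    put("extrasplanchnic_peripheral", K.R_EP0, K.C_EP, K.VU_EP)
    put("splanchnic_venous", K.R_SV, K.C_SV, K.VU_SV0)
    put("extrasplanchnic_venous", K.R_EV, K.C_EV, K.VU_EV0)
    put("pulmonary_arteries", K.R_PA, K.C_PA, K.VU_PA, K.L_PA)
    put("pulmonary_peripheral", K.R_PP, K.C_PP, K.VU_PP)
    put("pulmonary_veins", K.R_PV, K.C_PV, K.VU_PV)
    put("left_atrium", K.R_LA, K.C_LA, K.VU_LA)
    put("right_atrium", K.R_RA, K.C_RA, K.VU_RA)

    a[K.VTOT] = p.total_blood_volume

    lv, rv = p.left_ventricle, p.right_ventricle
    a[K.EMAX_LV] = lv.emax if lv.emax > 0 else lv.emax_norm
    a[K.EMAX0_LV], a[K.P0_LV], a[K.KE_LV] = lv.emax0, lv.p0, lv.ke
    a[K.VU_LV], a[K.KR_LV], a[K.EMAX_NORM] = lv.vu, lv.kr, lv.emax_norm
    a[K.EMAX0_RV], a[K.P0_RV], a[K.KE_RV] = rv.emax0, rv.p0, rv.ke
    a[K.VU_RV], a[K.KR_RV] = rv.vu, rv.kr

    t = p.timing
    a[K.T0], a[K.T_MIN], a[K.T_MAX] = t.t0, t.t_min, t.t_max
    a[K.TSYS0], a[K.KSYS] = t.tsys0, t.ksys

    b = p.baroreflex
    a[K.PN], a[K.KA], a[K.FAB_MIN], a[K.FAB_MAX] = b.p_n, b.k_a, b.f_min, b.f_max
    a[K.TAU_Z], a[K.TAU_P] = b.tau_z, b.tau_p
    a[K.FES_INF], a[K.FES_0], a[K.KES], a[K.FES_MIN] = (
        b.f_es_inf, b.f_es_0, b.k_es, b.f_es_min)
    a[K.FEV_0], a[K.FEV_INF], a[K.FAB0], a[K.KEV] = (
        b.f_ev_0, b.f_ev_inf, b.f_ab_0, b.k_ev)

    slots = {
        "emax_lv": (K.G_EMAXLV, K.D_EMAXLV, K.TAU_EMAXLV),
        "emax_rv": (K.G_EMAXRV, K.D_EMAXRV, K.TAU_EMAXRV),
        "r_sp": (K.G_RSP, K.D_RSP, K.TAU_RSP),
        "r_ep": (K.G_REP, K.D_REP, K.TAU_REP),
        "vu_sv": (K.G_VUSV, K.D_VUSV, K.TAU_VUSV),
        "vu_ev": (K.G_VUEV, K.D_VUEV, K.TAU_VUEV),
        "period_sym": (K.G_TS, K.D_TS, K.TAU_TS),
        "period_vagal": (K.G_TV, K.D_TV, K.TAU_TV),
    }
    for name, (ig, id_, it) in slots.items():
        e = b.effectors[name]
        a[ig], a[id_], a[it] = e.gain, e.delay, e.tau
    return a


# ---------------------------------------------------------------------------
# elementary operations (thin wrappers over the compiled scalar kernels)
# ---------------------------------------------------------------------------

def ventricular_activation(cycle_phase: float, timing: HeartTiming,
                           t_heart: Optional[float] = None) -> float:
    """Activation phi in [0, 1] at a given fraction of the cardiac cycle."""
    if not 0.0 <= cycle_phase < 1.0:
        raise ValueError("cycle_phase must lie in [0, 1)")
    T = timing.t0 if t_heart is None else t_heart
    return float(K.activation(cycle_phase * T, T, timing.tsys0, timing.ksys))


_KEV_BOUND = 50.0  # overflow guard on the EDPVR exponent


def ventricle_pressure(v: float, phi: float, vp: VentricleParameters,
                       emax: Optional[float] = None) -> float:
    """Isovolumic ventricular pressure at volume ``v`` and activation ``phi``."""
    if v < 0:
        raise ValueError("volume must be non-negative")
    if vp.ke * v > _KEV_BOUND:
        raise OverflowError("non-physiological state: ke*V exceeds bound")
    e = vp.emax0 if emax is None else emax
    return float(K.isovolumic_pressure(v, phi, e, vp.ke, vp.p0, vp.vu))


def valve_flow(p_upstream: float, p_downstream: float, r_valve: float) -> float:
    """Unidirectional Ohmic valve flow (ml/s)."""
    if r_valve <= 0:
        raise ValueError("valve resistance must be positive")
    return float(K.valve_flow(p_upstream, p_downstream, r_valve))


def baroreflex_update(carotid_pressure: float, bp: BaroreflexParameters) -> dict:
    """Steady-state regulated values for a held carotid pressure.

    Evaluates the afferent and efferent static characteristics and the
    effector equilibria (delays and first-order dynamics at steady state),
    returning the regulated offsets added to each basal value.
    """
    f_ab = float(K.afferent_firing(carotid_pressure, bp.p_n, bp.k_a,
                                   bp.f_min, bp.f_max))
    if not (0.0 <= f_ab <= bp.f_max):
        raise ValueError("afferent firing outside [0, saturation]")
    f_es = float(K.sympathetic_activity(f_ab, bp.f_es_inf, bp.f_es_0, bp.k_es))
    f_ev = float(K.vagal_activity(f_ab, bp.f_ev_0, bp.f_ev_inf,
                                  bp.f_ab_0, bp.k_ev))
    drive = float(K.sympathetic_drive(f_es, bp.f_es_min))
    out = {"f_ab": f_ab, "f_es": f_es, "f_ev": f_ev}
    for name in EFFECTOR_NAMES:
        g = bp.effectors[name].gain
        out[name] = g * (f_ev if name == "period_vagal" else drive)
    return out


def compartment_rhs(state: np.ndarray, p: CirculationParameters, t: float = 0.0,
                    cycle_time: float = 0.0, t_heart: Optional[float] = None,
                    fes: Optional[float] = None, fev: Optional[float] = None
                    ) -> np.ndarray:
    """Time-derivatives of the full state vector (mass/momentum balances).

    ``fes``/``fev`` stand in for the delayed efferent activities (held
    constant for a single evaluation).
    """
    pk = pack_parameters(p)
    if t_heart is None:
        t_heart = p.timing.t0
    if fes is None or fev is None:
        basal = baroreflex_update(p.baroreflex.p_n, p.baroreflex)
        fes = basal["f_es"] if fes is None else fes
        fev = basal["f_ev"] if fev is None else fev
    dy = np.empty(K.N_STATES)
    fes_del = np.full(7, float(fes))
    K.rhs(np.asarray(state, dtype=float), pk, cycle_time, t_heart,
          fes_del, float(fev), dy)
    if not np.all(np.isfinite(dy)):
        raise FloatingPointError("non-finite compartment derivative")
    return dy


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationOutput:
    """Uniform-grid traces of one closed-loop simulation."""

    time: np.ndarray          # s
    sap: np.ndarray           # systemic arterial pressure, mmHg
    pap: np.ndarray           # pulmonary arterial pressure, mmHg
    p_lv: np.ndarray          # mmHg
    v_lv: np.ndarray          # ml
    p_la: np.ndarray          # mmHg
    t_heart: np.ndarray       # instantaneous (per-beat frozen) period, s
    valve_flows: pd.DataFrame  # mitral/aortic/tricuspid/pulmonic, ml/s
    volumes: pd.DataFrame     # per-compartment volumes, ml
    total_volume: np.ndarray  # ml
    beat_starts: np.ndarray   # indices into the time grid
    dt: float
    transient: float          # duration discarded before analysis, s
    steady_state_reached: bool

    @property
    def analysis_slice(self) -> slice:
        return slice(int(round(self.transient / self.dt)), len(self.time))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.time,
            "sap_mmHg": self.sap,
            "pap_mmHg": self.pap,
            "p_lv_mmHg": self.p_lv,
            "v_lv_ml": self.v_lv,
            "p_la_mmHg": self.p_la,
            "t_heart_s": self.t_heart,
            "total_volume_ml": self.total_volume,
        })
        for c in self.valve_flows.columns:
            df[c] = self.valve_flows[c].to_numpy()
        return df


def initial_state(p: CirculationParameters) -> tuple[np.ndarray, float, float]:
    """Basal-tone initial condition (volumes, flows, reflex states).

    Pressures are seeded near the normal operating point; the extrasplanchnic
    venous compartment absorbs the remaining volume so that the total equals
    ``total_blood_volume`` exactly.  Effector states start at their basal
    equilibria so the reflex introduces no startup transient of its own.
    """
    basal = baroreflex_update(p.baroreflex.p_n, p.baroreflex)
    y = np.zeros(K.N_STATES)
    y[K.S_X_EMAXLV] = basal["emax_lv"]
    y[K.S_X_EMAXRV] = basal["emax_rv"]
    y[K.S_X_RSP] = basal["r_sp"]
    y[K.S_X_REP] = basal["r_ep"]
    y[K.S_X_VUSV] = basal["vu_sv"]
    y[K.S_X_VUEV] = basal["vu_ev"]
    y[K.S_X_TS] = basal["period_sym"]
    y[K.S_X_TV] = basal["period_vagal"]

    c = p.compartments
    press = {
        "systemic_arteries": 92.0,
        "splanchnic_venous": 4.5,
        "right_atrium": 3.5,
        "pulmonary_arteries": 15.0,
        "pulmonary_peripheral": 10.0,
        "pulmonary_veins": 7.0,
        "left_atrium": 7.5,
    }
    y[K.S_V_SA] = c["systemic_arteries"].Vu + c["systemic_arteries"].C * press["systemic_arteries"]
    y[K.S_V_SPER] = (c["splanchnic_peripheral"].Vu + c["extrasplanchnic_peripheral"].Vu
                     + (c["splanchnic_peripheral"].C + c["extrasplanchnic_peripheral"].C) * 90.0)
    y[K.S_V_SV] = (c["splanchnic_venous"].Vu + y[K.S_X_VUSV]
                   + c["splanchnic_venous"].C * press["splanchnic_venous"])
    y[K.S_V_RA] = c["right_atrium"].Vu + c["right_atrium"].C * press["right_atrium"]
    y[K.S_V_PA] = c["pulmonary_arteries"].Vu + c["pulmonary_arteries"].C * press["pulmonary_arteries"]
    y[K.S_V_PP] = c["pulmonary_peripheral"].Vu + c["pulmonary_peripheral"].C * press["pulmonary_peripheral"]
    y[K.S_V_PV] = c["pulmonary_veins"].Vu + c["pulmonary_veins"].C * press["pulmonary_veins"]
    y[K.S_V_LA] = c["left_atrium"].Vu + c["left_atrium"].C * press["left_atrium"]
    y[K.S_V_LV] = 130.0
    y[K.S_V_RV] = 130.0
    assigned = (y[K.S_V_SA] + y[K.S_V_SPER] + y[K.S_V_SV] + y[K.S_V_RA]
                + y[K.S_V_PA] + y[K.S_V_PP] + y[K.S_V_PV] + y[K.S_V_LA]
                + y[K.S_V_LV] + y[K.S_V_RV])
    y[K.S_V_EV] = p.total_blood_volume - assigned
    if y[K.S_V_EV] <= 0:
        raise ValueError("total blood volume too small for initial distribution")

    y[K.S_Q_SA] = 0.0
    y[K.S_Q_PA] = 0.0
    y[K.S_PTILDE] = press["systemic_arteries"]
    return y, basal["f_es"], basal["f_ev"]


def simulate(p: CirculationParameters, duration: float = 20.0, dt: float = 0.002,
             transient: float = 10.0, steady_tol: float = 0.005
             ) -> SimulationOutput:
    """Run the regulated closed loop; deterministic for identical inputs."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration <= transient:
        raise ValueError("duration must exceed the transient window")
    pk = pack_parameters(p)
    y0, fes0, fev0 = initial_state(p)
    trace, beat_starts, n_beats, status, fail_step = K.integrate(
        pk, y0, duration, dt, fes0, fev0)
    if status != 0:
        t_fail = fail_step * dt
        vols = trace[-1, K.O_V_SA:K.O_V_LV + 1]
        names = ["systemic_arteries", "splanchnic_peripheral",
                 "extrasplanchnic_peripheral", "splanchnic_venous",
                 "extrasplanchnic_venous", "right_atrium", "right_ventricle",
                 "pulmonary_arteries", "pulmonary_peripheral",
                 "pulmonary_veins", "left_atrium", "left_ventricle"]
        bad = [n for n, v in zip(names, vols) if not np.isfinite(v)]
        raise FloatingPointError(
            f"non-finite state at t={t_fail:.3f}s"
            + (f" (compartments: {bad})" if bad else ""))

    flows = pd.DataFrame({
        "q_mitral_ml_s": trace[:, K.O_Q_MITRAL],
        "q_aortic_ml_s": trace[:, K.O_Q_AORTIC],
        "q_tricuspid_ml_s": trace[:, K.O_Q_TRICUSPID],
        "q_pulmonic_ml_s": trace[:, K.O_Q_PULMONIC],
    })
    volumes = pd.DataFrame({
        "systemic_arteries": trace[:, K.O_V_SA],
        "splanchnic_peripheral": trace[:, K.O_V_SP],
        "extrasplanchnic_peripheral": trace[:, K.O_V_EP],
        "splanchnic_venous": trace[:, K.O_V_SV],
        "extrasplanchnic_venous": trace[:, K.O_V_EV],
        "right_atrium": trace[:, K.O_V_RA],
        "right_ventricle": trace[:, K.O_V_RV],
        "pulmonary_arteries": trace[:, K.O_V_PA],
        "pulmonary_peripheral": trace[:, K.O_V_PP],
        "pulmonary_veins": trace[:, K.O_V_PV],
        "left_atrium": trace[:, K.O_V_LA],
        "left_ventricle": trace[:, K.O_V_LV],
    })

    out = SimulationOutput(
        time=trace[:, K.O_T],
        sap=trace[:, K.O_SAP],
        pap=trace[:, K.O_PAP],
        p_lv=trace[:, K.O_PLV],
        v_lv=trace[:, K.O_VLV],
        p_la=trace[:, K.O_PLA],
        t_heart=trace[:, K.O_THEART],
        valve_flows=flows,
        volumes=volumes,
        total_volume=trace[:, K.O_VTOT],
        beat_starts=np.asarray(beat_starts),
        dt=dt,
        transient=transient,
        steady_state_reached=False,
    )
    out.steady_state_reached = _steady_state(out, steady_tol)
    return out


def _steady_state(out: SimulationOutput, tol: float) -> bool:
    """Cycle-to-cycle MSAP stability over the analysis window."""
    start = int(round(out.transient / out.dt))
    beats = out.beat_starts[out.beat_starts >= start]
    if len(beats) < 3:
        return False
    msaps = []
    for b0, b1 in zip(beats[:-1], beats[1:]):
        msaps.append(float(np.mean(out.sap[b0:b1])))
    msaps = np.array(msaps)
    rel = np.abs(np.diff(msaps)) / np.abs(msaps[:-1])
    return bool(np.all(rel < tol))
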