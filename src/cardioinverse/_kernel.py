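"""Compiled core of the 0D circulation model.

Everything in this module operates on flat float64 arrays so that the whole
beat-by-beat integration loop can be jit-compiled.  The named-parameter layer
lives in :mod:`cardioinverse.circulation_model`; the index constants below are
the single source of truth for the packed parameter vector.

Units: pressure mmHg, volume ml, time s, flow ml/s throughout.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# packed parameter vector layout
# ---------------------------------------------------------------------------
(
    R_SA, C_SA, L_SA, VU_SA,
    R_SP0, C_SP, VU_SP,
    R_EP0, C_EP, VU_EP,
    R_SV, C_SV, VU_SV0,
    R_EV, C_EV, VU_EV0,
    R_PA, C_PA, L_PA, VU_PA,
    R_PP, C_PP, VU_PP,
    R_PV, C_PV, VU_PV,
    R_LA, C_LA, VU_LA,
    R_RA, C_RA, VU_RA,
    VTOT,
    EMAX_LV, EMAX0_LV, P0_LV, KE_LV, VU_LV, KR_LV, EMAX_NORM,
    EMAX0_RV, P0_RV, KE_RV, VU_RV, KR_RV,
    T0, T_MIN, T_MAX, TSYS0, KSYS,
    PN, KA, FAB_MIN, FAB_MAX, TAU_Z, TAU_P,
    FES_INF, FES_0, KES, FES_MIN,
    FEV_0, FEV_INF, FAB0, KEV,
    G_EMAXLV, D_EMAXLV, TAU_EMAXLV,
    G_EMAXRV, D_EMAXRV, TAU_EMAXRV,
    G_RSP, D_RSP, TAU_RSP,
    G_REP, D_REP, TAU_REP,
    G_VUSV, D_VUSV, TAU_VUSV,
    G_VUEV, D_VUEV, TAU_VUEV,
    G_TS, D_TS, TAU_TS,
    G_TV, D_TV, TAU_TV,
) = range(88)

N_PARAMS = 88

# state vector layout (continuous states integrated by RK4)
(
    S_V_SA, S_V_SPER, S_V_SV, S_V_EV, S_V_RA, S_V_RV,
    S_V_PA, S_V_PP, S_V_PV, S_V_LA, S_V_LV,
    S_Q_SA, S_Q_PA, S_PTILDE,
    S_X_EMAXLV, S_X_EMAXRV, S_X_RSP, S_X_REP,
    S_X_VUSV, S_X_VUEV, S_X_TS, S_X_TV,
) = range(22)

N_STATES = 22

# output trace columns
(
    O_T, O_SAP, O_PAP, O_PLV, O_VLV, O_PLA, O_THEART,
    O_Q_MITRAL, O_Q_AORTIC, O_Q_TRICUSPID, O_Q_PULMONIC,
    O_VTOT,
    O_V_SA, O_V_SP, O_V_EP, O_V_SV, O_V_EV, O_V_RA, O_V_RV,
    O_V_PA, O_V_PP, O_V_PV, O_V_LA, O_V_LV,
) = range(24)

N_OUT = 24


@njit(cache=False)
def activation(u, t_heart, tsys0, ksys):
    """Squared-sine ventricular activation.

    ``u`` is time since beat onset; systole spans ``[0, tsys)`` with
    ``tsys = tsys0 - ksys / t_heart``.  Returns a value in [0, 1], zero
    throughout diastole, reaching 1 exactly once per beat (mid-systole).
    """
    tsys = tsys0 - ksys / t_heart
    if u < 0.0 or u >= tsys:
        return 0.0
    s = np.sin(np.pi * u / tsys)
    return s * s


@njit(cache=False)
def isovolumic_pressure(v, phi, emax, ke, p0, vu):
    """Elastance/EDPVR mixture: phi*Emax*(V-Vu) + (1-phi)*P0*(exp(ke*V)-1)."""
    return phi * emax * (v - vu) + (1.0 - phi) * p0 * (np.exp(ke * v) - 1.0)


@njit(cache=False)
def valve_flow(p_up, p_down, r_valve):
    """Ideal-diode valve: Ohmic when the gradient is positive, else closed."""
    if p_up > p_down:
        return (p_up - p_down) / r_valve
    return 0.0


@njit(cache=False)
def afferent_firing(p_tilde, pn, ka, f_min, f_max):
    e = np.exp((p_tilde - pn) / ka)
    return (f_min + f_max * e) / (1.0 + e)


@njit(cache=False)
def sympathetic_activity(f_ab, fes_inf, fes_0, kes):
    return fes_inf + (fes_0 - fes_inf) * np.exp(-kes * f_ab)


@njit(cache=False)
def vagal_activity(f_ab, fev_0, fev_inf, fab0, kev):
    e = np.exp((f_ab - fab0) / kev)
    return (fev_0 + fev_inf * e) / (1.0 + e)


@njit(cache=False)
def sympathetic_drive(fes_delayed, fes_min):
    """Logarithmic static effector characteristic (zero below threshold)."""
    x = fes_delayed - fes_min
    if x < 0.0:
        x = 0.0
    return np.log(x + 1.0)


@njit(cache=False)
def rhs(y, p, u, t_heart, fes_del, fev_del, dy):
    """Time-derivatives of the 22 continuous states.

    fes_del: delayed sympathetic firing, one entry per sympathetic effector
    in the order (Emax_lv, Emax_rv, R_sp, R_ep, Vu_sv, Vu_ev, T_sym).
    fev_del: delayed vagal firing for the vagal period effector.
    Returns the systemic arterial pressure of this evaluation (convenience).
    """
    # regulated quantities from effector states
    r_sp = p[R_SP0] + y[S_X_RSP]
    r_ep = p[R_EP0] + y[S_X_REP]
    vu_sv = p[VU_SV0] + y[S_X_VUSV]
    vu_ev = p[VU_EV0] + y[S_X_VUEV]
    emax_lv = p[EMAX_LV] * (p[EMAX0_LV] + y[S_X_EMAXLV]) / p[EMAX_NORM]
    emax_rv = p[EMAX0_RV] + y[S_X_EMAXRV]

    # compartment pressures (linear compliances)
    p_sa = (y[S_V_SA] - p[VU_SA]) / p[C_SA]
    c_per = p[C_SP] + p[C_EP]
    p_per = (y[S_V_SPER] - p[VU_SP] - p[VU_EP]) / c_per
    p_sv = (y[S_V_SV] - vu_sv) / p[C_SV]
    p_ev = (y[S_V_EV] - vu_ev) / p[C_EV]
    p_ra = (y[S_V_RA] - p[VU_RA]) / p[C_RA]
    p_pa = (y[S_V_PA] - p[VU_PA]) / p[C_PA]
    p_pp = (y[S_V_PP] - p[VU_PP]) / p[C_PP]
    p_pv = (y[S_V_PV] - p[VU_PV]) / p[C_PV]
    p_la = (y[S_V_LA] - p[VU_LA]) / p[C_LA]

    # ventricles: isovolumic pressure, viscous ejection resistance
    phi = activation(u, t_heart, p[TSYS0], p[KSYS])
    pmax_lv = isovolumic_pressure(y[S_V_LV], phi, emax_lv, p[KE_LV], p[P0_LV], p[VU_LV])
    r_lv = p[KR_LV] * pmax_lv
    if r_lv < 1.0e-6:
        r_lv = 1.0e-6
    q_ao = valve_flow(pmax_lv, p_sa, r_lv)
    p_lv = pmax_lv - r_lv * q_ao

    pmax_rv = isovolumic_pressure(y[S_V_RV], phi, emax_rv, p[KE_RV], p[P0_RV], p[VU_RV])
    r_rv = p[KR_RV] * pmax_rv
    if r_rv < 1.0e-6:
        r_rv = 1.0e-6
    q_po = valve_flow(pmax_rv, p_pa, r_rv)
    p_rv = pmax_rv - r_rv * q_po

    q_mi = valve_flow(p_la, p_lv, p[R_LA])
    q_tr = valve_flow(p_ra, p_rv, p[R_RA])

    # resistive inter-compartment flows (bidirectional)
    q_sp = (p_per - p_sv) / r_sp
    q_ep = (p_per - p_ev) / r_ep
    q_sv = (p_sv - p_ra) / p[R_SV]
    q_ev = (p_ev - p_ra) / p[R_EV]
    q_pp = (p_pp - p_pv) / p[R_PP]
    q_pv = (p_pv - p_la) / p[R_PV]

    # mass conservation
    dy[S_V_SA] = q_ao - y[S_Q_SA]
    dy[S_V_SPER] = y[S_Q_SA] - q_sp - q_ep
    dy[S_V_SV] = q_sp - q_sv
    dy[S_V_EV] = q_ep - q_ev
    dy[S_V_RA] = q_sv + q_ev - q_tr
    dy[S_V_RV] = q_tr - q_po
    dy[S_V_PA] = q_po - y[S_Q_PA]
    dy[S_V_PP] = y[S_Q_PA] - q_pp
    dy[S_V_PV] = q_pp - q_pv
    dy[S_V_LA] = q_pv - q_mi
    dy[S_V_LV] = q_mi - q_ao

    # momentum balance on the inertial arterial branches
    dy[S_Q_SA] = (p_sa - p_per - p[R_SA] * y[S_Q_SA]) / p[L_SA]
    dy[S_Q_PA] = (p_pa - p_pp - p[R_PA] * y[S_Q_PA]) / p[L_PA]

    # afferent baroreceptor filter (static nonlinearity applied downstream)
    dp_sa = dy[S_V_SA] / p[C_SA]
    dy[S_PTILDE] = (p_sa + p[TAU_Z] * dp_sa - y[S_PTILDE]) / p[TAU_P]

    # first-order effectors driven by delayed efferent activity
    dy[S_X_EMAXLV] = (p[G_EMAXLV] * sympathetic_drive(fes_del[0], p[FES_MIN]) - y[S_X_EMAXLV]) / p[TAU_EMAXLV]
    dy[S_X_EMAXRV] = (p[G_EMAXRV] * sympathetic_drive(fes_del[1], p[FES_MIN]) - y[S_X_EMAXRV]) / p[TAU_EMAXRV]
    dy[S_X_RSP] = (p[G_RSP] * sympathetic_drive(fes_del[2], p[FES_MIN]) - y[S_X_RSP]) / p[TAU_RSP]
    dy[S_X_REP] = (p[G_REP] * sympathetic_drive(fes_del[3], p[FES_MIN]) - y[S_X_REP]) / p[TAU_REP]
    dy[S_X_VUSV] = (p[G_VUSV] * sympathetic_drive(fes_del[4], p[FES_MIN]) - y[S_X_VUSV]) / p[TAU_VUSV]
    dy[S_X_VUEV] = (p[G_VUEV] * sympathetic_drive(fes_del[5], p[FES_MIN]) - y[S_X_VUEV]) / p[TAU_VUEV]
    dy[S_X_TS] = (p[G_TS] * sympathetic_drive(fes_del[6], p[FES_MIN]) - y[S_X_TS]) / p[TAU_TS]
    dy[S_X_TV] = (p[G_TV] * fev_del - y[S_X_TV]) / p[TAU_TV]

    return p_sa


@njit(cache=False)
def _observe(y, p, u, t_heart, out_row, t):
    """Fill one output-trace row from the current state."""
    vu_sv = p[VU_SV0] + y[S_X_VUSV]
    vu_ev = p[VU_EV0] + y[S_X_VUEV]
    emax_lv = p[EMAX_LV] * (p[EMAX0_LV] + y[S_X_EMAXLV]) / p[EMAX_NORM]
    emax_rv = p[EMAX0_RV] + y[S_X_EMAXRV]

    p_sa = (y[S_V_SA] - p[VU_SA]) / p[C_SA]
    c_per = p[C_SP] + p[C_EP]
    p_per = (y[S_V_SPER] - p[VU_SP] - p[VU_EP]) / c_per
    p_pa = (y[S_V_PA] - p[VU_PA]) / p[C_PA]
    p_la = (y[S_V_LA] - p[VU_LA]) / p[C_LA]
    p_ra = (y[S_V_RA] - p[VU_RA]) / p[C_RA]

    phi = activation(u, t_heart, p[TSYS0], p[KSYS])
    pmax_lv = isovolumic_pressure(y[S_V_LV], phi, emax_lv, p[KE_LV], p[P0_LV], p[VU_LV])
    r_lv = p[KR_LV] * pmax_lv
    if r_lv < 1.0e-6:
        r_lv = 1.0e-6
    q_ao = valve_flow(pmax_lv, p_sa, r_lv)
    p_lv = pmax_lv - r_lv * q_ao

    pmax_rv = isovolumic_pressure(y[S_V_RV], phi, emax_rv, p[KE_RV], p[P0_RV], p[VU_RV])
    r_rv = p[KR_RV] * pmax_rv
    if r_rv < 1.0e-6:
        r_rv = 1.0e-6
    q_po = valve_flow(pmax_rv, p_pa, r_rv)
    p_rv = pmax_rv - r_rv * q_po

    out_row[O_T] = t
    out_row[O_SAP] = p_sa
    out_row[O_PAP] = p_pa
    out_row[O_PLV] = p_lv
    out_row[O_VLV] = y[S_V_LV]
    out_row[O_PLA] = p_la
    out_row[O_THEART] = t_heart
    out_row[O_Q_MITRAL] = valve_flow(p_la, p_lv, p[R_LA])
    out_row[O_Q_AORTIC] = q_ao
    out_row[O_Q_TRICUSPID] = valve_flow(p_ra, p_rv, p[R_RA])
    out_row[O_Q_PULMONIC] = q_po
    # split the shared peripheral node back into its two compartments
    v_sp = p[VU_SP] + p[C_SP] * p_per
    v_ep = p[VU_EP] + p[C_EP] * p_per
    out_row[O_V_SA] = y[S_V_SA]
    out_row[O_V_SP] = v_sp
    out_row[O_V_EP] = v_ep
    out_row[O_V_SV] = y[S_V_SV]
    out_row[O_V_EV] = y[S_V_EV]
    out_row[O_V_RA] = y[S_V_RA]
    out_row[O_V_RV] = y[S_V_RV]
    out_row[O_V_PA] = y[S_V_PA]
    out_row[O_V_PP] = y[S_V_PP]
    out_row[O_V_PV] = y[S_V_PV]
    out_row[O_V_LA] = y[S_V_LA]
    out_row[O_V_LV] = y[S_V_LV]
    vtot = (y[S_V_SA] + v_sp + v_ep + y[S_V_SV] + y[S_V_EV] + y[S_V_RA]
            + y[S_V_RV] + y[S_V_PA] + y[S_V_PP] + y[S_V_PV] + y[S_V_LA]
            + y[S_V_LV])
    out_row[O_VTOT] = vtot


@njit(cache=False)
def integrate(p, y0, duration, dt, fes0, fev0):
    """Fixed-step RK4 integration of the regulated closed loop.

    Delayed efferent activities are read from on-grid ring buffers (pure
    delays rounded to the step); the heart period is frozen within each beat.

    Returns (trace, beat_starts, n_beats, status, fail_step) where status is
    0 on success and 1 if a non-finite state was produced.
    """
    n_steps = int(np.round(duration / dt))
    trace = np.empty((n_steps + 1, N_OUT))
    beat_starts = np.empty(n_steps + 2, dtype=np.int64)

    fes_hist = np.empty(n_steps + 1)
    fev_hist = np.empty(n_steps + 1)
    fes_hist[0] = fes0
    fev_hist[0] = fev0

    lags = np.empty(7, dtype=np.int64)
    lags[0] = int(np.round(p[D_EMAXLV] / dt))
    lags[1] = int(np.round(p[D_EMAXRV] / dt))
    lags[2] = int(np.round(p[D_RSP] / dt))
    lags[3] = int(np.round(p[D_REP] / dt))
    lags[4] = int(np.round(p[D_VUSV] / dt))
    lags[5] = int(np.round(p[D_VUEV] / dt))
    lags[6] = int(np.round(p[D_TS] / dt))
    lag_tv = int(np.round(p[D_TV] / dt))

    y = y0.copy()
    k1 = np.empty(N_STATES)
    k2 = np.empty(N_STATES)
    k3 = np.empty(N_STATES)
    k4 = np.empty(N_STATES)
    yt = np.empty(N_STATES)
    fes_del = np.empty(7)

    # heart period frozen at beat onset
    t_heart = p[T0] + y[S_X_TS] + y[S_X_TV]
    if t_heart < p[T_MIN]:
        t_heart = p[T_MIN]
    if t_heart > p[T_MAX]:
        t_heart = p[T_MAX]
    u = 0.0
    n_beats = 0
    beat_starts[n_beats] = 0
    n_beats += 1

    _observe(y, p, u, t_heart, trace[0], 0.0)

    for n in range(n_steps):
        t = n * dt
        for j in range(7):
            idx = n - lags[j]
            if idx < 0:
                idx = 0
            fes_del[j] = fes_hist[idx]
        idx = n - lag_tv
        if idx < 0:
            idx = 0
        fev_del = fev_hist[idx]

        rhs(y, p, u, t_heart, fes_del, fev_del, k1)
        for i in range(N_STATES):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        rhs(yt, p, u + 0.5 * dt, t_heart, fes_del, fev_del, k2)
        for i in range(N_STATES):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        rhs(yt, p, u + 0.5 * dt, t_heart, fes_del, fev_del, k3)
        for i in range(N_STATES):
            yt[i] = y[i] + dt * k3[i]
        rhs(yt, p, u + dt, t_heart, fes_del, fev_del, k4)
        ok = True
        for i in range(N_STATES):
            y[i] = y[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not np.isfinite(y[i]):
                ok = False
        if not ok:
            return trace[: n + 1], beat_starts[:n_beats], n_beats, 1, n

        u += dt
        if u >= t_heart:
            u -= t_heart
            t_heart = p[T0] + y[S_X_TS] + y[S_X_TV]
            if t_heart < p[T_MIN]:
                t_heart = p[T_MIN]
            if t_heart > p[T_MAX]:
                t_heart = p[T_MAX]
            beat_starts[n_beats] = n + 1
            n_beats += 1

        # efferent activities from the freshly advanced afferent state
        f_ab = afferent_firing(y[S_PTILDE], p[PN], p[KA], p[FAB_MIN], p[FAB_MAX])
        fes_hist[n + 1] = sympathetic_activity(f_ab, p[FES_INF], p[FES_0], p[KES])
        fev_hist[n + 1] = vagal_activity(f_ab, p[FEV_0], p[FEV_INF], p[FAB0], p[KEV])

        _observe(y, p, u, t_heart, trace[n + 1], (n + 1) * dt)

    return trace, beat_starts[:n_beats], n_beats, 0, n_steps
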