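"""Lumped-parameter (0-D) digital twin of the left-heart pulse duplicator.

The physical rig is a piston pump driving a rigid left ventricle (LV) that
carries an air-filled compliance chamber, ejecting through an aortic valve
into a reservoir that drains back into a high-compliance left atrium (LA)
through a peripheral resistance; the mitral valve sits between LA and LV.
The twin mirrors that topology with three pressure states (LV, LA,
reservoir):

* the piston imposes a prescribed flow — half-sine ejection and filling
  lobes, each integrating to the set stroke volume;
* both valves are quadratic (Bernoulli) orifices with separate forward and
  regurgitant effective areas, i.e. pressure-controlled diodes;
* the LV pressure is generated by an isothermal ideal-gas pocket of
  reference volume ``cv_ml`` (plus a small parasitic linear compliance that
  represents wall/tubing elasticity and keeps the rigid ``cv_ml = 0`` case
  well-posed);
* the reservoir is a single-compartment Windkessel; the LA is a large
  linear compliance around its baseline pressure.

Integration is fixed-step classical Runge–Kutta (RK4), which keeps the
solution bit-reproducible for a given configuration and seed.  Sensor
streams are linearly resampled onto the nominal sampling grid and Gaussian
sensor noise is added from a seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import RigConfig

MMHG_TO_PA = 133.322

#: Parasitic linear LV compliance, ml/mmHg (wall/tubing elasticity; keeps
#: the pressure ODE well-posed when the air pocket is absent).
PARASITIC_COMPLIANCE_ML_PER_MMHG = 0.02

#: Left-atrial compliance, ml/mmHg (the LA is a large, nearly isobaric bag).
LA_COMPLIANCE_ML_PER_MMHG = 40.0

#: Pressure-smoothing scale of the orifice law, mmHg (regularizes the
#: square-root singularity at zero gradient).
ORIFICE_SMOOTHING_MMHG = 1.0


class SimulationError(RuntimeError):
    """Raised when the integration leaves the physical regime."""


def pump_flow(t: float | np.ndarray, config: RigConfig) -> float | np.ndarray:
    """Piston flow (ml/s, positive into the LV) at time ``t`` seconds.

    The waveform is periodic with period ``60/hr_bpm``: a half-sine ejection
    lobe occupying ``systolic_fraction`` of the cycle and integrating to
    ``+sv_pump_ml``, followed by a half-sine filling lobe integrating to
    ``-sv_pump_ml``.  Continuous everywhere (zero at the lobe boundaries).
    """
    period = config.period_s
    t_sys = config.systolic_fraction * period
    t_dia = period - t_sys
    q_ej = 0.5 * math.pi * config.sv_pump_ml / t_sys
    q_fill = 0.5 * math.pi * config.sv_pump_ml / t_dia
    tau = np.asarray(t) % period
    out = np.where(
        tau < t_sys,
        q_ej * np.sin(np.pi * tau / t_sys),
        -q_fill * np.sin(np.pi * (tau - t_sys) / t_dia),
    )
    if np.ndim(t) == 0:
        return float(out)
    return out


def orifice_flow(
    dp_mmhg: float | np.ndarray,
    area_cm2: float,
    rho_kg_m3: float = 1060.0,
    smoothing_mmhg: float = ORIFICE_SMOOTHING_MMHG,
) -> float | np.ndarray:
    """Quadratic-orifice (Bernoulli) flow in ml/s through ``area_cm2``.

    ``|Q| = A * sqrt(2 |dp| / rho)`` with the sign of the pressure drop; the
    square root is smoothly regularized near ``dp = 0`` (scale
    ``smoothing_mmhg``) so the valve law is Lipschitz for the integrator.
    """
    if area_cm2 < 0:
        raise ValueError("orifice area must be non-negative")
    k = 100.0 * math.sqrt(2.0 * MMHG_TO_PA / rho_kg_m3)
    dp = np.asarray(dp_mmhg, dtype=float)
    q = area_cm2 * k * dp / (dp * dp + smoothing_mmhg**2) ** 0.25
    if np.ndim(dp_mmhg) == 0:
        return float(q)
    return q


def ideal_gas_pocket(v_ref_ml: float, p_ref_abs_mmhg: float, p_abs_mmhg: float) -> float:
    """Isothermal air volume (ml) of the compliance pocket at ``p_abs_mmhg``.

    Boyle's law: a pocket holding ``v_ref_ml`` at ``p_ref_abs_mmhg`` occupies
    ``v_ref * p_ref / p`` at pressure ``p``.  The compressed (fluid-absorbed)
    volume relative to the reference is ``v_ref - ideal_gas_pocket(...)``.
    """
    if v_ref_ml < 0:
        raise ValueError("reference volume must be non-negative")
    if p_ref_abs_mmhg <= 0 or p_abs_mmhg <= 0:
        raise ValueError("absolute pressures must be positive")
    if v_ref_ml == 0:
        return 0.0
    return v_ref_ml * p_ref_abs_mmhg / p_abs_mmhg


@dataclass
class SensorStream:
    """Uniformly sampled pressure/flow record, as the rig's sensors report it.

    Pressures are absolute (mmHg); aortic flow is positive from the LV to
    the reservoir (ml/s).
    """

    t: np.ndarray
    p_la_abs: np.ndarray
    p_lv_abs: np.ndarray
    q_aortic: np.ndarray
    fs_hz: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ValueError("a sensor stream needs at least two samples")
        for name in ("p_la_abs", "p_lv_abs", "q_aortic"):
            if len(getattr(self, name)) != n:
                raise ValueError("all series must have equal length")
        dt = np.diff(self.t)
        if np.any(np.abs(dt - 1.0 / self.fs_hz) > 1e-6):
            raise ValueError("time grid is not uniform at fs_hz")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "p_la_mmhg": self.p_la_abs,
                "p_lv_mmhg": self.p_lv_abs,
                "q_ao_ml_s": self.q_aortic,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fs_hz: float | None = None) -> "SensorStream":
        df = pd.read_csv(path)
        required = {"t_s", "p_la_mmhg", "p_lv_mmhg", "q_ao_ml_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        t = df["t_s"].to_numpy(float)
        if fs_hz is None:
            fs_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(
            t=t,
            p_la_abs=df["p_la_mmhg"].to_numpy(float),
            p_lv_abs=df["p_lv_mmhg"].to_numpy(float),
            q_aortic=df["q_ao_ml_s"].to_numpy(float),
            fs_hz=fs_hz,
            meta={"source": str(path)},
        )


@dataclass
class GroundTruth:
    """Per-cycle volumes from the noise-free fine-step solution.

    ``compliance_absorbed_ml`` is the pocket volume the piston received back
    instead of ejecting: the piston withdrawal before the mitral valve
    opens plus the pocket volume still stored at mitral opening.  With that
    bookkeeping each steady-state cycle satisfies
    ``sv_pump = aortic + mitral_backflow + compliance_absorbed`` up to
    integration error.
    """

    mitral_backflow_ml: np.ndarray
    aortic_ml: np.ndarray
    compliance_absorbed_ml: np.ndarray
    sv_pump_ml: float

    @property
    def n_cycles(self) -> int:
        return len(self.mitral_backflow_ml)

    def conservation_residual_ml(self) -> np.ndarray:
        """Per-cycle ``sv_pump - (aortic + backflow + absorbed)``."""
        return self.sv_pump_ml - (
            self.aortic_ml + self.mitral_backflow_ml + self.compliance_absorbed_ml
        )


def _integrate(config: RigConfig) -> tuple[np.ndarray, ...]:
    """Fixed-step RK4 integration on the fine grid, transient included."""
    period = config.period_s
    t_sys = config.systolic_fraction * period
    t_dia = period - t_sys
    dt = config.dt_s
    cv = config.cv_ml
    p_ref = config.p_atm_mmhg + config.p_la_baseline_mmhg
    c_par = PARASITIC_COMPLIANCE_ML_PER_MMHG
    c_la = LA_COMPLIANCE_ML_PER_MMHG
    c_res = config.c_reservoir_ml_per_mmhg
    r_per = config.r_peripheral_mmhg_s_per_ml
    eps2 = ORIFICE_SMOOTHING_MMHG**2
    k = 100.0 * math.sqrt(2.0 * MMHG_TO_PA / config.rho_kg_m3)
    a_mv_fwd = config.mv_forward_area_cm2
    a_mv_back = config.mv_ero_cm2
    a_av_fwd = config.av_area_cm2
    a_av_back = config.av_leak_area_cm2
    q_ej = 0.5 * math.pi * config.sv_pump_ml / t_sys
    q_fill = 0.5 * math.pi * config.sv_pump_ml / t_dia

    transient_cycles = max(3, int(math.ceil(4.0 * r_per * c_res / period)) + 3)
    n_cycles = transient_cycles + max(1, int(round(config.duration_s / period)))
    n_steps = int(round(n_cycles * period / dt))

    sin = math.sin
    pi = math.pi

    def qpump(t: float) -> float:
        tau = t - period * int(t / period)
        if tau < t_sys:
            return q_ej * sin(pi * tau / t_sys)
        return -q_fill * sin(pi * (tau - t_sys) / t_dia)

    def deriv(t: float, plv: float, pla: float, pres: float):
        dp_mv = pla - plv
        a = a_mv_fwd if dp_mv > 0.0 else a_mv_back
        qmv = a * k * dp_mv / (dp_mv * dp_mv + eps2) ** 0.25
        dp_ao = plv - pres
        a = a_av_fwd if dp_ao > 0.0 else a_av_back
        qao = a * k * dp_ao / (dp_ao * dp_ao + eps2) ** 0.25
        qper = (pres - pla) / r_per
        c_lv = cv * p_ref / (plv * plv) + c_par
        return (
            (qpump(t) + qmv - qao) / c_lv,
            (qper - qmv) / c_la,
            (qao - qper) / c_res,
            qmv,
            qao,
        )

    plv = p_ref
    pla = p_ref
    pres = config.p_atm_mmhg + 60.0

    rec = np.empty((n_steps + 1, 6))
    t = 0.0
    half = dt / 2.0
    sixth = dt / 6.0
    for i in range(n_steps + 1):
        d1 = deriv(t, plv, pla, pres)
        rec[i, 0] = t
        rec[i, 1] = plv
        rec[i, 2] = pla
        rec[i, 3] = pres
        rec[i, 4] = d1[3]
        rec[i, 5] = d1[4]
        d2 = deriv(t + half, plv + half * d1[0], pla + half * d1[1], pres + half * d1[2])
        d3 = deriv(t + half, plv + half * d2[0], pla + half * d2[1], pres + half * d2[2])
        d4 = deriv(t + dt, plv + dt * d3[0], pla + dt * d3[1], pres + dt * d3[2])
        plv += sixth * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
        pla += sixth * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
        pres += sixth * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2])
        t += dt
        if not (math.isfinite(plv) and math.isfinite(pla) and math.isfinite(pres)) or (
            abs(plv) > 5000.0 or plv <= 0.0
        ):
            raise SimulationError(
                f"integration unstable at t={t:.4f} s (P_LV={plv!r} mmHg); "
                "check dt_s against valve areas and compliances "
                f"(dt_s={dt}, av_area_cm2={a_av_fwd}, cv_ml={cv})"
            )

    i_keep = int(round(transient_cycles * period / dt))
    rec = rec[i_keep:]
    rec[:, 0] -= rec[0, 0]
    return rec, transient_cycles


def _ground_truth(rec: np.ndarray, config: RigConfig) -> GroundTruth:
    t, plv = rec[:, 0], rec[:, 1]
    qmv, qao = rec[:, 4], rec[:, 5]
    dt = config.dt_s
    period = config.period_s
    t_sys = config.systolic_fraction * period
    p_ref = config.p_atm_mmhg + config.p_la_baseline_mmhg
    n_cycles = int(round(t[-1] / period))

    # Stored (fluid) volume in the LV compartment vs the reference state:
    # pocket compression plus the parasitic linear store.
    v_stored = (
        config.cv_ml * (1.0 - p_ref / plv)
        + PARASITIC_COMPLIANCE_ML_PER_MMHG * (plv - p_ref)
    )

    q_pump = pump_flow(t, config)

    back = np.empty(n_cycles)
    aortic = np.empty(n_cycles)
    absorbed = np.empty(n_cycles)
    steps_per_cycle = int(round(period / dt))
    steps_sys = int(round(t_sys / dt))
    for kk in range(n_cycles):
        i0 = kk * steps_per_cycle
        i1 = min((kk + 1) * steps_per_cycle, len(t) - 1)
        back[kk] = np.trapezoid(np.maximum(-qmv[i0 : i1 + 1], 0.0), dx=dt)
        aortic[kk] = np.trapezoid(qao[i0 : i1 + 1], dx=dt)
        # Mitral opening: first forward mitral flow after the ejection lobe.
        seg = qmv[i0 + steps_sys : i1 + 1]
        rel = int(np.argmax(seg > 0.0)) if np.any(seg > 0.0) else len(seg) - 1
        i_open = i0 + steps_sys + rel
        withdrawal = np.trapezoid(np.maximum(-q_pump[i0 : i_open + 1], 0.0), dx=dt)
        absorbed[kk] = (v_stored[i_open] - v_stored[i0]) + withdrawal
    return GroundTruth(
        mitral_backflow_ml=back,
        aortic_ml=aortic,
        compliance_absorbed_ml=absorbed,
        sv_pump_ml=config.sv_pump_ml,
    )


def simulate(config: RigConfig) -> tuple[SensorStream, GroundTruth]:
    """Run the twin and return its sensor streams and per-cycle ground truth.

    The internal solution uses a fine fixed step ``dt_s``; an initial
    transient (at least three cycles, longer when the Windkessel time
    constant demands it) is discarded before anything is reported.  The
    sensor streams are linearly resampled to ``fs_hz`` and carry additive
    Gaussian noise from a generator seeded with ``config.seed``, so a given
    configuration is bit-reproducible.
    """
    rec, transient_cycles = _integrate(config)
    truth = _ground_truth(rec, config)

    n_out = int(math.floor(config.duration_s * config.fs_hz)) + 1
    t_out = np.arange(n_out) / config.fs_hz
    t_out = t_out[t_out <= rec[-1, 0] + 1e-12]
    p_la = np.interp(t_out, rec[:, 0], rec[:, 2])
    p_lv = np.interp(t_out, rec[:, 0], rec[:, 1])
    q_ao = np.interp(t_out, rec[:, 0], rec[:, 5])

    rng = np.random.default_rng(config.seed)
    if config.noise_sd_mmhg > 0.0:
        p_la = p_la + rng.normal(0.0, config.noise_sd_mmhg, len(t_out))
        p_lv = p_lv + rng.normal(0.0, config.noise_sd_mmhg, len(t_out))
    if config.noise_sd_ml_s > 0.0:
        q_ao = q_ao + rng.normal(0.0, config.noise_sd_ml_s, len(t_out))

    stream = SensorStream(
        t=t_out,
        p_la_abs=p_la,
        p_lv_abs=p_lv,
        q_aortic=q_ao,
        fs_hz=config.fs_hz,
        meta={
            "config": config.model_dump(),
            "seed": config.seed,
            "transient_cycles_discarded": transient_cycles,
            "noise_free": config.noise_sd_mmhg == 0.0 and config.noise_sd_ml_s == 0.0,
        },
    )
    return stream, truth


class CalibrationError(RuntimeError):
    """Raised when the afterload cannot reach the requested pressure."""


def calibrate_afterload(
    config: RigConfig,
    sbp_target_mmhg: float,
    tol_mmhg: float = 3.0,
    r_bounds: tuple[float, float] = (0.05, 6.0),
    max_iter: int = 40,
) -> RigConfig:
    """Tune the peripheral resistance so the measured SBP hits the target.

    Mirrors the bench procedure of adjusting the afterload until the
    competent valve produces the desired systolic pressure.  Measurement
    uses the same beat pipeline as any external recording, on short
    noise-free runs; the search is a bisection (SBP is monotone in the
    peripheral resistance), so the result is deterministic.
    """
    if sbp_target_mmhg <= 0:
        raise ValueError("sbp_target_mmhg must be positive")

    from .beats import measure_sbp  # local import to avoid a cycle

    probe = config.replace(noise_sd_mmhg=0.0, noise_sd_ml_s=0.0, duration_s=8.0)

    def measured_sbp(r: float) -> float:
        stream, _ = simulate(probe.replace(r_peripheral_mmhg_s_per_ml=r))
        return measure_sbp(stream, p_atm=config.p_atm_mmhg,
                           expected_hr=config.hr_bpm)

    current = measured_sbp(config.r_peripheral_mmhg_s_per_ml)
    if abs(current - sbp_target_mmhg) <= tol_mmhg:
        return config

    lo, hi = r_bounds
    s_lo, s_hi = measured_sbp(lo), measured_sbp(hi)
    if not (s_lo <= sbp_target_mmhg <= s_hi):
        raise CalibrationError(
            f"SBP target {sbp_target_mmhg} mmHg outside reachable bracket "
            f"[{s_lo:.1f}, {s_hi:.1f}] mmHg for r_peripheral in {r_bounds}"
        )
    r = config.r_peripheral_mmhg_s_per_ml
    for _ in range(max_iter):
        r = 0.5 * (lo + hi)
        s = measured_sbp(r)
        if abs(s - sbp_target_mmhg) <= 0.5 * tol_mmhg:
            break
        if s < sbp_target_mmhg:
            lo = r
        else:
            hi = r
    else:
        s = measured_sbp(r)
        if abs(s - sbp_target_mmhg) > tol_mmhg:
            raise CalibrationError(
                f"calibration did not converge: measured {s:.1f} mmHg vs "
                f"target {sbp_target_mmhg} mmHg after {max_iter} iterations"
            )
    return config.replace(r_peripheral_mmhg_s_per_ml=r)
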