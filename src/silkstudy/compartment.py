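"""Forward model of Abeta40 production, turnover and CSF transport.

Five well-mixed compartments carry soluble Abeta40: brain interstitial fluid
(ISF), the ventricles, the cisternal, cranial and spinal subarachnoid space
(SAS).  Abeta40 enters the ISF at rate ``f_ab40 * R_APP`` (nmol/h), split
between labeled and unlabeled species by the plasma leucine enrichment through
:func:`labeled_production_fraction`.  Processes:

* ISF loss at ``k_BPD40 * C_ISF`` (proteolysis + blood-brain barrier efflux,
  lumped first order),
* ISF -> ventricular solute transport as an equivalent flow
  ``k_t * (C_ISF - C_V)``,
* bulk CSF flow ``Q_CSF`` ventricles -> cisterna, splitting into
  ``phi_CR * Q_CSF`` (cisterna -> cranial SAS -> absorption) and
  ``(1 - phi_CR) * Q_CSF + Q_leak`` (cisterna -> spinal SAS), with spinal
  efflux ``(1 - phi_CR) * Q_CSF`` (absorption) plus ``Q_leak`` (catheter
  leak),
* oscillatory mixing as a symmetric exchange flow ``Q_osc`` on the
  cisterna-cranial and cisterna-spinal connections,
* each scheduled lumbar draw displaces ``draw_volume`` mL along the advective
  chain instantaneously: spinal CSF is replaced from the cisternal side
  (``C_SP += (draw/V_SP) * (C_CIS - C_SP)``), cisternal from the ventricular
  side, and ventricular volume is made up by freshly produced, solute-free
  CSF — so serial sampling strictly depletes CSF solute, as observed for
  bi-hourly 6 mL draws.

The system is linear and time-invariant for a fixed parameter set, so the
simulator propagates the state exactly with matrix exponentials over a fine
node grid, treating the labeled-production forcing as piecewise linear
between nodes.  This is deterministic and fast enough to sit inside the
128-combination grid fit; tests cross-check it against an adaptive ODE
integration of the same right-hand side.

Measured lumbar concentration is ``SF_40`` times the spinal total (labeled +
unlabeled) concentration, converted to pg/mL; SF_40 cancels in the labeled
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import expm

from .config import defaults_view, volume_coefficients
from .data_model import SampleSchedule, ValidationError

# state ordering for all 5-vectors / matrices
ISF, VENT, CIS, CRA, SPI = range(5)
COMPARTMENTS = ("ISF", "ventricular", "cisternal", "cranial_sas", "spinal_sas")


class ParameterError(ValueError):
    """A kinetic parameter violates an admissibility constraint."""


@dataclass(frozen=True)
class KineticParameters:
    """Full parameter vector of the Abeta40 transport model.

    Adjustable in the fit: k_bpd40, sf40, q_csf, q_osc (and r_app, profiled).
    Systematically varied on the grid: f_vcsf, v_sp, q_leak.
    The rest are structural constants from the packaged config.
    """

    r_app: float          # APP production rate, nmol/h
    f_ab40: float         # fraction of APP yielding Abeta40
    tau_delay: float      # labeling/processing delay, h
    k_bpd40: float        # first-order ISF clearance, 1/h
    sf40: float           # measurement scaling factor
    q_csf: float          # CSF production/clearance flow, mL/h
    q_osc: float          # SAS mixing exchange flow, mL/h
    q_leak: float         # catheter leak flow, mL/h
    f_vcsf: float         # CSF-volume error multiplier
    v_sp: float           # spinal SAS volume, mL
    phi_cr: float         # fraction of CSF absorbed via cranial SAS
    k_t: float            # ISF -> ventricular transport equivalent flow, mL/h
    v_isf: float          # ISF volume, mL
    v_v: float            # ventricular volume, mL
    v_cis: float          # cisternal volume, mL
    v_cr: float           # cranial SAS volume, mL
    n_leu: int = 1

    def validate(self) -> None:
        for name in ("r_app", "f_ab40", "k_bpd40", "sf40", "q_csf", "q_osc",
                     "q_leak", "f_vcsf", "v_sp", "k_t", "v_isf", "v_v",
                     "v_cis", "v_cr"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if not (0.05 <= self.k_bpd40 <= 0.35):
            raise ParameterError(
                f"k_bpd40 {self.k_bpd40:g} outside admissible [0.05, 0.35]")
        if not (0 < self.phi_cr < 1):
            raise ParameterError("phi_cr must lie in (0, 1)")
        if not self.sf40 > 0:
            raise ParameterError("sf40 must be positive")
        for name in ("v_sp", "v_isf", "v_v", "v_cis", "v_cr"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")

    @property
    def volumes(self) -> np.ndarray:
        return np.array([self.v_isf, self.v_v, self.v_cis, self.v_cr,
                         self.v_sp])

    @classmethod
    def default(cls, age: float = 70.0, **overrides) -> "KineticParameters":
        d = defaults_view()
        st, nom = d["structure"], d["nominal"]
        f_vcsf = overrides.pop("f_vcsf", 1.0)
        v_v, v_cis, v_cr = estimate_csf_volumes(age, f_vcsf)
        base = dict(
            r_app=nom["r_app_nmol_per_h"],
            f_ab40=st["f_ab40"], tau_delay=st["tau_delay_h"],
            k_bpd40=nom["k_bpd40_per_h"], sf40=nom["sf40"],
            q_csf=nom["q_csf_mL_per_h"], q_osc=nom["q_osc_mL_per_h"],
            q_leak=0.0, f_vcsf=f_vcsf, v_sp=70.0,
            phi_cr=st["phi_cranial"], k_t=st["k_t_mL_per_h"],
            v_isf=st["v_isf_mL"], v_v=v_v, v_cis=v_cis, v_cr=v_cr,
            n_leu=st["n_leu"],
        )
        base.update(overrides)
        return cls(**base)


def estimate_csf_volumes(age: float, f_vcsf: float,
                         coefficients: dict | None = None):
    """Age-linear ventricular, cisternal and cranial-SAS volumes (mL).

    Each volume is ``f_vcsf * (a + b * age)``; the default coefficients live
    in the packaged config and total ~150 mL at age 70 with ``f_vcsf = 1``.
    """
    if not (40 <= age <= 100):
        raise ParameterError(f"age {age:g} outside supported [40, 100]")
    coeffs = coefficients or volume_coefficients()
    vols = tuple(f_vcsf * (a + b * age)
                 for a, b in (coeffs["ventricular"], coeffs["cisternal"],
                              coeffs["cranial_sas"]))
    if any(v <= 0 for v in vols):
        raise ParameterError(
            f"nonpositive CSF volume from f_vcsf={f_vcsf:g} at age {age:g}")
    return vols


@dataclass(frozen=True)
class EnrichmentCurve:
    """Plasma leucine labeled mole fraction vs time (h); 0 before t=0."""

    times: np.ndarray
    enrichment: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, float)
        e = np.asarray(self.enrichment, float)
        if np.any((e < 0) | (e > 1)):
            raise ValidationError("enrichment must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "enrichment", e)

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, float), self.times, self.enrichment,
                         left=0.0, right=float(self.enrichment[-1]))

    @classmethod
    def zero(cls) -> "EnrichmentCurve":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 0.0]))


def labeled_production_fraction(enrichment: EnrichmentCurve, t, tau_delay: float,
                                n_leu: int = 1) -> np.ndarray:
    """Probability that an Abeta molecule made from leucine enriched at
    ``t - tau_delay`` carries at least one label: 1 - (1 - e)^n_leu."""
    t = np.asarray(t, float)
    e = np.where(t - tau_delay >= 0, enrichment(t - tau_delay), 0.0)
    return 1.0 - (1.0 - e) ** n_leu


def system_matrix(p: KineticParameters) -> np.ndarray:
    """Jacobian A of the concentration ODE dC/dt = A C + production."""
    q_sp = (1.0 - p.phi_cr) * p.q_csf + p.q_leak   # cisterna -> spinal flow
    q_cr = p.phi_cr * p.q_csf                      # cisterna -> cranial flow
    A = np.zeros((5, 5))
    # ISF
    A[ISF, ISF] = -(p.k_bpd40 * p.v_isf + p.k_t) / p.v_isf
    A[ISF, VENT] = p.k_t / p.v_isf
    # ventricles
    A[VENT, ISF] = p.k_t / p.v_v
    A[VENT, VENT] = -(p.k_t + p.q_csf) / p.v_v
    # cisterna
    A[CIS, VENT] = p.q_csf / p.v_cis
    A[CIS, CIS] = -(q_cr + q_sp + 2.0 * p.q_osc) / p.v_cis
    A[CIS, CRA] = p.q_osc / p.v_cis
    A[CIS, SPI] = p.q_osc / p.v_cis
    # cranial SAS (flow-through absorption)
    A[CRA, CIS] = (q_cr + p.q_osc) / p.v_cr
    A[CRA, CRA] = -(q_cr + p.q_osc) / p.v_cr
    # spinal SAS (absorption + leak efflux)
    A[SPI, CIS] = (q_sp + p.q_osc) / p.v_sp
    A[SPI, SPI] = -(q_sp + p.q_osc) / p.v_sp
    return A


def production_vector(p: KineticParameters, rate_nmol_h: float) -> np.ndarray:
    """Concentration source term (nmol/mL/h) for a given production rate."""
    u = np.zeros(5)
    u[ISF] = rate_nmol_h / p.v_isf
    return u


def steady_state(p: KineticParameters) -> np.ndarray:
    """Pre-infusion unlabeled concentrations (nmol/mL): solve A c = -u."""
    p.validate()
    prod = p.f_ab40 * p.r_app
    if prod == 0.0:
        return np.zeros(5)
    A = system_matrix(p)
    u = production_vector(p, prod)
    try:
        c = np.linalg.solve(A, -u)
    except np.linalg.LinAlgError as exc:
        raise ParameterError("singular transport system: production cannot "
                             "be cleared") from exc
    if np.any(c < -1e-12 * max(1.0, np.abs(c).max())):
        raise ParameterError("steady state has negative concentrations")
    return np.maximum(c, 0.0)


def clearance_fluxes(p: KineticParameters, conc: np.ndarray) -> dict[str, float]:
    """Solute efflux terms (nmol/h) for the mass-balance accounting."""
    q_sp_abs = (1.0 - p.phi_cr) * p.q_csf
    return {
        "isf_first_order": p.k_bpd40 * p.v_isf * conc[ISF],
        "cranial_absorption": p.phi_cr * p.q_csf * conc[CRA],
        "spinal_absorption": q_sp_abs * conc[SPI],
        "catheter_leak": p.q_leak * conc[SPI],
    }


@njit(cache=True)
def _march_study(Phi, w0, w1, x0, p_nodes, g, record_at, draw_flag,
                 a_sp, a_cis, a_v, out):
    """March the whole study on a uniform node grid in one call.

    ``record_at[k] >= 0`` stores the pre-draw state into ``out`` row
    ``record_at[k]``; ``draw_flag[k]`` applies the withdrawal displacement.
    """
    x = x0.copy()
    n = p_nodes.shape[0]
    for k in range(n):
        r = record_at[k]
        if r >= 0:
            for i in range(5):
                out[r, i] = x[i]
        if draw_flag[k]:
            sp = x[4] + a_sp * (x[2] - x[4])
            cis = x[2] + a_cis * (x[1] - x[2])
            v = x[1] * (1.0 - a_v)
            x[4] = sp
            x[2] = cis
            x[1] = v
        if k < n - 1:
            p0 = p_nodes[k]
            dp = p_nodes[k + 1] - p0
            y = np.zeros(5)
            for i in range(5):
                acc = 0.0
                for j in range(5):
                    acc += Phi[i, j] * x[j]
                y[i] = acc + g * (p0 * w0[i] + dp * w1[i])
            x = y
    return x


@njit(cache=True)
def _propagate(Phi, w0, w1, x, p_nodes, g):
    """March one inter-draw interval: x_{k+1} = Phi x_k + g(p_k w0 + dp w1).

    ``p_nodes`` holds the forcing fraction at each node; the forcing is
    linearly interpolated between nodes, for which w0/w1 are the exact
    convolution operators (first columns of S0 and S1/h).
    """
    n = p_nodes.shape[0]
    y = x.copy()
    for k in range(n - 1):
        p0 = p_nodes[k]
        dp = p_nodes[k + 1] - p0
        z = np.zeros(5)
        for i in range(5):
            acc = 0.0
            for j in range(5):
                acc += Phi[i, j] * y[j]
            z[i] = acc + g * (p0 * w0[i] + dp * w1[i])
        y = z
    return y


def _step_operators(A: np.ndarray, h: float):
    """Phi = e^{Ah}, w0 = S0 e1, w1 = (S1/h) e1 with
    S0 = int_0^h e^{A(h-s)} ds and S1 = int_0^h e^{A(h-s)} s ds."""
    Phi = expm(A * h)
    e1 = np.zeros(5)
    e1[ISF] = 1.0
    S0e1 = np.linalg.solve(A, Phi @ e1 - e1)
    S1e1 = h * S0e1 - np.linalg.solve(A, h * (Phi @ e1) - S0e1)
    return Phi, S0e1, S1e1 / h


@dataclass
class ModelOutput:
    """Trajectories at the sampling times (values taken just before each draw)."""

    times: np.ndarray
    labeled: np.ndarray        # (n_times, 5) nmol/mL
    unlabeled: np.ndarray      # (n_times, 5) nmol/mL
    measured_lumbar_pg: np.ndarray   # SF_40 x spinal total, pg/mL
    labeled_fraction_lumbar: np.ndarray
    isf_lumbar_ratio: float    # at the pre-infusion steady state


def simulate(p: KineticParameters, enrichment: EnrichmentCurve,
             schedule: SampleSchedule, fine_step: float = 0.25,
             withdrawals: bool = True) -> ModelOutput:
    """Integrate from the pre-infusion steady state through the sampling
    schedule, applying a lumbar withdrawal event at every draw time."""
    p.validate()
    pg_per_nmol = float(defaults_view()["units"]["ab40_pg_per_nmol"])
    prod = p.f_ab40 * p.r_app

    times = schedule.times
    if times[0] < 0:
        raise ValidationError("schedule must start at t >= 0")

    ss = steady_state(p)
    ratio = float(ss[ISF] / ss[SPI]) if ss[SPI] > 0 else 0.0

    n_t = len(times)
    lab = np.zeros((n_t, 5))
    unl = np.zeros((n_t, 5))
    if prod == 0.0:
        meas = np.zeros(n_t)
        return ModelOutput(times.copy(), lab, unl, meas, np.zeros(n_t), ratio)

    A = system_matrix(p)
    g = prod / p.v_isf
    dv = schedule.draw_volume if withdrawals else 0.0
    a_sp, a_cis, a_v = dv / p.v_sp, dv / p.v_cis, dv / p.v_v

    # Node grid over [0, t_end] with every sample time on a node.  For the
    # (usual) commensurate schedule a single step operator serves the whole
    # horizon and one kernel call per species does the march; irregular
    # actual-time schedules fall back to per-interval operators.
    spans = np.diff(np.concatenate(([0.0], times))) if times[0] > 0 \
        else np.diff(times)
    spans = spans[spans > 0]
    base = float(np.min(spans)) if len(spans) else fine_step
    n_sub = max(1, int(math.ceil(base / fine_step - 1e-12)))
    h = base / n_sub
    commensurate = bool(np.allclose(spans / h, np.round(spans / h),
                                    rtol=0.0, atol=1e-9))

    if commensurate:
        n_nodes = int(round(times[-1] / h)) + 1
        nodes = h * np.arange(n_nodes)
        record_at = np.full(n_nodes, -1, dtype=np.int64)
        draw_flag = np.zeros(n_nodes, dtype=np.bool_)
        for k, t_k in enumerate(times):
            j = int(round(t_k / h))
            record_at[j] = k
            draw_flag[j] = withdrawals
        Phi, w0, w1 = _step_operators(A, h)
        p_lab = labeled_production_fraction(enrichment, nodes, p.tau_delay,
                                            p.n_leu)
        _march_study(Phi, w0, w1, np.zeros(5), p_lab, g, record_at, draw_flag,
                     a_sp, a_cis, a_v, lab)
        _march_study(Phi, w0, w1, ss.copy(), 1.0 - p_lab, g, record_at,
                     draw_flag, a_sp, a_cis, a_v, unl)
    else:
        op_cache: dict[float, tuple] = {}
        xl, xu = np.zeros(5), ss.copy()
        t_prev = 0.0
        for k, t_k in enumerate(times):
            if t_k > t_prev + 1e-12:
                span = t_k - t_prev
                m = max(1, int(math.ceil(span / fine_step - 1e-12)))
                hk = span / m
                if hk not in op_cache:
                    op_cache[hk] = _step_operators(A, hk)
                Phi, w0, w1 = op_cache[hk]
                seg = t_prev + hk * np.arange(m + 1)
                p_lab = labeled_production_fraction(enrichment, seg,
                                                    p.tau_delay, p.n_leu)
                xl = _propagate(Phi, w0, w1, xl, p_lab, g)
                xu = _propagate(Phi, w0, w1, xu, 1.0 - p_lab, g)
                t_prev = t_k
            lab[k], unl[k] = xl, xu
            if withdrawals:
                for x in (xl, xu):
                    sp, cis, v = x[SPI], x[CIS], x[VENT]
                    x[SPI] = sp + a_sp * (cis - sp)
                    x[CIS] = cis + a_cis * (v - cis)
                    x[VENT] = v * (1.0 - a_v)

    total_sp = lab[:, SPI] + unl[:, SPI]
    if np.any(lab < -1e-9) or np.any(unl < -1e-9):
        raise ParameterError("integration produced negative concentrations "
                             f"beyond tolerance for parameter set {p}")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total_sp > 0, lab[:, SPI] / total_sp, 0.0)
    meas = p.sf40 * total_sp * pg_per_nmol
    return ModelOutput(times.copy(), lab, unl, meas, frac, ratio)
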