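"""Closed-form contrast-agent kinetics for the three-compartment LGE model.

The model: a dose D (mmol/kg) is injected instantaneously into the plasma
space V_p at t = 0.  Plasma exchanges with a lumped body EES (volume V_e,
coefficient K) and is cleared by the kidneys (GFR).  The myocardial EES is
a passive tracer compartment driven by the plasma concentration through
the permeability–surface-area product PS; its back-contribution to plasma
is neglected (small relative to the whole-body interstitial pool).  With
these assumptions the plasma concentration is a biexponential decay and
the myocardial EES concentration a corresponding triexponential; both are
represented exactly as :class:`ExponentialMixture` objects.  An optional
catenary split of the tissue EES into a pericapillary and a remote pool
approximates diffusion-limited access to an expanded interstitium.

First-pass bolus dynamics and recirculation are deliberately outside the
model; curves are meaningful from about a minute post injection onward.
Time is in minutes throughout, except the diffusion utilities (seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .params import BodyParams, ScenarioPreset, TissueParams

__all__ = [
    "ExponentialMixture",
    "TissueCurves",
    "ConcentrationCurves",
    "body_rates",
    "plasma_curve",
    "body_ees_curve",
    "myocardial_ees_curve",
    "catenary_curves",
    "assemble_curves",
    "ode_oracle",
    "renal_cleared",
    "diffusion_time",
    "diffusion_length",
]

# relative rate separation below which two exponentials are merged into the
# confluent t*exp(-m t) form
_DEGENERACY_RTOL = 1e-10


@dataclass(frozen=True)
class ExponentialMixture:
    """A finite sum  C(t) = sum_i a_i * t**p_i * exp(-m_i t).

    ``powers`` is 0 for every term except confluent (repeated-rate) cases,
    where a single t*exp(-m t) term replaces the vanishing difference of
    two plain exponentials.
    """

    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    powers: tuple[int, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.powers is None:
            object.__setattr__(self, "powers", (0,) * len(self.amplitudes))
        if not (len(self.amplitudes) == len(self.rates) == len(self.powers)):
            raise ValueError("amplitudes, rates, powers must have equal length")
        if any(m < 0 for m in self.rates):
            raise ValueError("rates must be >= 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, m, p in zip(self.amplitudes, self.rates, self.powers):
            term = a * np.exp(-m * t)
            if p:
                term = term * t**p
            out = out + term
        return out

    def at0(self) -> float:
        """Value at t = 0 (sum of power-0 amplitudes)."""
        return float(sum(a for a, p in zip(self.amplitudes, self.powers) if p == 0))

    def integral(self, t) -> np.ndarray:
        """Closed-form running integral  int_0^t C(s) ds."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, m, p in zip(self.amplitudes, self.rates, self.powers):
            if m == 0.0:
                out = out + a * (t ** (p + 1)) / (p + 1)
            elif p == 0:
                out = out + a * (1.0 - np.exp(-m * t)) / m
            elif p == 1:
                out = out + a * (1.0 - (1.0 + m * t) * np.exp(-m * t)) / m**2
            else:  # pragma: no cover - powers > 1 never arise in this model
                raise NotImplementedError("powers > 1 not supported")
        return out

    def scaled(self, c: float) -> "ExponentialMixture":
        return ExponentialMixture(
            tuple(c * a for a in self.amplitudes), self.rates, self.powers
        )

    def __add__(self, other: "ExponentialMixture") -> "ExponentialMixture":
        return ExponentialMixture(
            self.amplitudes + other.amplitudes,
            self.rates + other.rates,
            self.powers + other.powers,
        )


def _relax_response(forcing: ExponentialMixture, mu: float, gain: float
                    ) -> ExponentialMixture:
    """Solve  y' = -mu*y + gain*f(t),  y(0) = 0, for a mixture forcing f.

    The solution is the convolution gain * exp(-mu t) * f and is again an
    exponential mixture; rate coincidences fall back to confluent terms.
    """
    amps: list[float] = []
    rates: list[float] = []
    powers: list[int] = []
    tail = 0.0  # accumulated coefficient of exp(-mu t)
    for a, m, p in zip(forcing.amplitudes, forcing.rates, forcing.powers):
        d = mu - m
        scale = max(abs(mu), abs(m), 1.0)
        if p == 0:
            if abs(d) < _DEGENERACY_RTOL * scale:
                amps.append(gain * a)
                rates.append(mu)
                powers.append(1)
            else:
                amps.append(gain * a / d)
                rates.append(m)
                powers.append(0)
                tail -= gain * a / d
        elif p == 1:
            if abs(d) < _DEGENERACY_RTOL * scale:  # pragma: no cover - doubly degenerate
                raise NotImplementedError("triple rate coincidence")
            amps.append(gain * a / d)
            rates.append(m)
            powers.append(1)
            amps.append(-gain * a / d**2)
            rates.append(m)
            powers.append(0)
            tail += gain * a / d**2
        else:  # pragma: no cover
            raise NotImplementedError
    amps.append(tail)
    rates.append(mu)
    powers.append(0)
    return ExponentialMixture(tuple(amps), tuple(rates), tuple(powers))


# ---------------------------------------------------------------------------
# Whole-body (plasma / body-EES) system
# ---------------------------------------------------------------------------

def body_rates(body: BodyParams, mode: str = "exact") -> tuple[float, float]:
    """Decay rates (m1, m2), min^-1, of the biexponential plasma curve.

    ``exact`` returns the two positive roots of the characteristic
    quadratic of the coupled plasma / body-EES system with renal
    clearance.  ``approximate`` returns the fast/slow split

        m1 = K (1/V_p + 1/V_e),    m2 = GFR / (V_p + V_e),

    valid when plasma–EES exchange is much faster than renal clearance;
    this is the form used in stage-2 of the fitting workflow.
    """
    vp, ve, k, gfr = body.v_p, body.v_e, body.k, body.gfr
    if mode == "approximate":
        return k * (1.0 / vp + 1.0 / ve), gfr / (vp + ve)
    if mode != "exact":
        raise ValueError(f"mode must be 'exact' or 'approximate', got {mode!r}")
    # lambda^2 + b lambda + c = 0 with decay rates m = -lambda
    b = (k + gfr) / vp + k / ve
    c = k * gfr / (vp * ve)
    disc = max(b * b - 4.0 * c, 0.0)
    root = np.sqrt(disc)
    m1 = 0.5 * (b + root)
    m2 = c / m1 if m1 > 0 else 0.0  # numerically stable small root
    return float(m1), float(m2)


def plasma_curve(body: BodyParams) -> ExponentialMixture:
    """Exact biexponential plasma concentration C_p(t), mmol/L.

    Initial condition C_p(0) = D/V_p, C_e(0) = 0; the sum of the
    amplitudes therefore equals D/V_p.
    """
    vp = body.v_p
    c0 = body.dose / vp
    m1, m2 = body_rates(body, "exact")
    alpha = (body.k + body.gfr) / vp  # -C_p'(0)/C_p(0)
    if abs(m1 - m2) < _DEGENERACY_RTOL * max(m1, 1.0):
        # repeated root: C_p = (C0 + (m-alpha) C0 t) exp(-m t)
        m = 0.5 * (m1 + m2)
        return ExponentialMixture((c0, (m - alpha) * c0), (m, m), (0, 1))
    a1 = c0 * (alpha - m2) / (m1 - m2)
    a2 = c0 * (m1 - alpha) / (m1 - m2)
    return ExponentialMixture((a1, a2), (m1, m2))


def body_ees_curve(body: BodyParams) -> ExponentialMixture:
    """Exact body-EES concentration C_e(t), mmol/L; C_e(0) = 0."""
    kappa = body.k / body.v_e
    return _relax_response(plasma_curve(body), kappa, kappa)


def myocardial_ees_curve(tissue: TissueParams, plasma: ExponentialMixture
                         ) -> ExponentialMixture:
    """Well-stirred myocardial EES concentration C_me(t), mmol/L.

    Solves v_e dC_me/dt = PS (C_p - C_me): the convolution of the plasma
    curve with k exp(-k t), k = PS/v_e — a triexponential when the plasma
    curve is biexponential.  PS = 0 (or v_e = 0) yields the zero curve.
    """
    if tissue.ps == 0.0 or tissue.v_e == 0.0:
        return ExponentialMixture((0.0,), (0.0,))
    k = tissue.ps / tissue.v_e
    return _relax_response(plasma, k, k)


def catenary_curves(tissue: TissueParams, plasma: ExponentialMixture
                    ) -> tuple[ExponentialMixture, Optional[ExponentialMixture]]:
    """Concentrations (C1, C2) of the pericapillary and remote EES pools.

    Solves the chained system

        v_e1 dC1/dt = PS (C_p - C1) - PS_ee (C1 - C2)
        v_e2 dC2/dt = PS_ee (C1 - C2)

    with v_e1 = f_peri*v_e, v_e2 = (1-f_peri)*v_e.  With f_peri = 1 the
    remote pool vanishes and the well-stirred solution is returned with
    ``C2 = None``.
    """
    if tissue.catenary is None:
        raise ValueError("tissue has no catenary parameters")
    f = tissue.catenary.f_peri
    ps_ee = tissue.catenary.ps_ee
    if f >= 1.0:
        return myocardial_ees_curve(tissue, plasma), None
    ve1 = f * tissue.v_e
    ve2 = (1.0 - f) * tissue.v_e
    if ps_ee == 0.0:
        # remote pool decoupled: C1 is well-stirred with volume ve1, C2 = 0
        sub = tissue.model_copy(update={"v_e": ve1, "catenary": None})
        return myocardial_ees_curve(sub, plasma), ExponentialMixture((0.0,), (0.0,))
    m = np.array([
        [-(tissue.ps + ps_ee) / ve1, ps_ee / ve1],
        [ps_ee / ve2, -ps_ee / ve2],
    ])
    lam, w = np.linalg.eig(m)  # real: m is similar to a symmetric matrix
    lam = lam.real
    w = w.real
    g = np.linalg.solve(w, np.array([tissue.ps / ve1, 0.0]))
    parts = []
    for i in range(2):
        parts.append(_relax_response(plasma, -lam[i], g[i]))
    c1 = parts[0].scaled(w[0, 0]) + parts[1].scaled(w[0, 1])
    c2 = parts[0].scaled(w[1, 0]) + parts[1].scaled(w[1, 1])
    return c1, c2


# ---------------------------------------------------------------------------
# Assembled per-scenario curves
# ---------------------------------------------------------------------------

@dataclass
class TissueCurves:
    """Sampled concentration curves for one tissue channel."""

    c_me: np.ndarray            # EES concentration (pericapillary pool if catenary)
    c_t: np.ndarray             # total tissue concentration, mmol per L tissue
    c_me2: Optional[np.ndarray] = None  # remote EES pool (catenary only)


@dataclass
class ConcentrationCurves:
    """All compartment curves of a scenario sampled on a common time grid."""

    times: np.ndarray           # minutes
    c_p: np.ndarray             # plasma, mmol/L
    c_e: np.ndarray             # body EES, mmol/L
    c_b: np.ndarray             # whole blood, mmol/L
    tissues: dict[str, TissueCurves] = field(default_factory=dict)


def _tissue_total(tissue: TissueParams, c_p: np.ndarray,
                  plasma: ExponentialMixture, times: np.ndarray) -> TissueCurves:
    vp_t = tissue.v_mb * (1.0 - tissue.hct_m)  # tissue plasma fraction
    if tissue.catenary is not None and tissue.catenary.f_peri < 1.0:
        f = tissue.catenary.f_peri
        c1m, c2m = catenary_curves(tissue, plasma)
        c1 = c1m(times)
        c2 = c2m(times) if c2m is not None else np.zeros_like(times)
        c_t = vp_t * c_p + f * tissue.v_e * c1 + (1.0 - f) * tissue.v_e * c2
        return TissueCurves(c_me=c1, c_t=c_t, c_me2=c2)
    c_me = myocardial_ees_curve(tissue, plasma)(times)
    return TissueCurves(c_me=c_me, c_t=vp_t * c_p + tissue.v_e * c_me)


def assemble_curves(preset: ScenarioPreset, times) -> ConcentrationCurves:
    """Sample every compartment curve of a scenario on a time grid (minutes).

    C_b = (1-Hct) C_p;  C_t = v_mb (1-Hct_m) C_p + v_e C_me (with the EES
    term split over both pools for catenary tissues).  The myocardium does
    not feed back into the plasma.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time grid")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    plasma = plasma_curve(preset.body)
    c_p = plasma(times)
    c_e = body_ees_curve(preset.body)(times)
    c_b = (1.0 - preset.body.hct) * c_p
    tissues = {
        name: _tissue_total(t, c_p, plasma, times)
        for name, t in preset.tissues.items()
    }
    return ConcentrationCurves(times=times, c_p=c_p, c_e=c_e, c_b=c_b,
                               tissues=tissues)


def ode_oracle(preset: ScenarioPreset, times, rtol: float = 1e-11,
               atol: float = 1e-13) -> ConcentrationCurves:
    """Numerically integrate the full coupled system (verification path).

    Integrates plasma, body EES, and every tissue EES (both pools for
    catenary tissues) with tight tolerances; intended as an independent
    check of the closed forms, not for production use.
    """
    times = np.asarray(times, dtype=float)
    body = preset.body
    vp, ve, k, gfr = body.v_p, body.v_e, body.k, body.gfr
    names = list(preset.tissues)
    # state: [C_p, C_e, then 1 or 2 slots per tissue]
    slots: list[tuple[str, int]] = []
    for name in names:
        t = preset.tissues[name]
        two = t.catenary is not None and t.catenary.f_peri < 1.0
        slots.append((name, 2 if two else 1))
    n = 2 + sum(s for _, s in slots)

    def rhs(_t, y):
        dy = np.zeros(n)
        cp, ce = y[0], y[1]
        dy[0] = -(k * (cp - ce) + gfr * cp) / vp
        dy[1] = k * (cp - ce) / ve
        i = 2
        for name, width in slots:
            t = preset.tissues[name]
            if width == 1:
                dy[i] = t.ps * (cp - y[i]) / t.v_e if t.v_e > 0 else 0.0
                i += 1
            else:
                f = t.catenary.f_peri
                ve1, ve2 = f * t.v_e, (1.0 - f) * t.v_e
                c1, c2 = y[i], y[i + 1]
                dy[i] = (t.ps * (cp - c1) - t.catenary.ps_ee * (c1 - c2)) / ve1
                dy[i + 1] = t.catenary.ps_ee * (c1 - c2) / ve2
                i += 2
        return dy

    y0 = np.zeros(n)
    y0[0] = body.dose / vp
    t_end = float(times[-1]) if times[-1] > 0 else 1.0
    sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=times, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE oracle failed: {sol.message}")
    c_p, c_e = sol.y[0], sol.y[1]
    out = ConcentrationCurves(times=times, c_p=c_p, c_e=c_e,
                              c_b=(1.0 - body.hct) * c_p)
    i = 2
    for name, width in slots:
        t = preset.tissues[name]
        vp_t = t.v_mb * (1.0 - t.hct_m)
        if width == 1:
            c_me = sol.y[i]
            out.tissues[name] = TissueCurves(
                c_me=c_me, c_t=vp_t * c_p + t.v_e * c_me)
            i += 1
        else:
            f = t.catenary.f_peri
            c1, c2 = sol.y[i], sol.y[i + 1]
            c_t = vp_t * c_p + f * t.v_e * c1 + (1.0 - f) * t.v_e * c2
            out.tissues[name] = TissueCurves(c_me=c1, c_t=c_t, c_me2=c2)
            i += 2
    return out


def renal_cleared(body: BodyParams, t) -> np.ndarray:
    """Cumulative renally cleared contrast, mmol/kg: GFR * int_0^t C_p ds.

    Non-decreasing in t and -> D as t -> infinity whenever GFR > 0.
    """
    return body.gfr * plasma_curve(body).integral(np.asarray(t, dtype=float))


# ---------------------------------------------------------------------------
# Interstitial diffusion scales (Discussion-level order-of-magnitude utility)
# ---------------------------------------------------------------------------

def diffusion_time(d: float, dcoef: float = 2e-4) -> float:
    """Time (s) to diffuse a distance d (mm): t = d^2 / (4 D), D in mm^2/s."""
    if d <= 0 or dcoef <= 0:
        raise ValueError("d and dcoef must be positive")
    return d * d / (4.0 * dcoef)


def diffusion_length(t: float, dcoef: float = 2e-4) -> float:
    """Classical diffusion length (mm) over time t (s): 2 sqrt(D t)."""
    if t < 0 or dcoef <= 0:
        raise ValueError("t must be >= 0 and dcoef > 0")
    return 2.0 * np.sqrt(dcoef * t)
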