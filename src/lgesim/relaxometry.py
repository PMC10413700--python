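"""Concentration -> T1 conversion and inversion-recovery / PSIR signals.

A single linear-relaxivity agent is assumed (fast water exchange, one T1
per channel from the volume-weighted total concentration):

    1/T1 = 1/T1_0 + r1 * C

The signal model is the ideal single-inversion, full-recovery IR curve
S = 1 - 2 exp(-TI/T1) with unit proton density for every channel; in
phase-sensitive (PSIR) reconstruction the sign is kept, in magnitude
reconstruction |S| is taken.  Nulling a reference tissue means choosing
TI = T1_ref * ln 2, which is recomputed per time point by default as the
reference T1 recovers during contrast washout (a fixed TI can be given
instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import assemble_curves
from .params import ScenarioPreset

__all__ = [
    "T1Series",
    "PsirSeries",
    "t1_from_conc",
    "conc_from_t1",
    "simulate_t1",
    "t1_difference",
    "null_ti",
    "ir_signal",
    "psir_timecourse",
]

LN2 = float(np.log(2.0))


@dataclass
class T1Series:
    """Sampled T1 time courses, ms, for blood and each tissue channel."""

    times: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass
class PsirSeries:
    """Signed IR signals per channel with the per-time-point nulling TI."""

    times: np.ndarray
    ti_null: np.ndarray                 # ms, per time point
    signals: dict[str, np.ndarray] = field(default_factory=dict)
    reference: str = ""


def t1_from_conc(t1_0: float, r1: float, c) -> np.ndarray:
    """T1 (ms) at concentration c (mmol/L): 1/(1/T1_0 + r1*c)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    return 1.0 / (1.0 / t1_0 + r1 * c)


def conc_from_t1(t1_0: float, r1: float, t1, rtol: float = 1e-6) -> np.ndarray:
    """Concentration (mmol/L) from measured T1: (1/T1 - 1/T1_0)/r1.

    T1 slightly above T1_0 (within ``rtol``, e.g. from noise) is clipped
    to zero concentration; larger excursions are flagged as inconsistent.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if np.any(t1 > t1_0 * (1.0 + rtol)):
        raise ValueError(
            f"T1 exceeds native T1_0={t1_0} ms beyond tolerance: implies a "
            "negative contrast concentration"
        )
    return np.maximum((1.0 / t1 - 1.0 / t1_0) / r1, 0.0)


def simulate_t1(preset: ScenarioPreset, times) -> T1Series:
    """Forward-simulate blood and tissue T1 time courses for a scenario.

    The blood channel is converted from the whole-blood concentration C_b
    with the native blood T1; each tissue channel from its total tissue
    concentration C_t with its own native T1.
    """
    curves = assemble_curves(preset, times)
    r1 = preset.relaxometry.r1
    channels = {"blood": t1_from_conc(preset.relaxometry.t1_b0, r1, curves.c_b)}
    for name, tc in curves.tissues.items():
        channels[name] = t1_from_conc(preset.tissues[name].t1_0, r1, tc.c_t)
    return T1Series(times=curves.times, channels=channels)


def t1_difference(series: T1Series, tissue: str) -> np.ndarray:
    """Blood-minus-tissue T1 difference (ms) per time point."""
    return series["blood"] - series[tissue]


def null_ti(t1_ref) -> np.ndarray:
    """Inversion time (ms) nulling a tissue of the given T1: TI = T1 ln 2."""
    t1_ref = np.asarray(t1_ref, dtype=float)
    if np.any(t1_ref <= 0):
        raise ValueError("T1_ref must be positive")
    return t1_ref * LN2


def ir_signal(t1, ti, mode: str = "phase_sensitive") -> np.ndarray:
    """Ideal inversion-recovery signal S = 1 - 2 exp(-TI/T1).

    ``phase_sensitive`` keeps the sign (range [-1, 1]); ``magnitude``
    returns |S|, which renders long-T1 regions spuriously bright.
    """
    t1 = np.asarray(t1, dtype=float)
    ti = np.asarray(ti, dtype=float)
    if np.any(t1 <= 0) or np.any(ti <= 0):
        raise ValueError("T1 and TI must be positive")
    s = 1.0 - 2.0 * np.exp(-ti / t1)
    if mode == "magnitude":
        return np.abs(s)
    if mode != "phase_sensitive":
        raise ValueError(f"mode must be 'phase_sensitive' or 'magnitude', got {mode!r}")
    return s


def psir_timecourse(preset: ScenarioPreset, times, reference: str | None = None,
                    mode: str = "phase_sensitive",
                    fixed_ti: float | None = None) -> PsirSeries:
    """IR signal time courses with nulling of a reference tissue.

    At every time point the inversion time is set to null the current T1
    of the reference channel (so the reference signal is identically
    zero), unless ``fixed_ti`` pins TI to a single value.  All other
    channels are read out at the same TI.
    """
    reference = reference or preset.reference_tissue
    t1s = simulate_t1(preset, times)
    t1_ref = t1s[reference]  # raises on unknown channel
    ti = np.full_like(t1_ref, fixed_ti) if fixed_ti is not None else null_ti(t1_ref)
    signals = {name: ir_signal(t1, ti, mode) for name, t1 in t1s.channels.items()}
    return PsirSeries(times=t1s.times, ti_null=ti, signals=signals,
                      reference=reference)
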