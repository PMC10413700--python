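"""Synthetic serial T1 observation sets for testing the calibration loop.

The generator forward-simulates blood and tissue T1 time courses from a
scenario and adds independent Gaussian noise on T1 (ms) per point and
channel — T1 being the measured quantity in practice.  Default noise
levels (20 ms blood, 30 ms myocardium) are plausible T1-mapping
precision at 1.5 T.  The default sampling grid spans 1–45 min post
injection; times under a minute are excluded because first-pass bolus
dynamics are outside the kinetic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import ObservedT1Series
from .params import ScenarioPreset
from .relaxometry import simulate_t1

__all__ = ["GeneratorSpec", "default_grid", "generate"]

DEFAULT_BLOOD_SD = 20.0   # ms
DEFAULT_TISSUE_SD = 30.0  # ms
_T1_FLOOR = 1.0           # ms; noise never drives T1 non-physical


def default_grid() -> np.ndarray:
    """Standard post-injection sampling times, minutes."""
    return np.array([1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0, 45.0])


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic observation set.

    ``noise_sd`` maps channel name to Gaussian sd on T1 in ms; channels
    not listed get the blood/tissue defaults.  ``noise_sd = 0`` (all
    channels) reproduces the forward model exactly.  The seed fixes the
    full output stream.
    """

    preset: ScenarioPreset
    times: np.ndarray = field(default_factory=default_grid)
    noise_sd: dict[str, float] | float = field(default_factory=dict)
    replicates: int = 1
    seed: int = 0

    def sd_for(self, channel: str) -> float:
        if isinstance(self.noise_sd, (int, float)):
            return float(self.noise_sd)
        if channel in self.noise_sd:
            return float(self.noise_sd[channel])
        return DEFAULT_BLOOD_SD if channel == "blood" else DEFAULT_TISSUE_SD


def generate(spec: GeneratorSpec) -> ObservedT1Series | list[ObservedT1Series]:
    """Generate one observation set (or a list when ``replicates > 1``).

    Deterministic per seed; sd values propagate into the ``sd`` field of
    the output so fits can weight accordingly.
    """
    times = np.asarray(spec.times, dtype=float)
    clean = simulate_t1(spec.preset, times)
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.replicates):
        channels, sds = {}, {}
        for name, t1 in clean.channels.items():
            sd = spec.sd_for(name)
            if sd < 0:
                raise ValueError(f"noise sd for {name!r} must be >= 0")
            noisy = t1 + rng.normal(0.0, sd, size=t1.shape) if sd > 0 else t1.copy()
            channels[name] = np.maximum(noisy, _T1_FLOOR)
            if sd > 0:
                sds[name] = np.full_like(t1, sd)
        out.append(ObservedT1Series(times=times.copy(), channels=channels, sd=sds))
    return out[0] if spec.replicates == 1 else out
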