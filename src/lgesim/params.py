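"""Parameter types, physiologic constraints, and named scenario presets.

Unit conventions
----------------
All whole-body quantities are expressed per kg of body weight so that weight
cancels in concentrations: dose ``D`` in mmol/kg, blood volume ``V_b`` and
body-EES volume ``V_e`` in L/kg, the plasma/body-EES exchange coefficient
``K`` in L/min/kg.  The glomerular filtration rate is stored as the total
GFR in mL/min at the stated weight and converted internally to L/min/kg.
Tissue quantities are per unit tissue volume: fractional volumes are
dimensionless and the permeability–surface-area product ``PS`` is in
mL/min per mL tissue (equivalently min^-1).  Relaxivity ``r1`` is in
L/(mmol*ms) so that T1 values in ms are consistent throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict

SCHEMA_VERSION = "1"

__all__ = [
    "BodyParams",
    "CatenaryParams",
    "TissueParams",
    "RelaxometryParams",
    "ScenarioPreset",
    "ConstraintViolation",
    "PRESET_NAMES",
    "load_preset",
    "validate",
    "violations",
    "plasma_volume",
    "ecv",
    "load_scenario_file",
    "save_scenario_file",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class BodyParams(_Model):
    """Whole-body kinetic parameters (per kg of body weight).

    Attributes
    ----------
    dose : float
        Injected contrast dose D, mmol per kg body weight.
    weight : float
        Body weight, kg (used only to convert the total GFR to per-kg units).
    hct : float
        Large-vessel hematocrit, fraction.
    gfr_total : float
        Glomerular filtration rate, mL/min for the stated weight.
    v_b : float
        Blood volume, L/kg.
    v_e : float
        Body extravascular-extracellular-space (EES) volume, L/kg.
    k : float
        Plasma <-> body-EES exchange coefficient, L/min per kg.
    """

    dose: float = 0.1
    weight: float = 70.0
    hct: float = 0.42
    gfr_total: float = 90.0
    v_b: float = 0.075
    v_e: float = 0.15
    k: float = 0.0083

    @property
    def v_p(self) -> float:
        """Plasma volume V_p = V_b * (1 - Hct), L/kg."""
        return self.v_b * (1.0 - self.hct)

    @property
    def gfr(self) -> float:
        """Renal clearance in L/min per kg body weight."""
        return self.gfr_total / 1000.0 / self.weight


class CatenaryParams(_Model):
    """Split of the tissue EES into a pericapillary and a remote pool.

    ``f_peri`` is the fraction of v_e assigned to the (smaller, faster)
    pericapillary pool; ``ps_ee`` is the exchange coefficient between the
    two pools per unit tissue volume, min^-1.
    """

    f_peri: float = 0.25
    ps_ee: float = 0.1


class TissueParams(_Model):
    """Per-unit-volume myocardial tissue parameters.

    Attributes
    ----------
    v_mb : float
        Fractional myocardial whole-blood volume, dimensionless.
    hct_m : float
        Tissue (capillary) hematocrit, fraction.
    v_e : float
        Fractional myocardial EES volume, dimensionless.
    ps : float
        Permeability–surface-area product per unit tissue volume,
        mL/min per mL tissue (min^-1).
    t1_0 : float
        Native (pre-contrast) tissue T1, ms.
    catenary : CatenaryParams, optional
        When present, the tissue EES is modelled as a two-pool chain.
    """

    v_mb: float = 0.09
    hct_m: float = 0.30
    v_e: float = 0.25
    ps: float = 1.3
    t1_0: float = 962.0
    catenary: Optional[CatenaryParams] = None


class RelaxometryParams(_Model):
    """Contrast-agent relaxivity and native blood T1.

    ``r1`` is the longitudinal relaxivity in L/(mmol*ms); the default
    0.0042 corresponds to 4.2 L/(mmol*s), the accepted Gd-DTPA value at
    1.5 T.  ``t1_b0`` is the native blood T1 in ms.
    """

    r1: float = 0.0042
    t1_b0: float = 1535.0


class ScenarioPreset(_Model):
    """A complete, named parameter bundle for one simulation scenario.

    ``tissues`` maps channel names to tissue parameter sets; exactly one of
    them, ``reference_tissue``, is the channel nulled in PSIR imaging.
    """

    name: str = "custom"
    body: BodyParams = BodyParams()
    tissues: dict[str, TissueParams] = {}
    relaxometry: RelaxometryParams = RelaxometryParams()
    reference_tissue: str = "myocardium"
    schema_version: str = SCHEMA_VERSION


class ConstraintViolation(ValueError):
    """Raised when a parameter bundle violates a physical constraint."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def _check_body(body: BodyParams, where: str = "body") -> list[str]:
    out = []
    for field in ("dose", "weight", "v_b", "v_e", "k", "gfr_total"):
        if getattr(body, field) <= 0 and field not in ("k", "gfr_total"):
            out.append(f"{where}.{field} must be > 0")
        elif getattr(body, field) < 0:
            out.append(f"{where}.{field} must be >= 0")
    if not 0.0 < body.hct < 1.0:
        out.append(f"{where}.hct: 0 < Hct < 1 (got {body.hct})")
    elif body.v_p <= 0:
        out.append(f"{where}: derived V_p = V_b*(1-Hct) must be > 0")
    return out


def _check_tissue(t: TissueParams, where: str) -> list[str]:
    out = []
    if not 0.0 < t.hct_m < 1.0:
        out.append(f"{where}.hct_m: 0 < Hct_m < 1 (got {t.hct_m})")
    if t.v_mb < 0:
        out.append(f"{where}.v_mb must be >= 0")
    if t.v_e < 0:
        out.append(f"{where}.v_e must be >= 0")
    if t.v_mb + t.v_e > 1.0 + 1e-12:
        out.append(f"{where}: v_mb + v_e <= 1 (got {t.v_mb + t.v_e:g})")
    if t.ps < 0:
        out.append(f"{where}.ps must be >= 0")
    if t.t1_0 <= 0:
        out.append(f"{where}.t1_0 must be > 0")
    if t.catenary is not None:
        if not 0.0 < t.catenary.f_peri <= 1.0:
            out.append(f"{where}.catenary.f_peri: 0 < f_peri <= 1")
        if t.catenary.ps_ee < 0:
            out.append(f"{where}.catenary.ps_ee must be >= 0")
    return out


def violations(preset: ScenarioPreset) -> list[str]:
    """Return a list of violated physical/physiologic constraints (empty if valid)."""
    out = _check_body(preset.body)
    if not preset.tissues:
        out.append("preset must define at least one tissue")
    for name, t in preset.tissues.items():
        out.extend(_check_tissue(t, f"tissues[{name}]"))
    if preset.relaxometry.r1 <= 0:
        out.append("relaxometry.r1 must be > 0")
    if preset.relaxometry.t1_b0 <= 0:
        out.append("relaxometry.t1_b0 must be > 0")
    if preset.tissues and preset.reference_tissue not in preset.tissues:
        out.append(
            f"reference_tissue {preset.reference_tissue!r} not among tissues "
            f"{sorted(preset.tissues)}"
        )
    return out


def validate(preset: ScenarioPreset) -> ScenarioPreset:
    """Validate a preset against the physical constraints.

    Returns the preset unchanged when all invariants hold; raises
    :class:`ConstraintViolation` listing every violated constraint otherwise.
    """
    problems = violations(preset)
    if problems:
        raise ConstraintViolation(problems)
    return preset


def plasma_volume(v_b: float, hct: float) -> float:
    """Plasma volume V_p = V_b * (1 - Hct), same units as ``v_b``."""
    if v_b <= 0 or not 0.0 <= hct < 1.0:
        raise ConstraintViolation([f"plasma_volume: need v_b > 0 and 0 <= hct < 1"])
    return v_b * (1.0 - hct)


def ecv(tissue: TissueParams) -> float:
    """Combined myocardial extracellular volume fraction.

    ECV = v_e + v_mb * (1 - Hct_m): interstitium plus tissue plasma, the
    total distribution space of an extracellular agent per unit tissue.
    """
    return tissue.v_e + tissue.v_mb * (1.0 - tissue.hct_m)


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

def _initial() -> ScenarioPreset:
    # literature-derived starting values for normal myocardium
    return ScenarioPreset(
        name="initial",
        body=BodyParams(dose=0.1, weight=70.0, hct=0.42, gfr_total=90.0,
                        v_b=0.075, v_e=0.15, k=0.0083),
        tissues={"myocardium": TissueParams(v_mb=0.09, hct_m=0.30, v_e=0.25,
                                            ps=1.3, t1_0=962.0)},
        relaxometry=RelaxometryParams(r1=0.0042, t1_b0=1535.0),
        reference_tissue="myocardium",
    )


def _normal() -> ScenarioPreset:
    # adjusted values after calibration to control-subject T1 time courses
    return ScenarioPreset(
        name="normal",
        body=BodyParams(dose=0.1, weight=70.0, hct=0.42, gfr_total=90.0,
                        v_b=0.100, v_e=0.09, k=0.0108),
        tissues={"myocardium": TissueParams(v_mb=0.15, hct_m=0.24, v_e=0.17,
                                            ps=1.3, t1_0=962.0)},
        relaxometry=RelaxometryParams(r1=0.0042, t1_b0=1535.0),
        reference_tissue="myocardium",
    )


def _scar() -> ScenarioPreset:
    p = _normal()
    return ScenarioPreset(
        name="scar",
        body=p.body,
        tissues={
            "myocardium": p.tissues["myocardium"],
            "scar": TissueParams(v_mb=0.05, hct_m=0.24, v_e=0.95,
                                 ps=0.41, t1_0=1000.0),
        },
        relaxometry=p.relaxometry,
        reference_tissue="myocardium",
    )


def _amyloid_body() -> BodyParams:
    return BodyParams(dose=0.1, weight=70.0, hct=0.42, gfr_total=90.0,
                      v_b=0.115, v_e=0.13, k=0.0108)


def _amyloid_midwall() -> ScenarioPreset:
    return ScenarioPreset(
        name="amyloid_midwall",
        body=_amyloid_body(),
        tissues={"midwall": TissueParams(v_mb=0.11, hct_m=0.24, v_e=0.75,
                                         ps=0.32, t1_0=1100.0)},
        relaxometry=RelaxometryParams(r1=0.0042, t1_b0=1535.0),
        reference_tissue="midwall",
    )


def _amyloid_subendo() -> ScenarioPreset:
    p = _amyloid_midwall()
    return ScenarioPreset(
        name="amyloid_subendo",
        body=p.body,
        tissues={
            "midwall": p.tissues["midwall"],
            "subendo": TissueParams(v_mb=0.04, hct_m=0.24, v_e=0.96,
                                    ps=0.44, t1_0=1100.0),
        },
        relaxometry=p.relaxometry,
        reference_tissue="midwall",
    )


_PRESETS = {
    "initial": _initial,
    "normal": _normal,
    "scar": _scar,
    "amyloid_midwall": _amyloid_midwall,
    "amyloid_subendo": _amyloid_subendo,
}

PRESET_NAMES = tuple(_PRESETS)


def load_preset(name: str) -> ScenarioPreset:
    """Return the named scenario preset.

    ``normal`` is the calibrated normal-myocardium set; ``initial`` the
    literature starting values; ``scar`` overlays a fibrotic-scar tissue on
    the normal scenario; ``amyloid_midwall``/``amyloid_subendo`` model
    diffuse cardiac amyloid with an expanded body EES.
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    return validate(factory())


# ---------------------------------------------------------------------------
# Scenario file I/O
# ---------------------------------------------------------------------------

def load_scenario_file(path: str | Path) -> ScenarioPreset:
    """Load a scenario from a JSON or YAML file and validate it."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return validate(ScenarioPreset.model_validate(data))


def save_scenario_file(preset: ScenarioPreset, path: str | Path) -> None:
    """Write a scenario to JSON (or YAML by extension); round-trips exactly."""
    path = Path(path)
    data = preset.model_dump()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
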