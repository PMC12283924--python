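"""Material parameterization: elastography measurements to constraint compliances.

Shear-wave elastography (SWE) of soft tissue yields a Young's modulus E (in
kPa) and a Poisson's ratio nu per subject.  Internally everything is SI: E in
Pa.  The Lame parameters

    lambda = E*nu / ((1 + nu)(1 - 2*nu)),    mu = E / (2(1 + nu))

weight the hydrostatic (volumetric) and deviatoric (distortional) parts of
the Neo-Hookean energy, and the per-element constraint compliances are their
reciprocals scaled by the element rest volume:

    alpha_H = 1 / (lambda * V_rest),    alpha_D = 1 / (mu * V_rest).

Distance-constraint compliance defaults to 1/(mu * L_rest) (shear-like role)
and volume-constraint compliance to 1/(lambda * V_rest) (volumetric role);
both are overridable.  Shape matching takes a dimensionless stiffness in
[0, 1], defaulting to nu/0.5 (more incompressible tissue holds its shape
more rigidly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Material",
    "lame_from_young_poisson",
    "young_poisson_from_lame",
    "element_compliances",
    "timestep_scaled",
    "swe_liver_presets",
    "PRESET_NAMES",
]


def lame_from_young_poisson(E: float, nu: float) -> tuple[float, float]:
    """Lame parameters (lambda, mu) in Pa from Young's modulus and Poisson's ratio."""
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if nu < 0:
        raise ValueError(f"Poisson's ratio must be non-negative, got {nu}")
    if nu >= 0.5:
        raise ValueError(f"Poisson's ratio {nu} >= 0.5: incompressible limit is singular")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


def young_poisson_from_lame(lam: float, mu: float) -> tuple[float, float]:
    """Inverse map: E = mu(3*lambda + 2*mu)/(lambda + mu), nu = lambda/(2(lambda + mu))."""
    E = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    nu = lam / (2.0 * (lam + mu))
    return E, nu


def timestep_scaled(alpha: float, dt: float) -> float:
    """Timestep-scaled compliance alpha_tilde = alpha / dt**2."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return alpha / (dt * dt)


@dataclass
class Material:
    """Isotropic soft-tissue material with derived per-constraint compliances.

    ``compliance_overrides`` may contain any of the keys ``distance``,
    ``volume``, ``neo_hydro``, ``neo_dev`` (compliances, inverse-stiffness
    units) and ``shape_stiffness`` (dimensionless in [0, 1]); an override
    wins over the derived default.
    """

    young_modulus: float  # Pa
    poisson_ratio: float
    lame_lambda: float = None  # type: ignore[assignment]
    lame_mu: float = None  # type: ignore[assignment]
    density: float = 1000.0  # kg/m^3
    compliance_overrides: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        lam, mu = lame_from_young_poisson(self.young_modulus, self.poisson_ratio)
        if self.lame_lambda is None:
            self.lame_lambda = lam
        if self.lame_mu is None:
            self.lame_mu = mu
        for derived, given, label in ((lam, self.lame_lambda, "lambda"), (mu, self.lame_mu, "mu")):
            if abs(given - derived) > 1e-12 * max(1.0, abs(derived)):
                raise ValueError(f"lame_{label}={given} inconsistent with (E, nu): expected {derived}")
        unknown = set(self.compliance_overrides) - {
            "distance", "volume", "neo_hydro", "neo_dev", "shape_stiffness",
        }
        if unknown:
            raise ValueError(f"unknown compliance overrides: {sorted(unknown)}")

    @classmethod
    def from_young_poisson(
        cls,
        young_modulus_pa: float,
        poisson_ratio: float,
        density: float = 1000.0,
        overrides: dict | None = None,
        name: str = "",
    ) -> "Material":
        return cls(
            young_modulus=young_modulus_pa,
            poisson_ratio=poisson_ratio,
            density=density,
            compliance_overrides=dict(overrides or {}),
            name=name,
        )

    # -- derived per-constraint parameters ---------------------------------

    def distance_compliance(self, rest_length: float) -> float:
        if "distance" in self.compliance_overrides:
            return self.compliance_overrides["distance"]
        return 1.0 / (self.lame_mu * rest_length)

    def volume_compliance(self, rest_volume: float) -> float:
        if "volume" in self.compliance_overrides:
            return self.compliance_overrides["volume"]
        if self.lame_lambda == 0.0:
            return float("inf")  # volumetric constraint disabled at nu = 0
        return 1.0 / (self.lame_lambda * rest_volume)

    @property
    def shape_stiffness(self) -> float:
        if "shape_stiffness" in self.compliance_overrides:
            return self.compliance_overrides["shape_stiffness"]
        return min(1.0, max(0.0, self.poisson_ratio / 0.5))


def element_compliances(material: Material, rest_volume: float) -> tuple[float, float]:
    """Per-element Neo-Hookean compliances (alpha_H, alpha_D).

    alpha_H = 1/(lambda * V_rest); alpha_D = 1/(mu * V_rest).  Overrides win.
    A material with lambda = 0 (nu = 0) has no volumetric resistance: the
    hydrostatic constraint is disabled (infinite compliance), not an error.
    """
    if rest_volume <= 0:
        raise ValueError(f"rest_volume must be positive, got {rest_volume}")
    ov = material.compliance_overrides
    if "neo_hydro" in ov:
        alpha_h = ov["neo_hydro"]
    elif material.lame_lambda == 0.0:
        alpha_h = float("inf")
    else:
        alpha_h = 1.0 / (material.lame_lambda * rest_volume)
    alpha_d = ov.get("neo_dev", 1.0 / (material.lame_mu * rest_volume))
    return alpha_h, alpha_d


# Four liver stiffness presets measured in vivo by shear-wave elastography,
# spanning healthy (soft) to fibrotic (stiff) tissue: (E in kPa, nu).
_PRESET_ROWS = [
    ("liver_soft", 2.1972, 0.4597),
    ("liver_medium_soft", 5.8597, 0.4523),
    ("liver_medium", 6.2781, 0.4505),
    ("liver_stiff", 36.6175, 0.4377),
]

PRESET_NAMES = [name for name, _, _ in _PRESET_ROWS]


def swe_liver_presets(density: float = 1000.0) -> list[Material]:
    """The four SWE liver stiffness presets, E converted from kPa to Pa."""
    return [
        Material.from_young_poisson(e_kpa * 1000.0, nu, density=density, name=name)
        for name, e_kpa, nu in _PRESET_ROWS
    ]


def preset_by_name(name: str, density: float = 1000.0) -> Material:
    for mat in swe_liver_presets(density):
        if mat.name == name:
            return mat
    raise KeyError(f"unknown material preset {name!r}; available: {PRESET_NAMES}")
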