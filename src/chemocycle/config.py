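"""Run configuration: validated parameter schema, YAML loading, defaults.

A run is described by one YAML file with sections ``domain``,
``vasculature``, ``tissue``, ``drug``, ``growth``, ``schedule`` and
``solver``.  Unknown keys are rejected with their key path; values are
range-checked.  User-facing units are the natural ones of each quantity
(months for schedules, minutes for plasma half-life, µm for diameters);
they are converted to SI at the boundary to the solvers.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .growth import GrowthParams, Schedule, build_regimen
from .tissue import RegionParams, TissueGrid, TissueParams, build_domain
from .transport import DrugParams
from .vasculature import VascularNetwork, generate_synthetic_network

__all__ = ["RunConfig", "load_config", "dump_defaults", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unparsable run configuration."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DomainConfig(_Section):
    extent_m: float = Field(2.0e-3, gt=0)
    tumor_radius_m: float = Field(0.5e-3, gt=0)
    grid_n: int = Field(64, ge=4)

    @model_validator(mode="after")
    def _check(self):
        if self.tumor_radius_m >= self.extent_m / 2:
            raise ValueError("tumor_radius_m must be below extent_m / 2")
        return self


class VasculatureConfig(_Section):
    target_sv_per_m: float = Field(20000.0, gt=0)
    diam_min_um: float = Field(5.0, gt=1.1)
    diam_max_um: float = Field(25.0, gt=1.1)
    depth_m: float = Field(40e-6, gt=0)
    tumor_factor: float = Field(2.5, ge=1.0)
    core_factor: float = Field(0.15, ge=0.0)
    core_radius_frac: float = Field(0.6, ge=0.0, lt=1.0)
    hematocrit: float = Field(0.45, ge=0.0, lt=1.0)
    inlet_pressure_pa: float = Field(3330.0, gt=0)
    outlet_pressure_pa: float = Field(1330.0, ge=0)
    mu_plasma_pa_s: float = Field(1.0e-3, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.diam_min_um > self.diam_max_um:
            raise ValueError("diam_min_um must not exceed diam_max_um")
        if self.outlet_pressure_pa >= self.inlet_pressure_pa:
            raise ValueError("outlet pressure must be below inlet pressure")
        return self


class RegionConfig(_Section):
    L_p: float = Field(..., ge=0)              # m/(Pa·s)
    kappa: float = Field(..., gt=0)            # m^2/(Pa·s)
    sv_nominal: float = Field(..., ge=0)       # 1/m
    lymph_coeff: float = Field(..., ge=0)      # 1/(Pa·s)
    pi_b: float = 2660.0
    pi_i: float = Field(..., ge=0)
    sigma_s: float = Field(..., ge=0, le=1)
    p_L: float = 0.0
    drug_perm_factor: float = Field(..., ge=0)
    receptor_factor: float = Field(1.0, ge=0)

    def to_params(self) -> RegionParams:
        return RegionParams(**self.model_dump())


def _default_tumor_region() -> RegionConfig:
    return RegionConfig(
        L_p=2.1e-11, kappa=3.1e-14, sv_nominal=20000.0, lymph_coeff=0.0,
        pi_i=2000.0, sigma_s=0.82, drug_perm_factor=1.0,
    )


def _default_normal_region() -> RegionConfig:
    return RegionConfig(
        L_p=2.7e-12, kappa=6.4e-15, sv_nominal=7000.0, lymph_coeff=1.042e-6,
        pi_i=1330.0, sigma_s=0.91, drug_perm_factor=0.1, receptor_factor=0.2,
    )


class TissueConfig(_Section):
    tumor: RegionConfig = Field(default_factory=_default_tumor_region)
    normal: RegionConfig = Field(default_factory=_default_normal_region)

    def to_params(self) -> TissueParams:
        return TissueParams(tumor=self.tumor.to_params(), normal=self.normal.to_params())


#: Kill-rate constant omega (m^3/mol) calibrated once so that the baseline
#: MTD first-cycle tumor FKC on the default seeded geometry is ~0.3678.
CALIBRATED_OMEGA = 59.788581  # m^3/mol, frozen by the calibration (see docs/methods.md)


class DrugConfig(_Section):
    d_diff_m2_s: float = Field(3.4e-10, ge=0)
    k_on_m3_mol_s: float = Field(15.0, ge=0)
    k_off_per_s: float = Field(1.0e-3, ge=0)
    k_int_per_s: float = Field(1.0e-2, ge=0)
    phi: float = Field(0.4, gt=0, le=1)
    sigma_f: float = Field(0.15, ge=0, le=1)
    perm_m_s: float = Field(5.7e-7, ge=0)
    c0_mol_m3: float = Field(1.0e-3, gt=0)
    half_life_min: float = Field(6.0, gt=0)
    omega_m3_mol: float = Field(default_factory=lambda: CALIBRATED_OMEGA, ge=0)
    c_rec0_mol_m3: float = Field(0.01, ge=0)

    def to_params(self) -> DrugParams:
        return DrugParams(
            d_diff=self.d_diff_m2_s, k_on=self.k_on_m3_mol_s,
            k_off=self.k_off_per_s, k_int=self.k_int_per_s, phi=self.phi,
            sigma_f=self.sigma_f, perm=self.perm_m_s, c0=self.c0_mol_m3,
            half_life=self.half_life_min * 60.0, omega=self.omega_m3_mol,
            c_rec0=self.c_rec0_mol_m3,
        )


class GrowthConfig(_Section):
    n0: float = Field(5e9, gt=0)
    n_inf: float = Field(3.1e12, gt=0)
    b_per_month: float = Field(0.0283, gt=0)
    n1: float = Field(4.64e12, gt=0)
    healthy_rate_factor: float = Field(0.5, gt=0)
    density_ratio: float = Field(0.2, gt=0)

    def to_params(self) -> GrowthParams:
        return GrowthParams(
            n0=self.n0, n_inf=self.n_inf, b=self.b_per_month, n1=self.n1,
            healthy_rate_factor=self.healthy_rate_factor,
            density_ratio=self.density_ratio,
        )


class ScheduleConfig(_Section):
    kind: Literal["MTD", "LDC", "MC", "CS", "custom"] = "MTD"
    horizon_months: float = Field(2.5, gt=0)
    mtd_dose: float = Field(1.0, gt=0)
    mtd_interval_months: float = Field(0.5, gt=0)
    ldc_dose: float = Field(0.2, gt=0)
    ldc_interval_months: float = Field(0.1, gt=0)
    custom_events: Optional[list[tuple[float, float]]] = None

    def to_schedule(self) -> Schedule:
        return build_regimen(
            self.kind if self.kind != "custom" else "custom",
            horizon_months=self.horizon_months,
            mtd_dose=self.mtd_dose, mtd_interval=self.mtd_interval_months,
            ldc_dose=self.ldc_dose, ldc_interval=self.ldc_interval_months,
            custom_events=self.custom_events,
        )


class SolverConfig(_Section):
    delivery_hours: float = Field(24.0, gt=0)
    transport_rtol: float = Field(1e-5, gt=0)
    coupling_tol_pa: float = Field(0.1, gt=0)
    coupling_max_iter: int = Field(50, ge=1)


class RunConfig(_Section):
    seed: int = Field(20210, ge=0, lt=2**31)
    domain: DomainConfig = Field(default_factory=DomainConfig)
    vasculature: VasculatureConfig = Field(default_factory=VasculatureConfig)
    tissue: TissueConfig = Field(default_factory=TissueConfig)
    drug: DrugConfig = Field(default_factory=DrugConfig)
    growth: GrowthConfig = Field(default_factory=GrowthConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)

    # ---- factories -------------------------------------------------------
    def build_grid(self) -> TissueGrid:
        d = self.domain
        return build_domain(
            tumor_radius=d.tumor_radius_m, extent=d.extent_m,
            h=d.extent_m / d.grid_n, params=self.tissue.to_params(),
        )

    def build_network(self, seed: Optional[int] = None) -> VascularNetwork:
        v = self.vasculature
        d = self.domain
        return generate_synthetic_network(
            extent=d.extent_m, target_sv=v.target_sv_per_m,
            seed=self.seed if seed is None else seed,
            diam_range_um=(v.diam_min_um, v.diam_max_um), depth=v.depth_m,
            tumor_radius=d.tumor_radius_m, tumor_factor=v.tumor_factor,
            core_factor=v.core_factor, core_radius_frac=v.core_radius_frac,
            hematocrit=v.hematocrit, inlet_pressure=v.inlet_pressure_pa,
            outlet_pressure=v.outlet_pressure_pa,
        )

    def drug_params(self) -> DrugParams:
        return self.drug.to_params()

    def growth_params(self) -> GrowthParams:
        return self.growth.to_params()

    def build_schedule(self) -> Schedule:
        return self.schedule.to_schedule()


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {path}: {err['msg']}")
    return "\n".join(lines)


def load_config(path_or_stream=None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file (or ``None``) yields all defaults.  Unknown keys and
    out-of-range values raise :class:`ConfigError` listing the offending
    key paths.
    """
    if path_or_stream is None:
        data = {}
    elif hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream.read())
    else:
        with open(path_or_stream) as f:
            data = yaml.safe_load(f)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("run configuration must be a YAML mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"invalid run configuration:\n{_format_errors(exc)}") from exc


def dump_defaults(config: Optional[RunConfig] = None) -> str:
    """Serialize a configuration (defaults if omitted) to YAML."""
    cfg = config if config is not None else RunConfig()
    return yaml.safe_dump(cfg.model_dump(), sort_keys=False)
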