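"""Run configuration: validated parameter sets for the whole pipeline,
serialisable to/from YAML."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .closure import BinWidths, ClosureTolerances
from .geometry import HBondCriteria
from .sampling import RamachandranModel, RamaRegion

__all__ = ["RunConfig", "HBondConfig", "RamaRegionConfig", "RamaConfig",
           "BinConfig", "ClosureConfig", "AssayConfig", "LoopCountsConfig"]


class HBondConfig(BaseModel):
    max_ho_distance: float = Field(2.5, gt=0)
    min_nho_angle: float = Field(135.0, ge=0, le=180)
    min_hoc_angle: float = Field(90.0, ge=0, le=180)
    min_sequence_separation: int = Field(2, ge=1)

    def build(self) -> HBondCriteria:
        return HBondCriteria(**self.model_dump())


class RamaRegionConfig(BaseModel):
    name: str
    phi_center: float
    phi_half_width: float = Field(gt=0)
    psi_center: float
    psi_half_width: float = Field(gt=0)
    weight: float = Field(1.0, ge=0)

    def build(self) -> RamaRegion:
        return RamaRegion(**self.model_dump())


_DEFAULT_REGIONS = [
    RamaRegionConfig(name="alphaR", phi_center=-95, phi_half_width=35, psi_center=-40, psi_half_width=30),
    RamaRegionConfig(name="alphaL", phi_center=95, phi_half_width=35, psi_center=40, psi_half_width=30),
    RamaRegionConfig(name="betaExt", phi_center=-130, phi_half_width=40, psi_center=135, psi_half_width=45),
    RamaRegionConfig(name="betaExtMirror", phi_center=130, phi_half_width=40, psi_center=-135, psi_half_width=45),
]


class RamaConfig(BaseModel):
    regions: list[RamaRegionConfig] = Field(default_factory=lambda: list(_DEFAULT_REGIONS))
    cis_probability: float = Field(0.1, ge=0, le=1)
    omega_jitter_deg: float = Field(5.0, ge=0)

    def build(self) -> RamachandranModel:
        return RamachandranModel(
            regions=tuple(r.build() for r in self.regions),
            cis_probability=self.cis_probability,
            omega_jitter_deg=self.omega_jitter_deg,
        )


class LoopCountsConfig(BaseModel):
    n3: int = Field(100, ge=0)
    n4: int = Field(100, ge=0)
    n5: int = Field(100, ge=0)
    max_draws: int = Field(200_000, gt=0)

    def as_dict(self) -> dict[int, int]:
        return {3: self.n3, 4: self.n4, 5: self.n5}


class BinConfig(BaseModel):
    translation: float = Field(1.0, gt=0)
    orientation_deg: float = Field(15.0, gt=0)

    def build(self) -> BinWidths:
        return BinWidths(**self.model_dump())


class ClosureConfig(BaseModel):
    terminal_rmsd: float = Field(0.5, gt=0)
    bond_length: float = Field(0.1, gt=0)
    clash_radius: float = Field(2.8, gt=0)
    ccd_gap: float = Field(0.03, gt=0)
    ccd_max_sweeps: int = Field(200, gt=0)
    neighbor_bins: bool = True

    def build(self) -> ClosureTolerances:
        return ClosureTolerances(
            terminal_rmsd=self.terminal_rmsd,
            bond_length=self.bond_length,
            clash_radius=self.clash_radius,
            ccd_gap=self.ccd_gap,
            ccd_max_sweeps=self.ccd_max_sweeps,
        )


class AssayConfig(BaseModel):
    pampa_donor_volume_ml: float = Field(0.3, gt=0)
    pampa_acceptor_volume_ml: float = Field(0.2, gt=0)
    pampa_area_cm2: float = Field(0.3, gt=0)
    pampa_time_s: float = Field(17 * 3600.0, gt=0)
    permeability_cutoff_cm_s: float = Field(1.5e-6, gt=0)


class RunConfig(BaseModel):
    """Top-level configuration; every knob of the pipeline in one
    serialisable document."""

    master_seed: int = 0
    loops: LoopCountsConfig = Field(default_factory=LoopCountsConfig)
    rama: RamaConfig = Field(default_factory=RamaConfig)
    hbond: HBondConfig = Field(default_factory=HBondConfig)
    bins: BinConfig = Field(default_factory=BinConfig)
    closure: ClosureConfig = Field(default_factory=ClosureConfig)
    assay: AssayConfig = Field(default_factory=AssayConfig)

    @field_validator("master_seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not (0 <= v < 2**31):
            raise ValueError("master seed must be in [0, 2^31)")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
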