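"""Forward simulation of a sprayed-tissue dissection plate.

The generator emulates the validation experiment used to characterise the
workflow: a tissue section uniformly sprayed with test compounds, cut with
a 96-square microgrid and collected into a plate for extraction and
LC-MS/MS readout. The model, square by square:

1. analyte mass on the square = surface density x effective cut area,
   perturbed by multiplicative lognormal spray heterogeneity (mean 1);
2. capture ~ Bernoulli(p): a failed drop yields a ``lost`` well that
   contributes nothing (cross-well contamination is not modelled — a cut
   never lands in a neighbouring well);
3. captured mass dissolves in the extraction volume; the measured extract
   concentration carries a second, independent multiplicative lognormal
   measurement error (mean 1);
4. values below the calibration range are censored to ``bql``.

All randomness flows from a single mandatory seed, so identical
configurations give byte-identical plates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.stats import binomtest

from .grid import PRESETS, TemplatePreset
from .quantify import (
    LIVER_DENSITY_G_PER_CM3,
    CalibrationModel,
    DEFAULT_CALIBRATIONS,
    TissueCutGeometry,
    WellMeasurement,
    censor_bql,
    extract_to_tissue_conc,
    plate_summary,
    tissue_mass,
)
from .wellplate import Ordering, well_for_position

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "RecoveredParameters",
    "simulate_plate",
    "recover_parameters",
    "write_truth",
]

UM2_TO_MM2 = 1e-6


class SimulationConfig(BaseModel):
    """Study conditions for one simulated plate.

    Defaults reproduce the published validation conditions: the 270x270
    template, 40 um sections, the density implied by the LLOQ table, a
    sprayed surface density of 10 ng/mm^2 (the sprayer's deposition
    arithmetic and the back-calculated well concentrations both give
    ~9-12 ng/mm^2), capture probability 0.85 (the reported average capture
    efficiency), and spray/measurement CVs of 25%/15% (combined ~29%,
    the observed well-to-well CV at small cut sizes).
    """

    preset: str = "270x270"
    thickness_um: float = Field(default=40.0, gt=0)
    density_g_per_cm3: float = Field(default=LIVER_DENSITY_G_PER_CM3, gt=0)
    surface_density_ng_mm2: float = Field(default=10.0, gt=0)
    spray_cv: float = Field(default=0.25, ge=0)
    capture_probability: float = Field(default=0.85, ge=0, le=1)
    measurement_cv: float = Field(default=0.15, ge=0)
    extract_volume_ml: float = Field(default=0.1, gt=0)
    compound: str = "loperamide"
    calibration: Optional[CalibrationModel] = None
    ordering: Ordering = Ordering.ROW_MAJOR
    seed: int  # mandatory: reproducibility is part of the contract

    @model_validator(mode="after")
    def _fill_calibration(self) -> "SimulationConfig":
        if self.calibration is None:
            cal = DEFAULT_CALIBRATIONS.get(
                self.compound,
                CalibrationModel(
                    compound=self.compound, lower_ng_ml=0.1, upper_ng_ml=500.0
                ),
            )
            object.__setattr__(self, "calibration", cal)
        return self

    @property
    def template(self) -> TemplatePreset:
        try:
            return PRESETS[self.preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
            ) from None

    @property
    def geometry(self) -> TissueCutGeometry:
        return TissueCutGeometry(
            area_um2=self.template.measured_area,
            thickness_um=self.thickness_um,
            density_g_per_cm3=self.density_g_per_cm3,
        )


@dataclass
class GroundTruth:
    """Everything the simulator knew: the target of recovery tests."""

    config: SimulationConfig
    true_mass_ng: np.ndarray  # (96,) sprayed analyte mass per square
    captured: np.ndarray  # (96,) bool
    true_extract_conc_ng_ml: np.ndarray  # (96,) pre-measurement-noise, NaN if lost
    expected_extract_conc_ng_ml: float  # noise-free value d*A/V
    true_tissue_conc_ug_g: float  # noise-free tissue concentration

    def to_dict(self) -> dict:
        return {
            "config": json.loads(self.config.model_dump_json()),
            "true_mass_ng": self.true_mass_ng.tolist(),
            "captured": self.captured.astype(int).tolist(),
            "true_extract_conc_ng_ml": [
                None if not np.isfinite(v) else v
                for v in self.true_extract_conc_ng_ml
            ],
            "expected_extract_conc_ng_ml": self.expected_extract_conc_ng_ml,
            "true_tissue_conc_ug_g": self.true_tissue_conc_ug_g,
        }


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_plate(
    config: SimulationConfig,
) -> tuple[list[WellMeasurement], GroundTruth]:
    """Simulate one 96-well plate under ``config``.

    Returns the per-well measurements (one per square, in row-major grid
    order with wells assigned per ``config.ordering``) and the ground
    truth used to generate them.
    """
    rng = np.random.default_rng(config.seed)
    preset = config.template
    n = 96
    area_mm2 = preset.measured_area * UM2_TO_MM2
    base_mass_ng = config.surface_density_ng_mm2 * area_mm2
    mass_ng = base_mass_ng * _lognormal_factor(rng, config.spray_cv, n)
    captured = rng.random(n) < config.capture_probability
    true_conc = np.where(captured, mass_ng / config.extract_volume_ml, np.nan)
    measured = true_conc * _lognormal_factor(rng, config.measurement_cv, n)

    measurements = []
    i = 0
    for r in range(1, 9):
        for c in range(1, 13):
            well = well_for_position(r, c, config.ordering)
            if not captured[i]:
                m = WellMeasurement(well, config.compound, None, "lost")
            else:
                status = censor_bql(float(measured[i]), config.calibration)
                if status == "bql":
                    m = WellMeasurement(well, config.compound, None, "bql")
                else:
                    m = WellMeasurement(
                        well, config.compound, float(measured[i]), "ok"
                    )
            measurements.append(m)
            i += 1

    mass_g = tissue_mass(config.geometry)
    truth = GroundTruth(
        config=config,
        true_mass_ng=mass_ng,
        captured=captured,
        true_extract_conc_ng_ml=true_conc,
        expected_extract_conc_ng_ml=base_mass_ng / config.extract_volume_ml,
        true_tissue_conc_ug_g=extract_to_tissue_conc(
            base_mass_ng / config.extract_volume_ml,
            config.extract_volume_ml,
            mass_g,
        ),
    )
    return measurements, truth


@dataclass
class RecoveredParameters:
    capture_probability: float
    capture_ci: tuple[float, float]
    mean_tissue_conc_ug_g: float
    cv_pct: float
    n_plates: int
    n_wells: int


def recover_parameters(
    plates: Sequence[Sequence[WellMeasurement]],
    config: SimulationConfig,
    confidence: float = 0.95,
) -> RecoveredParameters:
    """Estimate the generating parameters back from simulated plates.

    Pools all wells: capture probability as the captured fraction with an
    exact binomial (Clopper-Pearson) CI; concentration mean and CV% from
    the ok wells via :func:`lmdgrid.quantify.plate_summary`.
    """
    if not plates:
        raise ValueError("need at least one plate")
    n_wells = 0
    n_captured = 0
    tissue_vals = []
    for plate in plates:
        plate = list(plate)
        n_wells += len(plate)
        n_captured += sum(1 for m in plate if m.status != "lost")
        res = plate_summary(
            plate, config.geometry, config.extract_volume_ml, n_total=len(plate)
        )
        ok = res.wells[res.wells.status == "ok"]
        tissue_vals.append(ok.tissue_conc_ug_g.to_numpy())
    ci = binomtest(k=n_captured, n=n_wells).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    vals = np.concatenate(tissue_vals)
    if vals.size == 0:
        mean = cv = float("nan")
    else:
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        cv = 100.0 * sd / mean if mean else float("nan")
    return RecoveredParameters(
        capture_probability=n_captured / n_wells,
        capture_ci=(ci.low, ci.high),
        mean_tissue_conc_ug_g=mean,
        cv_pct=cv,
        n_plates=len(plates),
        n_wells=n_wells,
    )


def write_truth(truth: GroundTruth, destination: Union[str, Path]) -> None:
    """Write the ground-truth sidecar as JSON."""
    Path(destination).write_text(json.dumps(truth.to_dict(), indent=1))
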