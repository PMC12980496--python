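"""Drift-tube ion mobility: step-field CCS determination and single-field
arrival-time -> CCS conversion.

The step-field method records the arrival time t_A of a mobility-selected
ion at several drift voltages dV and regresses t_A on 1/dV.  Under the
Mason-Schamp low-field relation the slope is

    S = CCS * (sqrt(mu)/z) * (16 L^2 / (3 e)) * sqrt(kB T / (2 pi))
        * N0 * (T0/T) * (p/p0)

(SI units; mu the ion-gas reduced mass) and the intercept t0 is the
non-drift transit time.  A calibration factor a = CCS_ref * sqrt(mu_ref) /
(z_ref * tA_ref), anchored on a step-field measurement of one reference
peak, then converts whole arrival-time distributions recorded at a single
drift voltage: CCS = a * (z / sqrt(mu)) * t_A.  The single-field conversion
ignores t0 by construction (the factor absorbs it at the reference point);
the error this introduces grows with t0/t_A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import BOLTZMANN, DA_TO_KG, ELEMENTARY_CHARGE
from .conformers import CCSDistribution
from .ions import IonSpecies

__all__ = [
    "DriftTubeConfig",
    "StepFieldSeries",
    "StepFieldFit",
    "CalibrationFactor",
    "reduced_mass_kg",
    "forward_drift_time",
    "stepfield_fit",
    "calibration_factor",
    "convert_atd",
    "qc_gate",
    "QC_WINDOW_A2",
]

M2_TO_A2 = 1e20

#: Quality-control acceptance window for the [(dTG4T)4(NH4)3]5- reference
#: ion, around its literature CCS of 788 A^2 (closed interval).
QC_WINDOW_A2 = (785.0, 791.0)
QC_REFERENCE_CCS_A2 = 788.0

#: Drift voltages of the standard five-segment step-field protocol (V).
STEP_FIELD_VOLTAGES = (650.0, 700.0, 800.0, 900.0, 1000.0)


@dataclass(frozen=True)
class DriftTubeConfig:
    """Instrument geometry and gas conditions of the helium drift tube."""

    L: float = 0.781  # drift length, m
    p_torr: float = 3.89  # drift gas pressure
    p0_torr: float = 760.0  # standard pressure
    T: float = 296.15  # gas temperature, K
    T0: float = 273.15  # standard temperature, K
    N0: float = 2.687e25  # gas number density at (T0, p0), m^-3
    gas_mass_da: float = 4.0026  # helium

    def __post_init__(self) -> None:
        for name in ("L", "p_torr", "p0_torr", "T", "T0", "N0", "gas_mass_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p_torr >= self.p0_torr:
            raise ValueError("drift pressure must be below standard pressure")

    @property
    def number_density(self) -> float:
        """Buffer-gas number density in the tube (m^-3)."""
        return self.N0 * (self.p_torr / self.p0_torr) * (self.T0 / self.T)


@dataclass
class StepFieldSeries:
    """(drift voltage, centroid arrival time) pairs for one selected ion."""

    voltages: np.ndarray  # V
    t_arrival_s: np.ndarray  # s
    ion: IonSpecies

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.t_arrival_s = np.asarray(self.t_arrival_s, dtype=float)
        if self.voltages.shape != self.t_arrival_s.shape:
            raise ValueError("voltages and arrival times must have equal length")
        if np.any(self.t_arrival_s <= 0):
            raise ValueError("arrival times must be positive")

    @classmethod
    def from_csv(cls, path, ion: IonSpecies) -> "StepFieldSeries":
        """Read columns (delta_v_volts, t_arrival_ms); times converted to s."""
        df = pd.read_csv(path)
        return cls(
            df["delta_v_volts"].to_numpy(),
            df["t_arrival_ms"].to_numpy() * 1e-3,
            ion,
        )


@dataclass(frozen=True)
class StepFieldFit:
    ccs_a2: float
    t0_s: float
    r_squared: float
    slope_se: float
    ccs_se_a2: float
    ion: IonSpecies


@dataclass(frozen=True)
class CalibrationFactor:
    """Single-field factor a with CCS[A^2] = a * (z/sqrt(mu_kg)) * tA[s]."""

    a: float
    gas_mass_da: float
    reference: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("calibration factor must be positive")


def reduced_mass_kg(ion: IonSpecies, cfg: DriftTubeConfig) -> float:
    """Ion-gas reduced mass (kg), using the full adducted, deprotonated mass."""
    m_ion = ion.ion_mass
    mu_da = cfg.gas_mass_da * m_ion / (cfg.gas_mass_da + m_ion)
    return mu_da * DA_TO_KG


def _slope_per_m2(ion: IonSpecies, cfg: DriftTubeConfig) -> float:
    """Step-field slope (V*s) per m^2 of CCS, for the given ion and tube."""
    mu = reduced_mass_kg(ion, cfg)
    return (
        (math.sqrt(mu) / ion.z)
        * (16.0 * cfg.L**2 / (3.0 * ELEMENTARY_CHARGE))
        * math.sqrt(BOLTZMANN * cfg.T / (2.0 * math.pi))
        * cfg.number_density
    )


def forward_drift_time(
    ccs_a2: float,
    ion: IonSpecies,
    delta_v,
    t0_s: float = 0.0,
    cfg: DriftTubeConfig = DriftTubeConfig(),
):
    """Arrival time (s) of an ion of given CCS at drift voltage(s) dV.

    Exact forward model inverted by :func:`stepfield_fit`.
    """
    if ccs_a2 <= 0:
        raise ValueError("CCS must be positive")
    slope = (ccs_a2 / M2_TO_A2) * _slope_per_m2(ion, cfg)
    return t0_s + slope / np.asarray(delta_v, dtype=float)


def stepfield_fit(series: StepFieldSeries, cfg: DriftTubeConfig = DriftTubeConfig()) -> StepFieldFit:
    """OLS regression of t_A on 1/dV; CCS from the slope, t0 the intercept."""
    if np.unique(series.voltages).size < 3:
        raise ValueError("step-field fit needs at least 3 distinct voltages")
    x = 1.0 / series.voltages
    res = stats.linregress(x, series.t_arrival_s)
    per_m2 = _slope_per_m2(series.ion, cfg)
    ccs_a2 = res.slope / per_m2 * M2_TO_A2
    if ccs_a2 <= 0:
        raise ValueError("degenerate input: fitted CCS is not positive")
    return StepFieldFit(
        ccs_a2=float(ccs_a2),
        t0_s=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr if res.stderr is not None else np.nan),
        ccs_se_a2=float((res.stderr or 0.0) / per_m2 * M2_TO_A2),
        ion=series.ion,
    )


def calibration_factor(
    fit: StepFieldFit,
    tA_ref_s: float,
    ion: IonSpecies | None = None,
    cfg: DriftTubeConfig = DriftTubeConfig(),
) -> CalibrationFactor:
    """Anchor the single-field factor a on the reference ion's 650 V segment.

    a = CCS * sqrt(mu) / (z * tA_ref), so that applying it back to the
    reference arrival time returns the step-field CCS exactly.
    """
    if tA_ref_s <= 0:
        raise ValueError("reference arrival time must be positive")
    ion = ion or fit.ion
    mu = reduced_mass_kg(ion, cfg)
    a = fit.ccs_a2 * math.sqrt(mu) / (ion.z * tA_ref_s)
    return CalibrationFactor(
        a=a,
        gas_mass_da=cfg.gas_mass_da,
        reference={"ccs_a2": fit.ccs_a2, "tA_ref_s": tA_ref_s, "z": ion.z},
    )


def single_field_ccs(
    tA_s, factor: CalibrationFactor, ion: IonSpecies, cfg: DriftTubeConfig = DriftTubeConfig()
):
    """CCS (A^2) of arrival time(s) recorded at the reference drift voltage."""
    if not math.isclose(factor.gas_mass_da, cfg.gas_mass_da, rel_tol=1e-9):
        raise ValueError("calibration factor and config use different drift gases")
    mu = reduced_mass_kg(ion, cfg)
    return factor.a * (ion.z / math.sqrt(mu)) * np.asarray(tA_s, dtype=float)


def convert_atd(
    t_s: np.ndarray,
    intensity: np.ndarray,
    factor: CalibrationFactor,
    ion: IonSpecies,
    cfg: DriftTubeConfig = DriftTubeConfig(),
    condition: str | None = None,
) -> CCSDistribution:
    """Relabel an arrival-time distribution axis as CCS (intensities kept)."""
    t_s = np.asarray(t_s, dtype=float)
    if np.any(t_s <= 0):
        raise ValueError("arrival times must be positive")
    ccs = single_field_ccs(t_s, factor, ion, cfg)
    return CCSDistribution(
        ccs_a2=ccs,
        intensity=np.asarray(intensity, dtype=float).copy(),
        species=ion,
        condition=condition,
    )


def qc_gate(fit: StepFieldFit, window: tuple[float, float] = QC_WINDOW_A2) -> bool:
    """Pass iff the QC ion's fitted CCS lies in the closed window (785-791)."""
    lo, hi = window
    return lo <= fit.ccs_a2 <= hi
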