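"""Synthetic-data generators with exact ground truth.

Every input the pipeline consumes can be synthesised here: profile mass
spectra (Gaussian peaks at species m/z with nonspecific-adduct ladders),
step-field series from the forward drift-time relation, arrival-time
distributions from planted CCS modes, CIU ladders, and two-state UV
melting curves with linear baselines.  Presets encode the qualitative
population structure observed for the five 60-mers: a compact sub-Rayleigh
family, an ammonium-retaining intermediate family, and an ammonium-free
extended family, with proportions shifting with ionic strength.

All randomness flows through an explicit integer seed (no global state);
identical spec + seed gives bit-identical output, and every generator
returns a machine-readable ground-truth object alongside the data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .conformers import CCSDistribution, CIULadder
from .ions import IonSpecies, tg4t_reference_ion
from .mobility import (
    QC_REFERENCE_CCS_A2,
    STEP_FIELD_VOLTAGES,
    CalibrationFactor,
    DriftTubeConfig,
    StepFieldSeries,
    forward_drift_time,
    reduced_mass_kg,
)
from .sequences import OligoSequence, parse_shorthand
from .spectra import Spectrum

__all__ = [
    "Population",
    "MeltingParams",
    "ScenarioSpec",
    "make_spectrum",
    "make_stepfield",
    "make_atd",
    "make_ciu_ladder",
    "make_melting_curve",
    "preset",
    "PRESETS",
]

GAS_CONSTANT = 8.31446261815324  # J/(mol K)


@dataclass(frozen=True)
class Population:
    """One planted (z, modal n_NH4) population with its CCS mode(s)."""

    z: int
    n_nh4: int  # modal (specific) ammonium count
    abundance: float
    ccs_modes: tuple  # ((mean A^2, sd A^2, weight), ...)
    extra_adducts: int = 0  # nonspecific ladder length above the modal n
    ladder_decay: float = 0.5  # geometric decay of the ladder intensities
    expected_call: str | None = None  # planted scenario ground truth


@dataclass(frozen=True)
class MeltingParams:
    """Two-state melting curve: logistic in 1/T between linear baselines."""

    tm_c: float = 55.0
    dh_kj_mol: float = 250.0  # van 't Hoff unfolding enthalpy (~60 kcal/mol)
    folded_baseline: tuple[float, float] = (0.52, -0.0008)  # intercept, slope/degC
    unfolded_baseline: tuple[float, float] = (0.30, 0.0004)
    t_min_c: float = 4.0
    t_max_c: float = 90.0
    step_c: float = 0.25
    noise_sd: float = 0.0005  # absorbance units (double-beam photometric noise)


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to synthesise one sample's full dataset."""

    name: str
    shorthand: str
    populations: tuple[Population, ...]
    ionic_strength_mm: float = 150.0
    drift_cfg: DriftTubeConfig = field(default_factory=DriftTubeConfig)
    peak_sigma_mz: float = 0.12
    mz_step: float = 0.02
    mz_pad: float = 20.0
    noise_frac: float = 0.001  # baseline noise sd / tallest peak
    melting: MeltingParams = field(default_factory=MeltingParams)

    @property
    def sequence(self) -> OligoSequence:
        return parse_shorthand(self.shorthand, name=self.name)


def _species_table(spec: ScenarioSpec) -> pd.DataFrame:
    """Planted species (z, n, m/z, amplitude) including nonspecific ladders."""
    seq = spec.sequence
    rows = []
    for pop in spec.populations:
        for k in range(pop.extra_adducts + 1):
            n = pop.n_nh4 + k
            amp = pop.abundance * pop.ladder_decay**k
            ion = IonSpecies(seq, z=pop.z, n_nh4=n)
            rows.append(
                {
                    "z": pop.z,
                    "n_nh4": n,
                    "mz": ion.mz,
                    "amplitude": amp,
                    "modal": k == 0,
                }
            )
    df = pd.DataFrame(rows, columns=["z", "n_nh4", "mz", "amplitude", "modal"])
    return df.sort_values("mz", ignore_index=True)


def make_spectrum(spec: ScenarioSpec, seed: int) -> tuple[Spectrum, pd.DataFrame]:
    """Profile spectrum: Gaussian peaks at species m/z plus baseline noise.

    Returns the spectrum and the ground-truth species table.  Species
    closer in m/z than one peak width trigger a warning (they will merge).
    """
    truth = _species_table(spec)
    if truth.empty:
        mz_lo, mz_hi = 600.0, 3000.0
    else:
        mz_lo = truth["mz"].min() - spec.mz_pad
        mz_hi = truth["mz"].max() + spec.mz_pad
        gaps = np.diff(truth["mz"].to_numpy())
        if np.any(gaps < spec.peak_sigma_mz):
            warnings.warn(
                "planted species closer than one peak width: peaks will overlap",
                stacklevel=2,
            )
    mz = np.arange(mz_lo, mz_hi + spec.mz_step, spec.mz_step)
    y = np.zeros_like(mz)
    for row in truth.itertuples():
        y += row.amplitude * np.exp(
            -0.5 * ((mz - row.mz) / spec.peak_sigma_mz) ** 2
        )
    rng = np.random.default_rng(seed)
    noise_sd = spec.noise_frac * (truth["amplitude"].max() if not truth.empty else 1.0)
    y = y + rng.normal(0.0, noise_sd, size=y.size)
    return Spectrum(mz, y, label=f"{spec.name} seed={seed}"), truth


def make_stepfield(
    ion: IonSpecies,
    planted_ccs_a2: float,
    planted_t0_s: float = 0.0,
    cfg: DriftTubeConfig = DriftTubeConfig(),
    voltages=STEP_FIELD_VOLTAGES,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[StepFieldSeries, dict]:
    """Step-field series from the forward drift-time relation (+noise)."""
    if planted_ccs_a2 <= 0:
        raise ValueError("planted CCS must be positive")
    v = np.asarray(voltages, dtype=float)
    t = forward_drift_time(planted_ccs_a2, ion, v, planted_t0_s, cfg)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        t = t * (1.0 + rng.normal(0.0, noise_frac, size=t.size))
    truth = {"ccs_a2": planted_ccs_a2, "t0_s": planted_t0_s}
    return StepFieldSeries(v, t, ion), truth


def qc_calibration(
    cfg: DriftTubeConfig = DriftTubeConfig(),
    t0_s: float = 0.0,
) -> CalibrationFactor:
    """Single-field factor anchored on a synthetic QC-ion step-field run."""
    from .mobility import calibration_factor, stepfield_fit

    ion = tg4t_reference_ion()
    series, _ = make_stepfield(ion, QC_REFERENCE_CCS_A2, t0_s, cfg)
    fit = stepfield_fit(series, cfg)
    tA_ref = float(series.t_arrival_s[np.argmin(series.voltages)])
    return calibration_factor(fit, tA_ref, ion, cfg)


def make_atd(
    ion: IonSpecies,
    ccs_modes,
    factor: CalibrationFactor,
    cfg: DriftTubeConfig = DriftTubeConfig(),
    dt_s: float = 5e-5,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Arrival-time distribution with Gaussian modes planted in CCS space.

    CCS modes are mapped to arrival time through the inverse single-field
    relation t_A = CCS * sqrt(mu) / (a z); because that map is linear,
    Gaussian CCS modes stay Gaussian in arrival time.
    """
    modes = [tuple(m) for m in ccs_modes]
    if not modes:
        raise ValueError("need at least one CCS mode")
    mu = reduced_mass_kg(ion, cfg)
    scale = math.sqrt(mu) / (factor.a * ion.z)  # s per A^2
    lo = min(m - 6 * s for m, s, _ in modes) * scale
    hi = max(m + 6 * s for m, s, _ in modes) * scale
    t = np.arange(max(lo, dt_s), hi + dt_s, dt_s)
    ccs_of_t = t / scale
    y = np.zeros_like(t)
    for mean, sd, w in modes:
        y += w * np.exp(-0.5 * ((ccs_of_t - mean) / sd) ** 2)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_frac * y.max(), size=y.size), 0.0, None)
    truth = {"ccs_modes": modes}
    return t, y, truth


def make_ciu_ladder(
    modes_by_voltage: dict[float, list],
    ccs_range: tuple[float, float] = (800.0, 4500.0),
    step_a2: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CIULadder:
    """CIU ladder of CCS distributions built directly in CCS space."""
    rng = np.random.default_rng(seed)
    ccs = np.arange(*ccs_range, step_a2)
    dists = {}
    for v, modes in modes_by_voltage.items():
        y = np.zeros_like(ccs)
        for mean, sd, w in modes:
            y += w * np.exp(-0.5 * ((ccs - mean) / sd) ** 2)
        if noise_sd > 0:
            y = np.clip(y + rng.normal(0.0, noise_sd, size=y.size), 0.0, None)
        dists[float(v)] = CCSDistribution(ccs, y, condition=f"{v} V")
    return CIULadder(dists)


def two_state_theta(t_c, tm_c: float, dh_kj_mol: float):
    """Two-state folded fraction: logistic in 1/T, exactly 0.5 at Tm."""
    t_k = np.asarray(t_c, dtype=float) + 273.15
    tm_k = tm_c + 273.15
    arg = (dh_kj_mol * 1e3 / GAS_CONSTANT) * (1.0 / tm_k - 1.0 / t_k)
    return 1.0 / (1.0 + np.exp(arg))


def make_melting_curve(
    params: MeltingParams,
    seed: int = 0,
    ramp: str = "heating",
) -> tuple["MeltingCurve", dict]:
    """A(T) = L0(T) + theta(T) (L1(T) - L0(T)) + noise, on a uniform ramp."""
    from .melting import MeltingCurve

    if not (params.t_min_c < params.tm_c < params.t_max_c):
        raise ValueError("planted Tm must lie inside the temperature range")
    t = np.arange(params.t_min_c, params.t_max_c + params.step_c / 2, params.step_c)
    theta = two_state_theta(t, params.tm_c, params.dh_kj_mol)
    l1 = params.folded_baseline[0] + params.folded_baseline[1] * t
    l0 = params.unfolded_baseline[0] + params.unfolded_baseline[1] * t
    a = l0 + theta * (l1 - l0)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, params.noise_sd, size=a.size)
    if ramp == "cooling":
        t, a = t[::-1], a[::-1]
    curve = MeltingCurve(t, a, wavelength_nm=295, ramp=ramp)
    truth = {"tm_c": params.tm_c, "dh_kj_mol": params.dh_kj_mol}
    return curve, truth


# ---------------------------------------------------------------------------
# Presets: qualitative population structures of the five 60-mer constructs.
# ---------------------------------------------------------------------------

_G4TN = "dT(TG3)4T43·(NH4+)2"
_TNG4 = "dT43T(TG3)4·(NH4+)2"
_TNG4TN = "dT21T(TG3)4T22·(NH4+)2"
_G4TNG4 = "dT(TG3)4T26T(TG3)4·(NH4+)4"
_NG = "dT4GT5TGT4(GT3)5(GT2)2GT4TGT4GT4T2"


def _pop(z, n, ab, ccs, sd, call, extra=0, decay=0.5):
    return Population(
        z=z,
        n_nh4=n,
        abundance=ab,
        ccs_modes=((ccs, sd, 1.0),),
        extra_adducts=extra,
        ladder_decay=decay,
        expected_call=call,
    )


def _g4tn_150() -> ScenarioSpec:
    pops = (
        # compact sub-Rayleigh family, 2 specific NH4+ plus a nonspecific ladder
        _pop(7, 2, 0.28, 1380.0, 40.0, "CRM", extra=3),
        _pop(8, 2, 0.34, 1450.0, 40.0, "CRM", extra=3),
        # intermediate beads-on-a-string family, centred on 16-
        _pop(14, 2, 0.04, 2600.0, 60.0, "BEM", extra=1),
        _pop(15, 2, 0.06, 2700.0, 60.0, "BEM", extra=1),
        _pop(16, 2, 0.08, 2800.0, 60.0, "BEM", extra=1),
        _pop(17, 2, 0.05, 2950.0, 60.0, "BEM", extra=1),
        # extended ammonium-free family, centred on 18-
        _pop(18, 0, 0.05, 3350.0, 70.0, "CEM"),
        _pop(19, 0, 0.04, 3450.0, 70.0, "CEM"),
        _pop(20, 0, 0.03, 3550.0, 70.0, "CEM"),
        _pop(21, 0, 0.02, 3650.0, 70.0, "CEM"),
        _pop(22, 0, 0.015, 3700.0, 70.0, "CEM"),
    )
    return ScenarioSpec("G4Tn_150mM", _G4TN, pops, ionic_strength_mm=150.0)


def _g4tn_1() -> ScenarioSpec:
    pops = (
        _pop(8, 2, 0.05, 1450.0, 40.0, "CRM", extra=2),
        _pop(18, 0, 0.12, 3350.0, 70.0, "CEM"),
        _pop(20, 0, 0.25, 3550.0, 70.0, "CEM"),
        _pop(22, 0, 0.30, 3700.0, 70.0, "CEM"),
        _pop(24, 0, 0.18, 3850.0, 70.0, "CEM"),
    )
    return ScenarioSpec(
        "G4Tn_1mM",
        _G4TN,
        pops,
        ionic_strength_mm=1.0,
        melting=MeltingParams(tm_c=55.0),
    )


def _g4tng4_150() -> ScenarioSpec:
    # both termini folded: only low charge states, unimodal compact CCSD
    pops = (
        _pop(7, 4, 0.35, 1400.0, 40.0, "CRM", extra=3),
        _pop(8, 4, 0.45, 1460.0, 40.0, "CRM", extra=3),
    )
    return ScenarioSpec(
        "G4TnG4_150mM",
        _G4TNG4,
        pops,
        ionic_strength_mm=150.0,
        melting=MeltingParams(tm_c=60.0),
    )


def _tng4tn_150() -> ScenarioSpec:
    # central G4, thymine overhangs on both ends: the high-charge family has
    # lost its ammoniums at intermediate extension -- the pattern the data
    # cannot attribute to either BEM-then-unfolding or direct CEM.
    pops = (
        _pop(7, 2, 0.20, 1380.0, 40.0, "CRM", extra=3),
        _pop(8, 2, 0.25, 1450.0, 40.0, "CRM", extra=3),
        _pop(17, 0, 0.06, 2900.0, 60.0, "ambiguous"),
        _pop(18, 0, 0.08, 3000.0, 60.0, "ambiguous"),
        _pop(19, 0, 0.09, 3100.0, 60.0, "ambiguous"),
        _pop(20, 0, 0.06, 3400.0, 70.0, "CEM"),
        _pop(22, 0, 0.04, 3600.0, 70.0, "CEM"),
        _pop(24, 0, 0.02, 3800.0, 70.0, "CEM"),
    )
    return ScenarioSpec(
        "TnG4Tn_150mM",
        _TNG4TN,
        pops,
        ionic_strength_mm=150.0,
        melting=MeltingParams(tm_c=52.0),
    )


def _ng_150() -> ScenarioSpec:
    # nonstructured control: no specific coordination sites at all
    pops = (
        _pop(7, 0, 0.18, 1380.0, 40.0, "CRM", extra=2),
        _pop(8, 0, 0.22, 1450.0, 40.0, "CRM", extra=2),
        _pop(19, 0, 0.10, 3400.0, 70.0, "CEM"),
        _pop(21, 0, 0.09, 3550.0, 70.0, "CEM"),
        _pop(23, 0, 0.07, 3700.0, 70.0, "CEM"),
        _pop(26, 0, 0.04, 3900.0, 70.0, "CEM"),
    )
    return ScenarioSpec("NG_150mM", _NG, pops, ionic_strength_mm=150.0)


PRESETS = {
    "G4Tn_150mM": _g4tn_150,
    "G4Tn_1mM": _g4tn_1,
    "G4TnG4_150mM": _g4tng4_150,
    "TnG4Tn_150mM": _tng4tn_150,
    "TnG4Tn": _tng4tn_150,
    "NG_150mM": _ng_150,
    "NG": _ng_150,
}


def preset(name: str) -> ScenarioSpec:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(set(PRESETS))}")
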