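"""Mass spectra: peak picking and charge-state/ammonium annotation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .ions import IonSpecies

__all__ = [
    "Spectrum",
    "Peak",
    "ChargeStateDistribution",
    "pick_peaks",
    "assign_peaks",
    "filter_low_charges",
]


@dataclass
class Spectrum:
    """A mass spectrum on an ascending m/z axis."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""
    mode: str = "profile"  # profile | centroid

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if self.mz.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), **kwargs)

    def to_csv(self, path) -> None:
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float  # integrated intensity over the half-prominence window
    height: float


@dataclass
class ChargeStateDistribution:
    """Summed intensity per (z, n_NH4), plus the unassigned remainder."""

    entries: pd.DataFrame  # columns: z, n_nh4, intensity, assigned_mz, candidate_mz, ppm_error
    unassigned: list[Peak] = field(default_factory=list)
    filtered_range: tuple[int, int] | None = None

    def intensity_by_state(self) -> pd.DataFrame:
        return (
            self.entries.groupby(["z", "n_nh4"], as_index=False)["intensity"]
            .sum()
            .sort_values(["z", "n_nh4"], ignore_index=True)
        )

    def charges(self) -> list[int]:
        return sorted(self.entries["z"].unique())

    def modal_nh4(self, z: int) -> int:
        """The dominant (modal-by-intensity) ammonium count at charge z.

        This is how a 'specific' adduct count is read off a ladder that
        also contains nonspecific adducts: the mode, not the mean.
        """
        sub = self.entries[self.entries["z"] == z]
        if sub.empty:
            raise KeyError(f"no entries at z={z}")
        return int(sub.groupby("n_nh4")["intensity"].sum().idxmax())

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def pick_peaks(
    spec: Spectrum,
    min_snr: float = 5.0,
    min_prominence: float | None = None,
) -> list[Peak]:
    """Pick local maxima above a MAD-based noise floor and centroid them.

    The noise floor is 1.4826 x the median absolute deviation of the
    intensity; peaks must exceed ``min_snr`` times it.  Each peak is
    centroided by the intensity-weighted mean m/z over its half-prominence
    window, and its intensity is the integral over that window.
    """
    if spec.mode != "profile":
        raise ValueError("peak picking requires a profile spectrum")
    y = spec.intensity
    noise = 1.4826 * np.median(np.abs(y - np.median(y)))
    height = min_snr * noise if noise > 0 else 0.0
    prominence = min_prominence if min_prominence is not None else max(height, 1e-12)
    idx, _props = signal.find_peaks(y, height=height, prominence=prominence)
    if idx.size == 0:
        return []
    # half-prominence window of each peak
    widths = signal.peak_widths(y, idx, rel_height=0.5)
    left, right = widths[2], widths[3]
    peaks = []
    for k, i in enumerate(idx):
        lo = max(int(np.floor(left[k])), 0)
        hi = min(int(np.ceil(right[k])) + 1, y.size)
        w = y[lo:hi]
        centroid = float(np.sum(spec.mz[lo:hi] * w) / np.sum(w))
        area = float(np.trapezoid(w, spec.mz[lo:hi]))
        peaks.append(Peak(mz=centroid, intensity=area, height=float(y[i])))
    return peaks


def assign_peaks(
    peaks: list[Peak],
    candidates: list[IonSpecies],
    tol_ppm: float = 20.0,
) -> ChargeStateDistribution:
    """Match each peak to the nearest candidate m/z within ``tol_ppm``.

    Ties (equal |dm/z|) are broken toward fewer adducts, then lower charge
    (parsimony).  Unmatched peaks are kept, not discarded.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    rows = []
    unassigned = []
    cand = sorted(candidates, key=lambda s: (s.n_nh4, s.z))
    cand_mz = np.array([s.mz for s in cand])
    for pk in peaks:
        d = np.abs(cand_mz - pk.mz)
        best = int(np.lexsort((np.arange(d.size), d))[0])  # stable: first min wins
        sp = cand[best]
        ppm = (pk.mz - sp.mz) / sp.mz * 1e6
        if abs(ppm) <= tol_ppm:
            rows.append(
                {
                    "z": sp.z,
                    "n_nh4": sp.n_nh4,
                    "intensity": pk.intensity,
                    "assigned_mz": pk.mz,
                    "candidate_mz": sp.mz,
                    "ppm_error": ppm,
                }
            )
        else:
            unassigned.append(pk)
    entries = pd.DataFrame(
        rows,
        columns=["z", "n_nh4", "intensity", "assigned_mz", "candidate_mz", "ppm_error"],
    )
    return ChargeStateDistribution(entries=entries, unassigned=unassigned)


def filter_low_charges(
    csd: ChargeStateDistribution, z_min_keep: int = 5
) -> ChargeStateDistribution:
    """Drop low-charge background entries (default: z = 1- to 4-).

    Electrospray background and salt clusters dominate the low charge
    states; the analysis keeps z >= ``z_min_keep``.
    """
    kept = csd.entries[csd.entries["z"] >= z_min_keep].reset_index(drop=True)
    filtered = (1, z_min_keep - 1) if z_min_keep > 1 else None
    return ChargeStateDistribution(
        entries=kept, unassigned=list(csd.unassigned), filtered_range=filtered
    )
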