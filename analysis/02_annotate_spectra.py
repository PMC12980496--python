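#!/usr/bin/env python
"""Annotate synthetic native ESI-MS spectra of all five presets: pick
peaks, assign (charge, ammonium count), drop the low-charge background,
and compare against the generator's ground truth.

Writes results/charge_state_annotation.csv (per-species assignments) and
results/modal_ammoniums.csv (the per-charge modal NH4+ counts).
"""

from pathlib import Path

import pandas as pd

from g4ims.pipeline import annotate_spectrum
from g4ims.simulate import make_spectrum, preset

SEED = 11
PRESETS = ["G4Tn_150mM", "G4Tn_1mM", "G4TnG4_150mM", "TnG4Tn_150mM", "NG_150mM"]
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    assignments, modal_rows = [], []
    for name in PRESETS:
        spec = preset(name)
        spectrum, truth = make_spectrum(spec, seed=SEED)
        csd = annotate_spectrum(spectrum, spec.sequence)
        df = csd.entries.assign(sample=name)
        assignments.append(df)
        planted = set(map(tuple, truth[["z", "n_nh4"]].to_numpy()))
        got = set(map(tuple, df[["z", "n_nh4"]].to_numpy()))
        for z in sorted(df["z"].unique()):
            modal_rows.append(
                {"sample": name, "z": z, "modal_n_nh4": csd.modal_nh4(z)}
            )
        print(
            f"{name:14s} planted species {len(planted):3d}  assigned "
            f"{len(got):3d}  spurious {len(got - planted)}  unassigned peaks "
            f"{len(csd.unassigned)}"
        )
    OUT.mkdir(exist_ok=True)
    pd.concat(assignments).to_csv(OUT / "charge_state_annotation.csv", index=False)
    modal = pd.DataFrame(modal_rows)
    modal.to_csv(OUT / "modal_ammoniums.csv", index=False)
    print("\nModal ammonium count per charge state:")
    print(
        modal.pivot(index="z", columns="sample", values="modal_n_nh4")
        .fillna("")
        .to_string()
    )
    print(
        "\nLow charge states carry their specific inner ammoniums (2 per G4 "
        "subunit, 4 for G4TnG4) under a nonspecific adduct ladder; the "
        "highest charge states carry none — the mass dimension alone reports "
        "whether G4 beads survived ionization."
    )


if __name__ == "__main__":
    main()
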