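#!/usr/bin/env python
"""Full pipeline to ionization-scenario calls for every preset: annotate
the spectrum, convert arrival-time distributions to CCS, group conformer
families, and classify each population as CRM / BEM / CEM / ambiguous.

Writes results/scenario_calls.csv.
"""

from pathlib import Path

import pandas as pd

from g4ims.pipeline import analyze_scenario
from g4ims.simulate import preset

SEED = 11
PRESETS = ["G4Tn_150mM", "G4Tn_1mM", "G4TnG4_150mM", "TnG4Tn_150mM", "NG_150mM"]
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    frames = [analyze_scenario(preset(name), seed=SEED) for name in PRESETS]
    df = pd.concat(frames, ignore_index=True)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "scenario_calls.csv", index=False)

    cols = ["sample", "z", "modal_n_nh4", "ccs_mode", "compactness", "z_over_p",
            "nh4_retention", "call"]
    print(df[cols].round({"ccs_mode": 0, "z_over_p": 3}).to_string(index=False))
    agree = (df["call"] == df["expected_call"]).mean()
    print(f"\nAgreement with planted scenario truth: {100*agree:.0f}%")
    print(
        "\nReading: compact 7-/8- ions below the Rayleigh limit are charged-"
        "residue products; supra-Rayleigh ions that keep their inner "
        "ammoniums at intermediate extension require bead ejection (folded "
        "beads + ejected linkers); bare fully-extended ions are chain-"
        "ejection products. TnG4Tn's supra-Rayleigh, ammonium-free, "
        "intermediate populations stay 'ambiguous': bead ejection followed "
        "by Coulomb unfolding and direct chain ejection are indistinguishable "
        "there."
    )


if __name__ == "__main__":
    main()
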