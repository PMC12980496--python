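# Methods

## Sequence model and masses

Sequences are linear DNA strands with 5′-OH and 3′-OH termini, so a
strand of n bases has P = n − 1 phosphodiester linkages. Neutral masses
are computed from elemental composition (nucleoside formulas, plus one
HPO₃ and minus one H₂O per linkage) using IUPAC standard atomic weights;
hard-coded residue constants are avoided so any composition calculator
can audit the numbers. Average masses are the default because isotopes
are unresolved for ~18.5 kDa ions at z = 5–26; a monoisotopic flag
exists for small species. A G4 subunit is detected on the expanded base
string with the regular expression `G{3,}([ACT]{1,2}G{3,}){3}`,
non-overlapping left-to-right: four G-tracts of at least three guanines
with loops of one or two bases. This is a motif rule, not a folding
predictor — whether a detected motif is actually folded in solution is
out of scope. Each three-quartet subunit is expected to coordinate two
inner NH₄⁺ ions.

Negative-mode ions are modelled as [M + n·NH₄ − (z+n)·H]ᶻ⁻: every
ammonium adduct replaces a proton, for a net average shift of
m(NH₃) = 17.031 Da, and m/z = (M + n·17.031 − z·1.00728)/z.
Noncovalent assemblies (the tetramolecular QC complex) take the sum of
their strand masses with no water correction.

## Spectrum synthesis and annotation

Synthetic profile spectra are sums of Gaussian peaks (default
σ = 0.12 Th) at the m/z of every planted species plus additive Gaussian
baseline noise (default sd = 0.1% of the tallest peak — a high-quality
averaged native spectrum). Nonspecific ammonium ladders above the modal
(specific) count decay geometrically (factor 0.5); following the
observed pattern, the ladders are long on the low charge states, short
on the ammonium-retaining intermediate states, and absent on the bare
high charge states.

Annotation picks local maxima above 5× a MAD-based noise floor,
centroids each peak by the intensity-weighted mean over its
half-prominence window, and integrates over the same window. Peaks are
matched to the enumerated (z, n) candidates within 20 ppm, ties broken
toward fewer adducts then lower charge (parsimony). Charges 1–4 are
discarded as electrospray background. The "specific" ammonium count of
a charge state is the **modal** n by intensity, not the mean: a
decaying nonspecific ladder shifts a mean but not the mode. (The
alternative criterion — which adducts strip first as activation
increases — is a fragmentor-voltage experiment this pipeline does not
model, so the mode is a proxy.)

## Drift-tube CCS

The step-field regression and single-field conversion use the low-field
Mason–Schamp relation with the drift-tube defaults: L = 0.781 m,
p = 3.89 Torr, T = 296.15 K, T₀ = 273.15 K, p₀ = 760 Torr,
N₀ = 2.687 × 10²⁵ m⁻³, helium (4.0026 Da). The regression of t_A on
1/ΔV is unweighted ordinary least squares over the five-voltage grid
(650–1000 V); standard errors propagate from the regression. The
reduced mass uses the full adducted, deprotonated ion mass; for these
ions μ is within 0.05% of the helium mass, so this choice is
numerically minor. Arrival-time files are in ms by convention and
converted to seconds internally; CCS is reported in Å² (= 10²⁰ m²).

The single-field factor a is anchored on the 650 V segment of the QC
ion and **absorbs t₀ by construction**: converting another ion's
arrival time assumes the same (zero-referenced) transit offset, and the
error grows with t₀/t_A. The generators plant t₀ = 0 for single-field
data, matching the experimental practice of anchoring on a peak
measured in the same segment. The QC gate is the closed interval
785 ≤ CCS ≤ 791 Å² around the 788 Å² reference.

## Conformer families and CIU

CCS distributions are smoothed with a Gaussian kernel (default
bandwidth: 2× the axis bin width — the minimum that merges digitisation
noise); modes are local maxima of the smoothed curve and each mode's
fraction is the intensity share of its watershed basin (split at the
inter-mode minima), so fractions sum to 1. True modes closer than the
bandwidth merge — a resolution limit, documented rather than patched.
Basin fractions are an extension beyond peak-maximum reporting and are
labelled as such in outputs. Compactness classes use the G4Tn
thresholds by default (compact ≤ 1500 < gap ≤ 2500 < intermediate
≤ 3200 < extended, in Å²), boundary values going to the lower interval;
the thresholds are per-sequence configuration since the families are
sequence-dependent. CIU ladders run 300–450 V in 20 V steps; the
"soft-condition maximum" is the CCS of the global intensity maximum at
the lowest voltage present.

## Rayleigh limit and scenario rules

z_R·e = 8π√(ε₀ γ R³) with R = (3m/4πρ)^⅓, ρ = 1000 kg/m³, and
γ = 0.073 N/m (room-temperature water; configurable). The droplet mass
is the **sprayed species**: strand plus its declared (or expected)
inner ammoniums. With these choices the four G4-containing 60-mers give
z_R = 10.80–10.90 and z_R/P ≈ 0.18. A population counts as above the
limit when z > ⌊z_R⌋.

The scenario call is a total rule table over (above-Rayleigh, NH₄⁺
retention, compactness) — reproduced verbatim in
`g4ims.scenarios._rule` — whose non-obvious cells are: full retention
at extended CCS is still BEM (an elongated ion with intact beads can
only be a bead-on-a-string); no retention at intermediate CCS is
*ambiguous*, because bead ejection followed by gas-phase Coulomb
unfolding and direct chain ejection predict the same observables (the
central-G4 TnG4Tn pattern); sub-Rayleigh non-compact patterns are also
ambiguous rather than forced into a scenario. Retention is "none" when
nothing is expected (the NG control), so an unstructured compact
low-charge ion is still CRM. Ionic strength is carried as metadata only
— the call never uses it, since its influence is a tendency, not a
threshold.

## Melting

Synthetic curves follow A(T) = L0(T) + θ(T)·(L1(T) − L0(T)) with
linear baselines and a two-state θ that is logistic in 1/T,
θ = 1/(1 + exp[(ΔH/R)(1/Tm − 1/T)]); θ = 0.5 exactly at Tm. Defaults:
ΔH = 250 kJ/mol (~60 kcal/mol, a typical three-quartet intramolecular
G4), ramp 4–90 °C in 0.25 °C steps, photometric noise 5 × 10⁻⁴ AU
(double-beam instrument). At 295 nm the folded species absorbs more, so
the folded baseline is the upper one; the code assigns folded/unfolded
by the sign of the fitted-line difference at mid-range rather than by
wavelength lore, so 260 nm traces work unchanged.

Baseline windows are required inputs (they are chosen manually in
practice); the canonical windows for a Tm ≈ 55 °C construct are
4–30 °C and 78–90 °C. A window overlapping the transition is flagged
when its residual RMS exceeds 5× the trace's second-difference noise
estimate. θ is clamped to [0, 1]; the conversion refuses baselines that
cross inside the transition region. Tm is read from a local linear fit
of θ over 0.3 ≤ θ ≤ 0.7 (falling back to two-point interpolation): the
logistic is symmetric in 1/T, not T, leaving a systematic of order
0.01 °C at these widths — negligible against the ~0.03 °C noise-driven
scatter. Because the logistic tails leak slightly into any finite
baseline window, windows should end ≥ 20 °C from Tm; the analysis
driver moves the upper window up for the 60 °C construct accordingly.
A 350 nm channel, when present, is a drift diagnostic only.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the estimators
face — multimodal charge-state and CCS distributions, adduct ladders,
regression noise, baseline drift — under known ground truth, so the
round-trip tests validate the estimators and the classification logic,
not the instrument. They do not model isotopic structure, detector
saturation, overlapping charge envelopes of mixtures, ion–molecule
chemistry, or real ESI droplet physics; passing tests therefore show
that the pipeline is correct and unbiased at realistic noise, not that
a real spectrum will be as clean. Problem sizes were chosen for quick
desk-scale runs: 20 seeds for the end-to-end classification check, 100
for melting statistics, 200 for the step-field Monte Carlo.

## Numerical conventions

All internal physics is SI; physical constants come from
scipy.constants. Degenerate inputs raise rather than warn: fewer than
three step-field voltages, non-positive fitted CCS, all-zero CCS
distributions, crossing baselines, empty sequences. Assignment ties
break deterministically (fewer adducts, then lower charge); mode
finding and peak picking are deterministic for fixed input; every
generator takes an explicit integer seed and never touches global
random state.
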