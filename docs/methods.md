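# Methods

`radscav` post-processes tabulated quantum-chemical energetics of an
antioxidant — reaction free energies ΔG, reorganization energies λ,
activation free energies ΔG‡, acid dissociation constants — into the
kinetic quantities chemists actually compare: rate constants, branching
ratios, pH-corrected overall rates, chelation equilibria and repair
verdicts. It performs no electronic-structure computation; energies are
inputs, always.

## Kinetic model

**Activated rates.** Every elementary channel is scored by conventional
transition-state theory at a 1 M standard state,

    k_TST = σ κ (k_B T / h) exp(−ΔG‡ / RT),

with path degeneracy σ (default 1) and tunneling transmission κ (default 1).
Energies are in kcal mol⁻¹ with R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹; at the
default 298.15 K, RT = 0.5925 kcal mol⁻¹ and k_BT/h = 6.212×10¹² s⁻¹.
Published hydrogen-transfer rate constants routinely embed a large,
unprinted tunneling correction; they are therefore *not* recoverable from
the printed barrier with κ = 1. `fit_tunneling_factor` makes that gap
explicit (the dominant lipid-phase H-transfer channel of the reference
dataset needs κ ≈ 1.1×10³).

**Electron transfers.** When no barrier is tabulated, SET channels get the
Marcus expression ΔG‡ = (λ/4)(1 + ΔG/λ)², valid on both arms of the
parabola. The inverted region (ΔG < −λ) is handled by the bare parabola
with no quantum correction — the reference dataset contains exactly one
inverted row and the bare parabola reproduces its printed barrier.
Tabulated ΔE values are carried as metadata only: λ is never derived from
ΔE − ΔG (the printed rows do not satisfy that identity) and is always taken
as given.

**Diffusion correction.** Bimolecular channels are capped by the
Smoluchowski encounter rate k_D = 4π(r_A+r_B)(D_A+D_B)N_A with
Stokes–Einstein diffusion coefficients D = k_BT/(6πηa), blended through the
Collins–Kimball interpolation k_app = k_TST·k_D/(k_TST+k_D). Defaults:
water η = 8.91×10⁻⁴ Pa s (pentyl ethanoate 8.6×10⁻⁴ as the lipid mimic),
radii 4.0 Å (antioxidant or complex) and 2.0 Å (small radical), giving
k_D ≈ 8.3×10⁹ M⁻¹ s⁻¹. These are the package's own choices — reference
datasets rarely print theirs, and published plateau rates near 4×10⁹ imply
somewhat different encounter parameters. Consequences: recomputed
diffusion-limited rates can differ from published ones by a factor ~2, so
comparisons against published *plateau* rates (e.g. the OIL-1 up/down
verdicts) operate on the tabulated rate constants rather than recomputed
ones. Debye electrostatic factors for charged partners are not implemented
(extension hook).

## Speciation and pH dependence

A polyprotic antioxidant is a `ProtonationLadder`; state *j* carries weight
10^(j·pH − Σ_{i≤j} pKa_i), normalized with a max-exponent shift so extreme
pH never overflows. No fraction is ever floored to zero: minority species
with huge per-species rates dominate overall kinetics, which is the central
lesson of the pH correction. The corrected overall rate at a given pH is

    k_overall = f_radical(pH) · Σ_j f_j(pH) · k_total,j

where f_radical is the protonated fraction of the attacking radical
(hydroperoxyl/superoxide, pKa 4.8) — omitted for repair reactions, where
the damaged biomolecule is the partner, and in lipid media, where no
speciation applies.

**Galangin pKa constants.** The shipped defaults pKa₁ = 7.4803,
pKa₂ = 9.3446 are *derived*, not published: the reference repair table
prints both k_total and k_overall per species, and their ratio is exactly
the species' molar fraction at pH 7.4, so the fractions (0.5433, 0.4516,
0.00513) can be read off three independent rows and inverted through
Henderson–Hasselbalch. Full precision is retained because rounding to two
decimals shifts the minority-species fraction by ~1%, visibly degrading
every dianion-row reproduction. The constants are overridable from config;
a laboratory pKa set should replace them when available. One published
monoanion overall value (NF-Tyr radical) implies a fraction of 0.405
instead of ~0.4513 and is carried with an `inconsistent_print` quality flag
rather than silently used.

**pH scans** default to the physiologically motivated 1.5–8.5 range
(inclusive, step 0.01). On the galangin fixture the scan shows an acid
plateau (log k ≈ 3.81), a basin between pH 4.5 and 6 with minimum
log k ≈ 3.36 at pH ≈ 5.4, and a steep rise to pH ≈ 8 as the highly reactive
dianion accumulates; above pH ≈ 8.4 the curve flattens and turns over
marginally because radical deprotonation (one decade per pH unit)
eventually outpaces the dianion's fractional growth.

## Chelation and OIL behaviour

Per-pathway chelation equilibrium constants are K = exp(−ΔG/RT);
Maxwell–Boltzmann populations across competing binding motifs use the same
energies (shift-invariant softmax). The apparent constant combines pathway
constants as a plain sum (parallel equilibria feeding one chelated pool);
a product rule for sequential stepwise constants is selectable because the
convention behind published apparent constants is not always recoverable.
Metal-reduction (pro-oxidant) kinetics run the Marcus→Eyring→Collins–Kimball
chain and then scale by the molar fractions of both partners. OIL-1
classification compares each complex's reduction rate against the free-ion
reference per reductant (tie at equality classified "down", the
conservative call in favour of the ligand) and flags a complex as an OIL-1
agent only when it is slower with *every* reductant. OIL-2 electron
transfers are scored kinetically; hydrogen-transfer/adduct channels on the
complexes are screened thermodynamically only (sign and ranking of ΔG),
since exergonic channels of this type sit at or beyond the diffusion limit
and rates would not discriminate between them.

## Screening, repair and regeneration

Thermochemical screening keeps all exergonic channels, endergonic
H-transfer/adduct channels below +10 kcal mol⁻¹ (slightly uphill steps can
still feed fast follow-up chemistry), and *all* electron transfers (Marcus
kinetics decouple the barrier from the sign of ΔG). Repair feasibility
applies the same threshold per biomolecule target; a target with no
surviving channel is "not repairable" (the model lipid acid is the one such
case in the reference data). Site-reactivity orderings are emitted twice —
by ΔG and by ΔG‡ — because the two genuinely disagree (C5 donors are more
exergonic but slower than C7) and conflating them is a known trap.
Regeneration steps are flagged feasible (ΔG < 0), diffusion-limited
(k_app ≥ 0.5·k_D, which on the reference data coincides with barriers
≤ 3.6 kcal mol⁻¹), and cycle-closing (reprotonation ΔG⁺ < 0 where present).

## Synthetic ensembles

`generate_synthetic` emulates the *shape* of a DFT pathway ensemble, not
any particular molecule: ΔG ~ Normal(μ, σ) (defaults 0 ± 10 kcal mol⁻¹,
spanning the exergonic-to-screened range of real tables), λ ~ Uniform
(default 10–40 kcal mol⁻¹, the observed span from narrow intramolecular to
wide solvent-coupled reorganization), SET barriers from the Marcus parabola
plus Gaussian noise, and H-transfer/adduct barriers from
max(0, ΔG + 17.5) + noise — the 17.5 kcal mol⁻¹ offset reproduces the
near-linear ΔG→ΔG‡ correlation of the reference H-transfer rows. A
configurable fraction of SET records is forced into the inverted region.
What it does *not* emulate: correlated errors between sites of one species,
tunneling, solvent-specific barrier shifts, or realistic site labels — so
passing property tests demonstrate the algebra and pipeline plumbing, not
chemical accuracy on real systems. Zero-noise ensembles must round-trip the
Marcus pipeline exactly; noisy ensembles are used for λ recovery by
nonlinear least squares (scipy `curve_fit`), asserted within 3 standard
errors at n = 200 SET records.

## Numerical choices and limitations

- Branching ratios are computed from unrounded rate constants; sums of
  3-significant-figure table entries reproduce printed totals to ~1% and
  printed ratios to ≤0.1 percentage point.
- Collins–Kimball returns 0 when both rates vanish; all-zero branching
  input is an error, not NaN.
- Speciation and Boltzmann weights use max-shift stabilization; fractions
  sum to 1 within 1e-12 across the full pH/energy range.
- Problem sizes in the test suite (ensembles of ≤10⁴ records, 0.01-pH
  grids) keep the whole suite at a few seconds while leaving statistical
  assertions (3-SE bands) meaningful.
- Known limitations: no Eckart/Wigner tunneling from imaginary frequencies
  (inputs absent from energy tables), no electrostatic work terms on k_D,
  macro-state speciation only (no tautomer resolution), and published
  diffusion-plateau rates are matched in order of magnitude, not digit by
  digit.
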