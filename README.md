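# radscav

Antioxidant reaction kinetics from tabulated quantum-chemical energetics.

Computational antioxidant studies end with tables: reaction free energies
(ΔG), reorganization energies (λ), activation free energies (ΔG‡) and pKa
values for every scavenging, chelation, repair and regeneration channel of
a compound. `radscav` is the post-processing layer that turns those tables
into the numbers chemists compare — rate constants, branching ratios,
pH-corrected overall rates, chelation equilibria and repair verdicts. It is
written for computational chemists and kineticists who already have the
energies (from DFT or elsewhere) and want reproducible, auditable kinetics
on top of them. It performs no electronic-structure computation.

The core model chain, per reaction channel:

- **Marcus theory** for electron transfers without a tabulated barrier:
  ΔG‡ = (λ/4)(1 + ΔG/λ)², valid on both arms of the parabola including the
  inverted region (ΔG < −λ);
- **transition-state theory** (Eyring): k_TST = σκ(k_BT/h)·exp(−ΔG‡/RT) at
  the 1 M standard state;
- **diffusion control** (Stokes–Einstein → Smoluchowski → Collins–Kimball):
  k_app = k_TST·k_D/(k_TST + k_D);
- **speciation** (Henderson–Hasselbalch, polyprotic): molar fractions f_j
  of each protonation state and of the attacking radical, giving
  k_overall = f_radical(pH)·Σ_j f_j(pH)·k_total,j.

Shipped fixtures encode the published kinetic tables for the flavonol
galangin reacting with the hydroperoxyl radical (•OOH, pKa 4.8), its Cu(II)
chelates and their hydroxyl-radical chemistry, and its repair/regeneration
reactions with model biomolecules — the worked reference dataset for every
module.

## Worked example

Overall hydroperoxyl-scavenging rate of galangin in water at pH 7.4, from
the three species' total rate constants:

```python
from radscav import corrected_overall, ph_scan
from radscav.datasets import load_fixture, galangin_ladder, hydroperoxyl_pair

fixture = load_fixture("table1")
res = corrected_overall(
    fixture.aqueous_totals(),        # [6.46e3, 5.11e4, 4.83e9] M^-1 s^-1
    galangin_ladder(),               # pKa 7.4803, 9.3446 (derived constants)
    hydroperoxyl_pair(),             # radical pKa 4.8
    ph=7.4,
)
print([f"{f:.4f}" for f in res.fractions], f"{res.radical_fraction:.4f}")
print([f"{k:.3g}" for k in res.k_corrected], f"{res.k_overall:.3g}")

scan = ph_scan(fixture.aqueous_totals(), galangin_ladder(), hydroperoxyl_pair())
print(f"min log10 k = {scan.min_log10_k:.2f} at pH {scan.argmin_ph:.2f}")
```

prints

```
['0.5433', '0.4516', '0.0051'] 0.0025
['8.79', '57.8', '6.21e+04'] 6.22e+04
min log10 k = 3.36 at pH 5.38
```

Read: at pH 7.4 the neutral form holds 54% of the population but
contributes ~9 M⁻¹ s⁻¹ once corrected for the 0.25% of the radical that is
protonated; the dianion, though only 0.5% of the population, dominates the
overall rate constant of ≈6.2×10⁴ M⁻¹ s⁻¹ because its per-species rate sits
at the diffusion limit. The pH scan locates the activity minimum
(log k ≈ 3.4) in the basin near pH 5.4.

The same pipeline is exposed on the command line:

```
radscav type1 --ph 7.4            # per-pathway rates, branching ratios, k_overall
radscav phscan --out scan.csv     # pH dependence of the overall rate
radscav type2 --mode oil1         # chelate vs free-ion reduction verdicts
radscav type3                     # biomolecule repair feasibility and rates
radscav regeneration              # superoxide-mediated regeneration cycle
radscav synth --seed 1 --out e.csv  # synthetic pathway ensemble
```

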