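"""Physical constants and package-wide defaults.

Energies are Gibbs free energies in kcal mol-1 throughout the package;
temperatures in kelvin; bimolecular rate constants in M-1 s-1 referenced
to the 1 mol L-1 standard state.
"""

# CODATA 2018 exact values
BOLTZMANN_J: float = 1.380649e-23  # J K-1
PLANCK_J: float = 6.62607015e-34  # J s
AVOGADRO: float = 6.02214076e23  # mol-1

#: Gas constant in kcal mol-1 K-1 (R = 8.31446 J mol-1 K-1 / 4184 J kcal-1).
R_KCAL: float = 1.987204e-3

#: Default absolute temperature (K) for all kinetic evaluations.
DEFAULT_TEMPERATURE: float = 298.15

# Solvent viscosities at 298.15 K, Pa s.  Water and pentyl ethanoate are the
# aqueous and lipid-mimetic media used for the galangin study conditions.
WATER_VISCOSITY: float = 8.91e-4
PENTYL_ETHANOATE_VISCOSITY: float = 8.6e-4

# Default hydrodynamic radii (angstrom) for the Stokes-Einstein /
# Smoluchowski diffusion limit: a flavonoid-sized antioxidant (or its metal
# complex) against a small oxygen-centred radical.
DEFAULT_RADIUS_ANTIOXIDANT: float = 4.0
DEFAULT_RADIUS_RADICAL: float = 2.0

#: Acid dissociation constant of the hydroperoxyl/superoxide pair
#: (HOO*/O2*-).  Only the minor protonated form attacks biological targets.
HYDROPEROXYL_PKA: float = 4.8

# Sequential macroscopic pKa values of galangin (H3Glg -> H2Glg- -> HGlg2-).
# DERIVED constants: the study's own dissociation constants are not printed
# in its main tables, so these were back-calculated from the ratio of
# overall to total repair rate constants, which equals the molar fraction of
# the reacting species at pH 7.4, and inverted through
# Henderson-Hasselbalch (f(H3Glg) = 9.23/17.0, f(H2Glg-) = 70.4/156,
# f(HGlg2-) = 1.21e-6/2.36e-4).  Override via user config where better
# values are available.
GALANGIN_PKA1: float = 7.4803
GALANGIN_PKA2: float = 9.3446

#: Thermochemical screening threshold (kcal mol-1): endergonic hydrogen
#: transfer / adduct pathways above this reaction free energy are dropped
#: from kinetic evaluation; electron transfers are always kept because
#: Marcus theory links their barrier to the reorganization energy rather
#: than to the sign of the reaction free energy.
ENDERGONIC_DG_THRESHOLD: float = 10.0

#: Default pH grid for speciation-corrected rate scans (stomach acidity to
#: small-intestine alkalinity), inclusive endpoints.
PH_SCAN_RANGE: tuple[float, float] = (1.5, 8.5)
PH_SCAN_STEP: float = 0.01
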