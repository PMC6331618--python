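"""Internal unit system and physical constants.

Internal units throughout the package: length nm, energy kJ/mol, mass u,
charge e, time ps, temperature K, pressure (internal) kJ/mol/nm^3.
Published quantities of interest are converted at I/O boundaries to the
units they are conventionally reported in: g/cm^3 (density), dimensionless
(dielectric constant), mN/m (surface tension), 1e-6/bar (isothermal
compressibility), mPa*s (shear viscosity).
"""

# Boltzmann constant, kJ/mol/K (identical to the molar gas constant R in
# these units).
KB = 0.00831446261815324

# Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2.
F_COULOMB = 138.935458

# Molar mass of water, g/mol (equivalently u per molecule).
M_WATER = 18.0153

# 1 kJ/mol/nm^3 expressed in bar.
PRESSURE_BAR = 16.6054

# 1 kJ/mol/nm^2 expressed in mN/m.
SURFACE_TENSION_MN_M = 1.66054

# 1 kJ/mol * ps / nm^3 expressed in mPa*s.
VISCOSITY_MPAS = 1.66054e-3

# 1 u/nm^3 expressed in g/cm^3.
DENSITY_G_CM3 = 1.66053906892e-3

DEG = 0.017453292519943295  # radians per degree
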