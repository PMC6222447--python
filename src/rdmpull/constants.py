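"""Physical constants in the MD unit system (nm, ps, kJ/mol, e, K).

All lengths are nanometres throughout the package, so spring constants come
out in kJ/(mol nm^2) and forces in kJ/mol/nm, matching GROMACS conventions.
"""

from scipy import constants as _sc

#: Avogadro's number, 1/mol.
AVOGADRO = _sc.Avogadro

#: Boltzmann constant in kJ/(mol K); kB*T at 310 K is ~2.58 kJ/mol.
KB_KJ_PER_MOL_K = _sc.R / 1000.0  # 0.008314462...

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2 (GROMACS f_elec).
COULOMB_KJ_NM_PER_E2 = (
    _sc.e**2 / (4.0 * _sc.pi * _sc.epsilon_0) * AVOGADRO / 1000.0 * 1e9
)  # 138.935...

#: Conversion of a dipole moment from e*nm to Debye (1 D = 1e-21/c C m).
DEBYE_PER_E_NM = _sc.e * 1e-9 / (1e-21 / _sc.c)  # 48.0320...

#: kJ/(mol nm^2) -> pN/nm for a harmonic spring constant.
PN_PER_NM_PER_KJ_MOL_NM2 = 1e24 / AVOGADRO  # 1.66054...
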