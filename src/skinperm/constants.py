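"""Physical constants and unit-conversion factors.

Internal canonical units are fixed throughout the package: depth z in nm,
free energies in kJ/mol, diffusion coefficients in nm^2/ps, friction in
ps/nm^2, temperature in K.  Conversions to the experimental reporting units
(permeation resistance in s/cm, permeability coefficient in cm/s) happen
only at the reporting boundary.
"""

#: Molar gas constant in kJ/(mol K).
R_GAS_KJ_PER_MOL_K = 0.0083144626

#: 1 ps/nm = 1e-12 s / 1e-7 cm = 1e-5 s/cm (resistance conversion).
PS_PER_NM_TO_S_PER_CM = 1e-5

#: 1 nm/ps = 1e-7 cm / 1e-12 s = 1e5 cm/s (permeability conversion).
NM_PER_PS_TO_CM_PER_S = 1e5

#: Polar headgroup window of the lipid lamella in the symmetrized
#: half-coordinate (nm); charged permeants localize here.
HEADGROUP_WINDOW_NM = (2.9, 3.3)


def thermal_energy(temperature: float) -> float:
    """kT in kJ/mol at the given temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return R_GAS_KJ_PER_MOL_K * temperature
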