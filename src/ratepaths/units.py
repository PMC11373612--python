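"""Unit system: Å, ps, amu, kcal/mol.

With these base units, energies expressed in kcal/mol must be converted to the
mechanical unit amu·Å²/ps² before entering equations of motion.
"""

#: 1 kcal/mol in amu·Å²/ps² (4184 J/mol / (1e-3 kg/g · 1e20 Å²/m² · 1e-24 ps²/s²) scale).
KCAL_PER_MOL_IN_AMU_A2_PS2 = 418.4
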