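"""Physical constants in the package's internal unit system (nm, ps, kJ/mol, K)."""

#: Boltzmann constant, kJ mol^-1 K^-1 (CODATA value in molar units).
KB = 0.0083144621

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0
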