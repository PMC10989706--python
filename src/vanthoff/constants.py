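"""Physical constants used throughout the package."""

#: Molar gas constant R in J mol^-1 K^-1 (CODATA exact value).
GAS_CONSTANT: float = 8.31446261815324

#: Offset between the Celsius and Kelvin scales.
CELSIUS_OFFSET: float = 273.15
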