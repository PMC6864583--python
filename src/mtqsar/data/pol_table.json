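{"property": "POL", "units": "A^3", "source": "atomic static dipole polarizabilities, CRC Handbook 97th ed.", "version": "builtin-1"}
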