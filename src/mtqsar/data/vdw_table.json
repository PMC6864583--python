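{"property": "VDW", "units": "A^3", "source": "sphere volumes from Bondi van der Waals radii (J. Phys. Chem. 1964)", "version": "builtin-1"}
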