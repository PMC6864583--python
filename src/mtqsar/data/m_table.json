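{"property": "M", "units": "Da", "source": "IUPAC 2021 standard atomic weights (abridged)", "version": "builtin-1"}
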