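{"property": "E", "units": "Pauling units", "source": "Pauling scale, CRC Handbook 97th ed.", "version": "builtin-1"}
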