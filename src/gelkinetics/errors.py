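class GelKineticsError(ValueError):
    """Contract violation in gelkinetics inputs (bad parameters, malformed files,
    geometrically unrealizable requests, analyses run on unsuitable data)."""
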