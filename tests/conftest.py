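import typinfer

# a domain dataclass, not a test case, despite the Test* name
typinfer.TestCharacteristics.__test__ = False
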