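1. Define the concept of chemically induced diseases clearly.
2. Determine whether chemical entity {head} induces the occurrence of disease entity {tail}.
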