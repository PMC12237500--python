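1. Define what constitutes a drug-induced adverse event.
2. Determine whether drug entity {head} causes the adverse event entity {tail}.
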