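1. Define what it means for a gene to be associated with a disease.
2. Determine whether gene entity {head} is related to disease entity {tail}.
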