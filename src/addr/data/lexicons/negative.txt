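# Tokens indicating an adverse (negative) drug-disease signal.
# One lowercase token per line; matched on word boundaries. Lines starting
# with '#' are comments.
worsened
worsening
exacerbated
deteriorated
toxicity
toxic
adverse
harmful
deleterious
hazardous
aggravated
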