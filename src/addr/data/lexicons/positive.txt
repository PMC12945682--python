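# Tokens indicating a therapeutic (positive) drug-disease signal.
# One lowercase token per line; matched on word boundaries. Lines starting
# with '#' are comments.
improved
improves
improvement
ameliorated
attenuated
rescued
neuroprotective
protective
beneficial
benefit
efficacious
efficacy
slowed
reversed
alleviated
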