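# Combination-therapy scenario: first-line rhTNFR:Fc plus methotrexate versus
# methotrexate alone; efficacy proxied from originator-plus-MTX trials.
name: combination
intervention_strategy: strategy_combination.yaml
overrides: {}
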