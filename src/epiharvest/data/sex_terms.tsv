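# bundled sex-term gazetteer (surface form <TAB> class)
men	SEX
women	SEX
male	SEX
female	SEX
males	SEX
females	SEX
boys	SEX
girls	SEX
intersex	SEX
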