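# prescriptive-channel token patterns: id <TAB> class <TAB> pattern
# pattern elements: NUM (numeric token), literal, (a|b) alternation; suffix ? or *
epi_head	EPI	(point|birth|annual|annualized|estimated|pooled|overall|crude|lifetime|period|minimal)* (prevalence|incidence|occurrence|frequency) (rate|rates|estimate|estimates)?
epi_at_birth	EPI	(prevalence|incidence) at birth
stat_in	STAT	NUM in every? NUM live? (births|inhabitants|newborns|people|persons|lives|population)?
stat_colon	STAT	NUM : NUM
stat_slash	STAT	NUM / NUM live? (births|inhabitants|newborns|people|persons|lives|population)?
stat_per_num	STAT	NUM per NUM live? (births|inhabitants|newborns|people|persons|lives|population)?
stat_per_word	STAT	NUM per (million|thousand) live? (births|inhabitants|newborns|people|persons|lives|population)?
stat_percent	STAT	NUM %
stat_cases	STAT	NUM (cases|case)
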