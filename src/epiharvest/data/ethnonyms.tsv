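# bundled mini ethnonym/demonym gazetteer (surface form <TAB> class)
Finnish	ETHN
Swedish	ETHN
Norwegian	ETHN
Danish	ETHN
Icelandic	ETHN
French	ETHN
German	ETHN
Italian	ETHN
Spanish	ETHN
Dutch	ETHN
Czech	ETHN
Polish	ETHN
Greek	ETHN
Turkish	ETHN
Japanese	ETHN
Chinese	ETHN
Korean	ETHN
Indian	ETHN
Iranian	ETHN
Jordanian	ETHN
Jordanians	ETHN
Qatari	ETHN
Kuwaiti	ETHN
Arab	ETHN
Arabian	ETHN
Ashkenazi Jew	ETHN
Ashkenazi Jewish	ETHN
Marshallese	ETHN
African Americans	ETHN
African American	ETHN
Brazilian	ETHN
Nepalese	ETHN
Yupik	ETHN
Roma	ETHN
Amish	ETHN
Hispanic	ETHN
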