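# bundled mini location gazetteer (surface form <TAB> class)
the United States	LOC
United States	LOC
North Dakota	LOC
Arkansas	LOC
California	LOC
Texas	LOC
New York	LOC
Minnesota	LOC
Canada	LOC
Mexico	LOC
Brazil	LOC
Argentina	LOC
Finland	LOC
northern Finland	LOC
Sweden	LOC
Norway	LOC
Northern Norway	LOC
Denmark	LOC
Iceland	LOC
Estonia	LOC
France	LOC
Germany	LOC
Italy	LOC
Spain	LOC
Portugal	LOC
the Netherlands	LOC
Belgium	LOC
Switzerland	LOC
Austria	LOC
Poland	LOC
the Czech Republic	LOC
Czech Republic	LOC
Slovakia	LOC
Hungary	LOC
Greece	LOC
Turkey	LOC
the United Kingdom	LOC
England	LOC
Scotland	LOC
Wales	LOC
Ireland	LOC
Japan	LOC
China	LOC
South Korea	LOC
Taiwan	LOC
India	LOC
Pakistan	LOC
Iran	LOC
Iraq	LOC
Israel	LOC
Jordan	LOC
Amman	LOC
Kuwait	LOC
Qatar	LOC
Saudi Arabia	LOC
the Arabian Gulf	LOC
Arabian Gulf	LOC
Egypt	LOC
Morocco	LOC
Tunisia	LOC
Nigeria	LOC
South Africa	LOC
Kenya	LOC
Ethiopia	LOC
Australia	LOC
New Zealand	LOC
Russia	LOC
Ukraine	LOC
Kazakhstan	LOC
the Middle East	LOC
North Africa	LOC
Southeast Asia	LOC
Scandinavia	LOC
Europe	LOC
North America	LOC
South America	LOC
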