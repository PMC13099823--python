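# Mock drug-name synonym table (synthetic stand-in for a trade-name ->
# generic-name dictionary).  Tab-separated: raw name<TAB>generic name,
# case-insensitive after whitespace normalization.
folotyn	pralatrexate
pralatrexate	pralatrexate
pralatrexate injection	pralatrexate
trexall	methotrexate
methotrexate	methotrexate
istodax	romidepsin
romidepsin	romidepsin
beleodaq	belinostat
belinostat	belinostat
adcetris	brentuximab vedotin
brentuximab vedotin	brentuximab vedotin
revlimid	lenalidomide
lenalidomide	lenalidomide
rituxan	rituximab
rituximab	rituximab
gemzar	gemcitabine
gemcitabine	gemcitabine
treanda	bendamustine
bendamustine	bendamustine
oncovin	vincristine
vincristine	vincristine
adriamycin	doxorubicin
doxorubicin	doxorubicin
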