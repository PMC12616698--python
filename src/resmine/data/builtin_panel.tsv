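hook_id	source_locus	category	annotation
HK01	synthetic	housekeeping	acetolactate synthase (synthetic bait)
HK02	synthetic	housekeeping	inosine-5'-monophosphate dehydrogenase (synthetic bait)
HK03	synthetic	housekeeping	proteasome subunit beta (synthetic bait)
HK04	synthetic	housekeeping	sphingolipid C4-hydroxylase (synthetic bait)
HK05	synthetic	housekeeping	adenylosuccinate synthetase (synthetic bait)
HK06	synthetic	housekeeping	phospho-2-dehydro-3-deoxyheptonate aldolase (synthetic bait)
HK07	synthetic	housekeeping	HMG-CoA reductase (synthetic bait)
HK08	synthetic	housekeeping	cyclophilin-type peptidyl-prolyl isomerase (synthetic bait)
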