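class_label	chemical
control	DMSO
control	water
anti-microbial	cyclosporin A
cancer-related drugs	vinblastine sulfate
cancer-related drugs	cytochalasin
energetics	TNT
halogenated contaminants
hormones and endocrine disruptors
inflammatory mediators	aspirin
inflammatory mediators	ibuprofen
inflammatory mediators	LPS
lipid and peroxisomal mediators
metals	zinc
oxidative stress mediators
pesticides
polyaromatic hydrocarbons
PPCPs
PXR mediators	dexamethasone
PXR mediators	ketoconazole
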