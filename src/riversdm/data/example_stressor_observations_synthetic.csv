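site,category,component
karnali,hydromorph_eco_degradation,irrigation intake and embankment
karnali,activities_facilities,vehicle crossing along river
geruwa,hydromorph_eco_degradation,fishing with toxins
geruwa,sanitation,bathing and washing
marin,hydromorph_eco_degradation,fishing with toxins
marin,effluents,agricultural effluent
seti,hydromorph_eco_degradation,sand quarrying
seti,effluents,agricultural effluent
kali,sanitation,bathing and washing
bijayapur,activities_facilities,vehicle washing
phurse,hydromorph_eco_degradation,bank cutting
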