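site,ph,temp_c,conductivity_us,tds_mg_l,do_mg_l
karnali,8.1,28.8,418.0,282.0,6.8
geruwa,8.3,26.4,352.5,236.0,5.62
marin,8.7,24.1,275.0,184.0,7.9
seti,7.8,14.9,177.2,118.0,9.7
kali,8.0,16.5,205.8,138.0,9.1
bijayapur,8.2,19.7,240.3,161.0,8.4
phurse,8.5,21.2,310.6,208.0,6.1
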