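trait	kind	lo	hi	members
Vt	interval	28	30	
D_spines	interval	13	14	
D_rays	interval	9	11	
A_spines	interval	3	3	
A_rays	interval	8	10	
LL	interval	2	2	
#Lt	interval	4	4	
#Sn	interval	1	1	
VtPtLDs	interval	12	14	
scale_type	cat_set			cycloid
flank_scale_wl_ratio	interval	1.0	1.0	
lacrimal_depth_pctHL	interval	12	12	
notch_on_cleithrum	cat_set			absent
supraneural_shape	cat_set			club-shaped
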