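five_in	three_in	deacylate	cap_clip	pnk	alkb	five_out	three_out
P	OH	0	0	0	0	P	OH
P	OH	0	0	0	1	P	OH
P	OH	0	0	1	0	P	OH
P	OH	0	0	1	1	P	OH
P	OH	0	1	0	0	P	OH
P	OH	0	1	0	1	P	OH
P	OH	0	1	1	0	P	OH
P	OH	0	1	1	1	P	OH
P	OH	1	0	0	0	P	OH
P	OH	1	0	0	1	P	OH
P	OH	1	0	1	0	P	OH
P	OH	1	0	1	1	P	OH
P	OH	1	1	0	0	P	OH
P	OH	1	1	0	1	P	OH
P	OH	1	1	1	0	P	OH
P	OH	1	1	1	1	P	OH
P	P	0	0	0	0	P	P
P	P	0	0	0	1	P	P
P	P	0	0	1	0	P	OH
P	P	0	0	1	1	P	OH
P	P	0	1	0	0	P	P
P	P	0	1	0	1	P	P
P	P	0	1	1	0	P	OH
P	P	0	1	1	1	P	OH
P	P	1	0	0	0	P	P
P	P	1	0	0	1	P	P
P	P	1	0	1	0	P	OH
P	P	1	0	1	1	P	OH
P	P	1	1	0	0	P	P
P	P	1	1	0	1	P	P
P	P	1	1	1	0	P	OH
P	P	1	1	1	1	P	OH
P	cP	0	0	0	0	P	cP
P	cP	0	0	0	1	P	cP
P	cP	0	0	1	0	P	OH
P	cP	0	0	1	1	P	OH
P	cP	0	1	0	0	P	cP
P	cP	0	1	0	1	P	cP
P	cP	0	1	1	0	P	OH
P	cP	0	1	1	1	P	OH
P	cP	1	0	0	0	P	cP
P	cP	1	0	0	1	P	cP
P	cP	1	0	1	0	P	OH
P	cP	1	0	1	1	P	OH
P	cP	1	1	0	0	P	cP
P	cP	1	1	0	1	P	cP
P	cP	1	1	1	0	P	OH
P	cP	1	1	1	1	P	OH
P	aa	0	0	0	0	P	aa
P	aa	0	0	0	1	P	aa
P	aa	0	0	1	0	P	aa
P	aa	0	0	1	1	P	aa
P	aa	0	1	0	0	P	aa
P	aa	0	1	0	1	P	aa
P	aa	0	1	1	0	P	aa
P	aa	0	1	1	1	P	aa
P	aa	1	0	0	0	P	OH
P	aa	1	0	0	1	P	OH
P	aa	1	0	1	0	P	OH
P	aa	1	0	1	1	P	OH
P	aa	1	1	0	0	P	OH
P	aa	1	1	0	1	P	OH
P	aa	1	1	1	0	P	OH
P	aa	1	1	1	1	P	OH
OH	OH	0	0	0	0	OH	OH
OH	OH	0	0	0	1	OH	OH
OH	OH	0	0	1	0	P	OH
OH	OH	0	0	1	1	P	OH
OH	OH	0	1	0	0	OH	OH
OH	OH	0	1	0	1	OH	OH
OH	OH	0	1	1	0	P	OH
OH	OH	0	1	1	1	P	OH
OH	OH	1	0	0	0	OH	OH
OH	OH	1	0	0	1	OH	OH
OH	OH	1	0	1	0	P	OH
OH	OH	1	0	1	1	P	OH
OH	OH	1	1	0	0	OH	OH
OH	OH	1	1	0	1	OH	OH
OH	OH	1	1	1	0	P	OH
OH	OH	1	1	1	1	P	OH
OH	P	0	0	0	0	OH	P
OH	P	0	0	0	1	OH	P
OH	P	0	0	1	0	P	OH
OH	P	0	0	1	1	P	OH
OH	P	0	1	0	0	OH	P
OH	P	0	1	0	1	OH	P
OH	P	0	1	1	0	P	OH
OH	P	0	1	1	1	P	OH
OH	P	1	0	0	0	OH	P
OH	P	1	0	0	1	OH	P
OH	P	1	0	1	0	P	OH
OH	P	1	0	1	1	P	OH
OH	P	1	1	0	0	OH	P
OH	P	1	1	0	1	OH	P
OH	P	1	1	1	0	P	OH
OH	P	1	1	1	1	P	OH
OH	cP	0	0	0	0	OH	cP
OH	cP	0	0	0	1	OH	cP
OH	cP	0	0	1	0	P	OH
OH	cP	0	0	1	1	P	OH
OH	cP	0	1	0	0	OH	cP
OH	cP	0	1	0	1	OH	cP
OH	cP	0	1	1	0	P	OH
OH	cP	0	1	1	1	P	OH
OH	cP	1	0	0	0	OH	cP
OH	cP	1	0	0	1	OH	cP
OH	cP	1	0	1	0	P	OH
OH	cP	1	0	1	1	P	OH
OH	cP	1	1	0	0	OH	cP
OH	cP	1	1	0	1	OH	cP
OH	cP	1	1	1	0	P	OH
OH	cP	1	1	1	1	P	OH
OH	aa	0	0	0	0	OH	aa
OH	aa	0	0	0	1	OH	aa
OH	aa	0	0	1	0	P	aa
OH	aa	0	0	1	1	P	aa
OH	aa	0	1	0	0	OH	aa
OH	aa	0	1	0	1	OH	aa
OH	aa	0	1	1	0	P	aa
OH	aa	0	1	1	1	P	aa
OH	aa	1	0	0	0	OH	OH
OH	aa	1	0	0	1	OH	OH
OH	aa	1	0	1	0	P	OH
OH	aa	1	0	1	1	P	OH
OH	aa	1	1	0	0	OH	OH
OH	aa	1	1	0	1	OH	OH
OH	aa	1	1	1	0	P	OH
OH	aa	1	1	1	1	P	OH
cap_m7G	OH	0	0	0	0	cap_m7G	OH
cap_m7G	OH	0	0	0	1	cap_m7G	OH
cap_m7G	OH	0	0	1	0	cap_m7G	OH
cap_m7G	OH	0	0	1	1	cap_m7G	OH
cap_m7G	OH	0	1	0	0	P	OH
cap_m7G	OH	0	1	0	1	P	OH
cap_m7G	OH	0	1	1	0	P	OH
cap_m7G	OH	0	1	1	1	P	OH
cap_m7G	OH	1	0	0	0	cap_m7G	OH
cap_m7G	OH	1	0	0	1	cap_m7G	OH
cap_m7G	OH	1	0	1	0	cap_m7G	OH
cap_m7G	OH	1	0	1	1	cap_m7G	OH
cap_m7G	OH	1	1	0	0	P	OH
cap_m7G	OH	1	1	0	1	P	OH
cap_m7G	OH	1	1	1	0	P	OH
cap_m7G	OH	1	1	1	1	P	OH
cap_m7G	P	0	0	0	0	cap_m7G	P
cap_m7G	P	0	0	0	1	cap_m7G	P
cap_m7G	P	0	0	1	0	cap_m7G	OH
cap_m7G	P	0	0	1	1	cap_m7G	OH
cap_m7G	P	0	1	0	0	P	P
cap_m7G	P	0	1	0	1	P	P
cap_m7G	P	0	1	1	0	P	OH
cap_m7G	P	0	1	1	1	P	OH
cap_m7G	P	1	0	0	0	cap_m7G	P
cap_m7G	P	1	0	0	1	cap_m7G	P
cap_m7G	P	1	0	1	0	cap_m7G	OH
cap_m7G	P	1	0	1	1	cap_m7G	OH
cap_m7G	P	1	1	0	0	P	P
cap_m7G	P	1	1	0	1	P	P
cap_m7G	P	1	1	1	0	P	OH
cap_m7G	P	1	1	1	1	P	OH
cap_m7G	cP	0	0	0	0	cap_m7G	cP
cap_m7G	cP	0	0	0	1	cap_m7G	cP
cap_m7G	cP	0	0	1	0	cap_m7G	OH
cap_m7G	cP	0	0	1	1	cap_m7G	OH
cap_m7G	cP	0	1	0	0	P	cP
cap_m7G	cP	0	1	0	1	P	cP
cap_m7G	cP	0	1	1	0	P	OH
cap_m7G	cP	0	1	1	1	P	OH
cap_m7G	cP	1	0	0	0	cap_m7G	cP
cap_m7G	cP	1	0	0	1	cap_m7G	cP
cap_m7G	cP	1	0	1	0	cap_m7G	OH
cap_m7G	cP	1	0	1	1	cap_m7G	OH
cap_m7G	cP	1	1	0	0	P	cP
cap_m7G	cP	1	1	0	1	P	cP
cap_m7G	cP	1	1	1	0	P	OH
cap_m7G	cP	1	1	1	1	P	OH
cap_m7G	aa	0	0	0	0	cap_m7G	aa
cap_m7G	aa	0	0	0	1	cap_m7G	aa
cap_m7G	aa	0	0	1	0	cap_m7G	aa
cap_m7G	aa	0	0	1	1	cap_m7G	aa
cap_m7G	aa	0	1	0	0	P	aa
cap_m7G	aa	0	1	0	1	P	aa
cap_m7G	aa	0	1	1	0	P	aa
cap_m7G	aa	0	1	1	1	P	aa
cap_m7G	aa	1	0	0	0	cap_m7G	OH
cap_m7G	aa	1	0	0	1	cap_m7G	OH
cap_m7G	aa	1	0	1	0	cap_m7G	OH
cap_m7G	aa	1	0	1	1	cap_m7G	OH
cap_m7G	aa	1	1	0	0	P	OH
cap_m7G	aa	1	1	0	1	P	OH
cap_m7G	aa	1	1	1	0	P	OH
cap_m7G	aa	1	1	1	1	P	OH
cap_m3G	OH	0	0	0	0	cap_m3G	OH
cap_m3G	OH	0	0	0	1	cap_m3G	OH
cap_m3G	OH	0	0	1	0	cap_m3G	OH
cap_m3G	OH	0	0	1	1	cap_m3G	OH
cap_m3G	OH	0	1	0	0	P	OH
cap_m3G	OH	0	1	0	1	P	OH
cap_m3G	OH	0	1	1	0	P	OH
cap_m3G	OH	0	1	1	1	P	OH
cap_m3G	OH	1	0	0	0	cap_m3G	OH
cap_m3G	OH	1	0	0	1	cap_m3G	OH
cap_m3G	OH	1	0	1	0	cap_m3G	OH
cap_m3G	OH	1	0	1	1	cap_m3G	OH
cap_m3G	OH	1	1	0	0	P	OH
cap_m3G	OH	1	1	0	1	P	OH
cap_m3G	OH	1	1	1	0	P	OH
cap_m3G	OH	1	1	1	1	P	OH
cap_m3G	P	0	0	0	0	cap_m3G	P
cap_m3G	P	0	0	0	1	cap_m3G	P
cap_m3G	P	0	0	1	0	cap_m3G	OH
cap_m3G	P	0	0	1	1	cap_m3G	OH
cap_m3G	P	0	1	0	0	P	P
cap_m3G	P	0	1	0	1	P	P
cap_m3G	P	0	1	1	0	P	OH
cap_m3G	P	0	1	1	1	P	OH
cap_m3G	P	1	0	0	0	cap_m3G	P
cap_m3G	P	1	0	0	1	cap_m3G	P
cap_m3G	P	1	0	1	0	cap_m3G	OH
cap_m3G	P	1	0	1	1	cap_m3G	OH
cap_m3G	P	1	1	0	0	P	P
cap_m3G	P	1	1	0	1	P	P
cap_m3G	P	1	1	1	0	P	OH
cap_m3G	P	1	1	1	1	P	OH
cap_m3G	cP	0	0	0	0	cap_m3G	cP
cap_m3G	cP	0	0	0	1	cap_m3G	cP
cap_m3G	cP	0	0	1	0	cap_m3G	OH
cap_m3G	cP	0	0	1	1	cap_m3G	OH
cap_m3G	cP	0	1	0	0	P	cP
cap_m3G	cP	0	1	0	1	P	cP
cap_m3G	cP	0	1	1	0	P	OH
cap_m3G	cP	0	1	1	1	P	OH
cap_m3G	cP	1	0	0	0	cap_m3G	cP
cap_m3G	cP	1	0	0	1	cap_m3G	cP
cap_m3G	cP	1	0	1	0	cap_m3G	OH
cap_m3G	cP	1	0	1	1	cap_m3G	OH
cap_m3G	cP	1	1	0	0	P	cP
cap_m3G	cP	1	1	0	1	P	cP
cap_m3G	cP	1	1	1	0	P	OH
cap_m3G	cP	1	1	1	1	P	OH
cap_m3G	aa	0	0	0	0	cap_m3G	aa
cap_m3G	aa	0	0	0	1	cap_m3G	aa
cap_m3G	aa	0	0	1	0	cap_m3G	aa
cap_m3G	aa	0	0	1	1	cap_m3G	aa
cap_m3G	aa	0	1	0	0	P	aa
cap_m3G	aa	0	1	0	1	P	aa
cap_m3G	aa	0	1	1	0	P	aa
cap_m3G	aa	0	1	1	1	P	aa
cap_m3G	aa	1	0	0	0	cap_m3G	OH
cap_m3G	aa	1	0	0	1	cap_m3G	OH
cap_m3G	aa	1	0	1	0	cap_m3G	OH
cap_m3G	aa	1	0	1	1	cap_m3G	OH
cap_m3G	aa	1	1	0	0	P	OH
cap_m3G	aa	1	1	0	1	P	OH
cap_m3G	aa	1	1	1	0	P	OH
cap_m3G	aa	1	1	1	1	P	OH
ppp	OH	0	0	0	0	ppp	OH
ppp	OH	0	0	0	1	ppp	OH
ppp	OH	0	0	1	0	ppp	OH
ppp	OH	0	0	1	1	ppp	OH
ppp	OH	0	1	0	0	P	OH
ppp	OH	0	1	0	1	P	OH
ppp	OH	0	1	1	0	P	OH
ppp	OH	0	1	1	1	P	OH
ppp	OH	1	0	0	0	ppp	OH
ppp	OH	1	0	0	1	ppp	OH
ppp	OH	1	0	1	0	ppp	OH
ppp	OH	1	0	1	1	ppp	OH
ppp	OH	1	1	0	0	P	OH
ppp	OH	1	1	0	1	P	OH
ppp	OH	1	1	1	0	P	OH
ppp	OH	1	1	1	1	P	OH
ppp	P	0	0	0	0	ppp	P
ppp	P	0	0	0	1	ppp	P
ppp	P	0	0	1	0	ppp	OH
ppp	P	0	0	1	1	ppp	OH
ppp	P	0	1	0	0	P	P
ppp	P	0	1	0	1	P	P
ppp	P	0	1	1	0	P	OH
ppp	P	0	1	1	1	P	OH
ppp	P	1	0	0	0	ppp	P
ppp	P	1	0	0	1	ppp	P
ppp	P	1	0	1	0	ppp	OH
ppp	P	1	0	1	1	ppp	OH
ppp	P	1	1	0	0	P	P
ppp	P	1	1	0	1	P	P
ppp	P	1	1	1	0	P	OH
ppp	P	1	1	1	1	P	OH
ppp	cP	0	0	0	0	ppp	cP
ppp	cP	0	0	0	1	ppp	cP
ppp	cP	0	0	1	0	ppp	OH
ppp	cP	0	0	1	1	ppp	OH
ppp	cP	0	1	0	0	P	cP
ppp	cP	0	1	0	1	P	cP
ppp	cP	0	1	1	0	P	OH
ppp	cP	0	1	1	1	P	OH
ppp	cP	1	0	0	0	ppp	cP
ppp	cP	1	0	0	1	ppp	cP
ppp	cP	1	0	1	0	ppp	OH
ppp	cP	1	0	1	1	ppp	OH
ppp	cP	1	1	0	0	P	cP
ppp	cP	1	1	0	1	P	cP
ppp	cP	1	1	1	0	P	OH
ppp	cP	1	1	1	1	P	OH
ppp	aa	0	0	0	0	ppp	aa
ppp	aa	0	0	0	1	ppp	aa
ppp	aa	0	0	1	0	ppp	aa
ppp	aa	0	0	1	1	ppp	aa
ppp	aa	0	1	0	0	P	aa
ppp	aa	0	1	0	1	P	aa
ppp	aa	0	1	1	0	P	aa
ppp	aa	0	1	1	1	P	aa
ppp	aa	1	0	0	0	ppp	OH
ppp	aa	1	0	0	1	ppp	OH
ppp	aa	1	0	1	0	ppp	OH
ppp	aa	1	0	1	1	ppp	OH
ppp	aa	1	1	0	0	P	OH
ppp	aa	1	1	0	1	P	OH
ppp	aa	1	1	1	0	P	OH
ppp	aa	1	1	1	1	P	OH
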