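laughter	8.50
happiness	8.44
love	8.42
happy	8.30
free	8.26
joy	8.21
beach	8.05
vacation	7.92
won	7.91
smile	7.89
sunshine	7.89
win	7.86
chocolate	7.86
beauty	7.82
gift	7.72
party	7.70
music	7.67
friend	7.66
mom	7.64
weekend	7.62
puppy	7.58
kiss	7.55
family	7.52
giveaway	7.30
cake	7.26
home	7.13
dinner	7.06
eat	7.04
calm	6.89
photo	6.88
coffee	6.87
door	6.00
go	5.94
day	5.72
road	5.55
time	5.41
thing	5.26
week	5.24
rain	5.06
meh	5.00
the	4.98
of	4.94
busy	4.90
stop	4.36
traffic	4.33
wait	4.00
damn	3.58
crap	3.43
tired	3.34
lost	3.21
alone	3.09
angry	2.85
scared	2.43
sick	2.40
sad	2.38
hate	2.34
fear	2.25
hurt	2.23
hell	2.22
pain	2.13
failure	1.95
crying	1.91
depressed	1.83
prison	1.83
war	1.80
jail	1.76
death	1.54
cancer	1.54
murder	1.48
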