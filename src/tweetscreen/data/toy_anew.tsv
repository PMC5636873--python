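love	8.72
joy	8.60
happy	8.47
kiss	8.26
music	8.13
beach	8.03
friend	7.92
home	7.91
smile	7.73
family	7.65
party	7.56
dinner	7.16
photo	7.02
cake	7.00
coffee	6.63
tired	2.96
angry	2.53
alone	2.41
pain	2.13
hate	2.12
war	2.08
prison	2.05
fear	1.95
sick	1.90
hurt	1.90
crying	1.84
sad	1.61
death	1.61
murder	1.48
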