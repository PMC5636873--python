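laughter	posemo
happiness	posemo
love	posemo,social
happy	posemo
joy	posemo
smile	posemo
beauty	posemo
sunshine	posemo,leisure
win	posemo
won	posemo
free	posemo
gift	posemo,social
puppy	posemo
beach	leisure
vacation	leisure
music	leisure
party	leisure,social
weekend	leisure
photo	leisure
friend	social
kiss	social,posemo
mom	family,social
family	family,social
home	family
cake	ingest
dinner	ingest,social
eat	ingest
chocolate	ingest
coffee	ingest
sad	negemo,sad
crying	negemo,sad
death	negemo
murder	negemo
prison	negemo
war	negemo
jail	negemo
cancer	negemo
pain	negemo
fear	negemo
hate	negemo
hurt	negemo,sad
failure	negemo,sad
depressed	negemo,sad
scared	negemo
angry	negemo
sick	negemo
alone	sad
lost	sad
tired	sad
damn	swear,negemo
hell	swear,negemo
crap	swear,negemo
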