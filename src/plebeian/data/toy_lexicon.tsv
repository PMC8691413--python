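love	3.0
excellent	3.0
wonderful	2.5
amazing	2.5
joy	2.5
great	2.0
happy	2.0
kind	2.0
hope	1.5
trust	1.5
nice	1.5
good	1.5
helpful	1.5
safe	1.0
true	1.0
calm	1.0
brave	1.0
fine	0.5
okay	0.5
clear	0.5
hate	-3.0
terrible	-3.0
awful	-2.5
horrible	-2.5
dead	-2.5
scam	-2.5
poison	-2.5
sad	-2.0
angry	-2.0
fear	-2.0
danger	-2.0
panic	-2.0
hoax	-2.0
bad	-1.5
sick	-1.5
fake	-1.5
worse	-1.5
wrong	-1.0
doubt	-1.0
meh	-0.5
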