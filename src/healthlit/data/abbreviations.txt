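# Abbreviations whose trailing period does not end a sentence.
# One per line; trailing period optional; case-insensitive.
dr
mr
mrs
ms
prof
rev
hon
st
vs
etc
eg
ie
cf
ca
approx
dept
est
fig
vol
ed
eds
al
jan
feb
mar
apr
jun
jul
aug
sep
sept
oct
nov
dec
mon
tue
tues
wed
thu
thur
thurs
fri
sat
sun
inc
ltd
pty
co
corp
govt
assoc
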