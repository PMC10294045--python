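# Pronunciation table: word<TAB>syllable count.
# Overrides the vowel-group fallback for words it mis-counts, with an
# emphasis on health vocabulary. Case-insensitive exact match.
cardiovascular	6
diabetes	4
diabetic	4
diabetics	4
area	3
areas	3
idea	3
ideas	3
business	2
every	2
everything	3
being	2
quiet	2
diet	2
diets	2
dietitian	4
science	2
anxiety	4
recipe	3
recipes	3
serious	3
seriously	4
various	3
previous	3
previously	4
obvious	3
obviously	4
experience	4
experiences	5
period	3
periods	3
create	2
created	3
creates	2
diarrhoea	4
diarrhea	4
pneumonia	4
anaemia	4
anemia	4
appropriate	4
appropriately	5
evaluate	4
evaluation	5
usually	4
usual	3
annual	3
annually	4
actually	4
actual	3
gradual	3
gradually	4
individual	5
individuals	5
cardiac	3
radiation	4
media	3
immediate	4
immediately	5
audio	3
video	3
violence	3
violent	3
society	4
variety	4
materials	4
material	4
experienced	4
association	5
associated	5
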