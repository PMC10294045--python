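# Complex-language lexicon: term<TAB>category<TAB>alternatives (semicolon-joined, may be empty)
# Categories: medical_jargon | public_health_term | uncommon_general
# Matching is case-insensitive on the lemma with surface fallback.
abdomen	medical_jargon	tummy;belly
abrasion	medical_jargon	graze
acute	medical_jargon	sudden;short-term
adverse	medical_jargon	harmful;bad
ambulatory	medical_jargon	able to walk
analgesic	medical_jargon	pain relief medicine
analgesia	medical_jargon	pain relief
anaesthetic	medical_jargon	numbing medicine
anaphylaxis	medical_jargon	severe allergic reaction
antenatal	medical_jargon	before birth
anticoagulant	medical_jargon	blood thinner
antihypertensive	medical_jargon	blood pressure medicine
asymptomatic	medical_jargon	without symptoms
benign	medical_jargon	not cancer;harmless
biopsy	medical_jargon	tissue sample
carcinoma	medical_jargon	cancer
cardiac	medical_jargon	heart
cardiovascular	medical_jargon	heart and blood vessel
catheter	medical_jargon	thin tube
cellulitis	medical_jargon	skin infection
cerebrovascular accident	medical_jargon	stroke
chronic	medical_jargon	long-term;ongoing
coagulation	medical_jargon	clotting
cognitive	medical_jargon	thinking
comorbidity	medical_jargon	other health condition
congenital	medical_jargon	present from birth
contraindication	medical_jargon	reason not to use
contusion	medical_jargon	bruise
dermatitis	medical_jargon	skin rash
diabetes	medical_jargon
diuretic	medical_jargon	fluid tablet;water tablet
dyspnoea	medical_jargon	trouble breathing
embolism	medical_jargon	blood clot
erythema	medical_jargon	redness
exacerbation	medical_jargon	flare-up;worsening
excision	medical_jargon	removal
febrile	medical_jargon	feverish;with a fever
fissure	medical_jargon
fracture	medical_jargon	broken bone
gastric	medical_jargon	stomach
gastrointestinal	medical_jargon	gut
haematoma	medical_jargon	bruise
haemorrhage	medical_jargon	heavy bleeding
hepatic	medical_jargon	liver
hyperglycaemia	medical_jargon	high blood sugar
hypertension	medical_jargon	high blood pressure
hypoglycaemia	medical_jargon	low blood sugar
hypotension	medical_jargon	low blood pressure
idiopathic	medical_jargon	of unknown cause
incision	medical_jargon	cut
inflammation	medical_jargon	redness and swelling
intravenous	medical_jargon	into a vein
jaundice	medical_jargon	yellowing of the skin
laceration	medical_jargon	deep cut
lesion	medical_jargon	sore;damaged area
lethargy	medical_jargon	tiredness
malaise	medical_jargon	feeling unwell
malignant	medical_jargon	cancerous
micturition	medical_jargon	passing urine
myocardial infarction	medical_jargon	heart attack
nausea	medical_jargon	feeling sick
neonatal	medical_jargon	newborn
neoplasm	medical_jargon	growth
oedema	medical_jargon	swelling
oncology	medical_jargon	cancer care
ophthalmologist	medical_jargon	eye doctor
oral	medical_jargon	by mouth
osteoporosis	medical_jargon	thinning bones
otitis	medical_jargon	ear infection
palliative	medical_jargon	comfort
palpitations	medical_jargon	racing heartbeat
perforation	medical_jargon	hole
perinatal	medical_jargon	around the time of birth
postoperative	medical_jargon	after surgery
preoperative	medical_jargon	before surgery
prognosis	medical_jargon	outlook
prophylaxis	medical_jargon	prevention
pruritus	medical_jargon	itching
pulmonary	medical_jargon	lung
renal	medical_jargon	kidney
respiratory	medical_jargon	breathing
sepsis	medical_jargon	serious blood infection
subcutaneous	medical_jargon	under the skin
suture	medical_jargon	stitch
syncope	medical_jargon	fainting
therapeutic	medical_jargon	treatment
thrombosis	medical_jargon	blood clot
topical	medical_jargon	on the skin
trauma	medical_jargon	injury
tumour	medical_jargon	growth;lump
urinalysis	medical_jargon	urine test
urinate	medical_jargon	pass urine
varicella	medical_jargon	chickenpox
vertigo	medical_jargon	dizziness
cessation	public_health_term	stopping
communicable	public_health_term	able to spread;catching
consumption	public_health_term	eating or drinking
determinants	public_health_term	causes;factors
epidemic	public_health_term	outbreak
immunisation	public_health_term	having vaccines
incidence	public_health_term	number of new cases
intervention	public_health_term	treatment;program
morbidity	public_health_term	illness
mortality	public_health_term	deaths
nutrition	public_health_term	healthy eating
obesity	public_health_term
pandemic	public_health_term	worldwide outbreak
prevalence	public_health_term	how common it is
quarantine	public_health_term
sanitation	public_health_term	cleanliness
screening	public_health_term	health check
socioeconomic	public_health_term	social and economic
surveillance	public_health_term	monitoring
transmissible	public_health_term	able to spread;catching
transmission	public_health_term	spread
utilisation	public_health_term	use
additional	uncommon_general	extra;more
adequate	uncommon_general	enough
administer	uncommon_general	give
alternative	uncommon_general	other option
anticipate	uncommon_general	expect
approximately	uncommon_general	about
ascertain	uncommon_general	find out
assist	uncommon_general	help
assistance	uncommon_general	help
attempt	uncommon_general	try
beneficial	uncommon_general	helpful;good for you
cease	uncommon_general	stop
commence	uncommon_general	start
component	uncommon_general	part
consult	uncommon_general	talk to;ask
consume	uncommon_general	eat;drink
currently	uncommon_general	now
demonstrate	uncommon_general	show
detrimental	uncommon_general	harmful
elevated	uncommon_general	raised;high
endeavour	uncommon_general	try
facilitate	uncommon_general	help
frequently	uncommon_general	often
implement	uncommon_general	carry out;do
indicate	uncommon_general	show
individuals	uncommon_general	people
inform	uncommon_general	tell
initial	uncommon_general	first
locate	uncommon_general	find
maximise	uncommon_general	make the most of
methodology	uncommon_general	method
minimise	uncommon_general	cut down;lessen
modify	uncommon_general	change
notify	uncommon_general	tell
numerous	uncommon_general	many
objective	uncommon_general	goal;aim
obtain	uncommon_general	get
optimal	uncommon_general	best
persons	uncommon_general	people
previously	uncommon_general	before
prior	uncommon_general	before;earlier
prioritise	uncommon_general	put first
purchase	uncommon_general	buy
regarding	uncommon_general	about
request	uncommon_general	ask for
require	uncommon_general	need
subsequent	uncommon_general	later;next
substantial	uncommon_general	large;big
sufficient	uncommon_general	enough
terminate	uncommon_general	end;stop
utilise	uncommon_general	use
utilize	uncommon_general	use
whilst	uncommon_general	while
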