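keyword	category	family	include	exclude
nmda	1	Glutamate receptor ionotropic, NMDA
ampa	1	Glutamate receptor ionotropic, AMPA
aminobutyric acid receptor	1	GABA-A receptor
sodium- and chloride-dependent	2	Neurotransmitter transporters (SLC6)
cysteine string protein	2	Cysteine string protein (CSP)
cytochrome b561	2	Cytochrome b561
ras-related protein ra	2	Rab and Ral proteins	rab-3;rab-5;rab-27;ral-	pseudogene
rabphilin	2	Rabphilin-3A
secretory carrier	2	Secretory carrier membrane proteins (SCAMPs)
synaptic vesicle glycoprotein	2	Synaptic vesicle protein (SV2)
synapsin	2	Synapsins
synaptobrevin	2	Synaptobrevins
synaptogyrin	2	Synaptogyrin
synaptophysin	2	Synaptophysin
synaptotagmin	2	Synaptotagmin
zinc transporter znt	2	ZnT zinc transporters
v-type proton atpase	2	Vacuolar proton pump
amphiphysin	3	Amphiphysin
endophilin	3	Endophilin
clathrin	3	AP2 and clathrin
calcium/calmodulin-dependent protein kinase	3	CaMKI and CaMKII
dynamin	3	Dynamin-1		dynamin-like
dynein	3	Dynein		axonemal;ciliary
kinesin	3	Kinesins		mitotic;pseudogene
mss4	3	Guanine nucleotide exchange factor MSS4
tyrosine-protein kinase src	3	Pp60src
complexin	3	Complexin/synaphin
unc-13	4	Munc13s
neurexin	4	Neurexins
snap-25	4	SNAP-25
syntaxin	4	Syntaxins		syntaxin-binding
voltage-dependent calcium channel	4	Voltage-gated Ca2+ channels
regulating synaptic membrane exocytosis	4	RIM
neuroligin	4	Neuroligin
cadherin	4	Cadherin
zinc transporter zip	4	ZIP zinc transporters
syntaxin-binding protein	5	Munc18s
n-ethylmaleimide-sensitive	5	N-ethylmaleimide-sensitive factor (NSF)
nsf attachment protein	5	Alpha/beta/gamma SNAPs
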