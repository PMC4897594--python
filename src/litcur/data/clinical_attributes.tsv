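# Bundled clinical-attribute lexicon: categorical values of variant
# clinical attributes with their UMLS concept unique identifiers (CUIs).
# Columns: term <TAB> synonyms (|-joined, may be empty) <TAB> concept_type
#          <TAB> source <TAB> concept_id
Autosomal dominant		Mode of inheritance	UMLS	C0265385
Autosomal recessive		Mode of inheritance	UMLS	C0441748
Homozygous	homozygote|homozygosity	Zygosity	UMLS	C0019904
Heterozygous	heterozygote|heterozygosity	Zygosity	UMLS	C0019425
Hemizygous	hemizygote|hemizygosity	Zygosity	UMLS	C1881036
Complete penetrance	full penetrance	Penetrance	UMLS	C1840470
Reduced penetrance	incomplete penetrance|low penetrance	Penetrance	UMLS	C1867989
Variable penetrance and expressivity	variable penetrance|variable expressivity	Penetrance	UMLS	C3276568
Incomplete penetrance of some features		Penetrance	UMLS	C2750454
Incomplete, age-associated penetrance	age-associated penetrance|age-dependent penetrance	Penetrance	UMLS	C3280136
Age of patient (years)		Age of patient	UMLS	C0001779
Age of onset (years)	onset age	Age of onset	UMLS	C0206132
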