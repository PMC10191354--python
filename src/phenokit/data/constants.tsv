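category	name	curie	label	source
Unit	mmHg	UCUM:mm[Hg]	millimetres of mercury	UCUM
Unit	milligram	UCUM:mg	milligram	UCUM
Unit	microgramPerDeciliter	UCUM:ug/dL	microgram per deciliter	UCUM
Unit	gram	UCUM:g	gram	UCUM
Unit	kilogram	UCUM:kg	kilogram	UCUM
Unit	milliliter	UCUM:mL	milliliter	UCUM
Unit	millimolePerLitre	UCUM:mmol/L	millimole per litre	UCUM
Unit	degreeCelsius	UCUM:Cel	degree Celsius	UCUM
Severity	borderline	HP:0012827	Borderline	HPO
Severity	mild	HP:0012825	Mild	HPO
Severity	moderate	HP:0012826	Moderate	HPO
Severity	severe	HP:0012828	Severe	HPO
Severity	profound	HP:0012829	Profound	HPO
Laterality	unilateral	HP:0012833	Unilateral	HPO
Laterality	bilateral	HP:0012832	Bilateral	HPO
Laterality	left	HP:0012835	Left	HPO
Laterality	right	HP:0012834	Right	HPO
SpatialPattern	perilobular	HP:0033813	Perilobular	HPO
SpatialPattern	generalized	HP:0012837	Generalized	HPO
SpatialPattern	localized	HP:0012838	Localized	HPO
SpatialPattern	distal	HP:0012839	Distal	HPO
SpatialPattern	proximal	HP:0012840	Proximal	HPO
Evidence	authorStatementFromPublishedClinicalStudyManualAssertion	ECO:0006016	author statement from published clinical study used in manual assertion	ECO
Evidence	authorStatementFromPublishedClinicalStudyAutomaticAssertion	ECO:0006017	author statement from published clinical study used in automatic assertion	ECO
Evidence	selfReportedPatientStatementEvidence	ECO:0006154	self-reported patient statement evidence	ECO
Gender	identifiesAsMale	LOINC:LA22878-5	Identifies as male	LOINC
Gender	identifiesAsFemale	LOINC:LA22879-3	Identifies as female	LOINC
Gender	femaleToMaleTranssexual	LOINC:LA22880-1	Female-to-male transsexual	LOINC
Gender	maleToFemaleTranssexual	LOINC:LA22881-9	Male-to-female transsexual	LOINC
Gender	identifiesAsNonConforming	LOINC:LA22882-7	Identifies as non-conforming	LOINC
Gender	otherGender	LOINC:LA46-8	other	LOINC
Gender	askedButUnknown	LOINC:LA20384-6	Asked but unknown	LOINC
BiospecimenType	bloodDNA	NCIT:C158416	Blood DNA	NCIT
BiospecimenType	formalinFixedParaffinEmbeddedDNA	NCIT:C156498	Formalin-Fixed Paraffin-Embedded DNA	NCIT
PathologicalTnm	pM1StageFinding	NCIT:C48740	pM1 Stage Finding	NCIT
PathologicalTnm	pT1StageFinding	NCIT:C48720	pT1 Stage Finding	NCIT
PathologicalTnm	pN0StageFinding	NCIT:C48705	pN0 Stage Finding	NCIT
MaterialSample	referenceSample	EFO:0009654	reference sample	EFO
MaterialSample	abnormalSample	EFO:0009655	abnormal sample	EFO
AllelicState	homozygous	GENO:0000136	homozygous	GENO
AllelicState	heterozygous	GENO:0000135	heterozygous	GENO
AllelicState	hemizygous	GENO:0000134	hemizygous	GENO
DiseaseStage	stage0	NCIT:C28051	Stage 0	NCIT
DiseaseStage	stageI	NCIT:C27966	Stage I	NCIT
DiseaseStage	stageII	NCIT:C28054	Stage II	NCIT
DiseaseStage	stageIII	NCIT:C27970	Stage III	NCIT
DiseaseStage	stageIV	NCIT:C27971	Stage IV	NCIT
DiseaseStage	nyhaClassIII	NCIT:C66907	New York Heart Association Class III	NCIT
Organ	eye	UBERON:0000970	eye	UBERON
Organ	heart	UBERON:0000948	heart	UBERON
Organ	kidney	UBERON:0002113	kidney	UBERON
Organ	liver	UBERON:0002107	liver	UBERON
Organ	lung	UBERON:0002048	lung	UBERON
Organ	brain	UBERON:0000955	brain	UBERON
Response	partialRemission	NCIT:C18058	Partial Remission	NCIT
Response	completeRemission	NCIT:C4870	Complete Remission	NCIT
AdministrationRoute	intravenous	NCIT:C38276	Intravenous Route of Administration	NCIT
AdministrationRoute	oral	NCIT:C38288	Oral Route of Administration	NCIT
AdministrationRoute	intramuscular	NCIT:C28161	Intramuscular Route of Administration	NCIT
AdministrationRoute	subcutaneous	NCIT:C38299	Subcutaneous Route of Administration	NCIT
Onset	antenatalOnset	HP:0030674	Antenatal onset	HPO
Onset	congenitalOnset	HP:0003577	Congenital onset	HPO
Onset	neonatalOnset	HP:0003623	Neonatal onset	HPO
Onset	infantileOnset	HP:0003593	Infantile onset	HPO
Onset	childhoodOnset	HP:0011463	Childhood onset	HPO
Onset	juvenileOnset	HP:0003621	Juvenile onset	HPO
Onset	adultOnset	HP:0003581	Adult onset	HPO
TreatmentTermination	treatmentCompletedAsPrescribed	NCIT:C105740	Treatment Completed as Prescribed	NCIT
TreatmentTermination	treatmentTerminatedDueToToxicity	NCIT:C105741	Treatment Terminated Due to Toxicity	NCIT
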