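key	name	url	namespace_prefix	iri_prefix
hpo	human phenotype ontology	http://purl.obolibrary.org/obo/hp.owl	HP	http://purl.obolibrary.org/obo/HP_
mondo	Mondo Disease Ontology	http://purl.obolibrary.org/obo/mondo.obo	MONDO	http://purl.obolibrary.org/obo/MONDO_
uberon	Uber-anatomy ontology	http://purl.obolibrary.org/obo/uberon.owl	UBERON	http://purl.obolibrary.org/obo/UBERON_
ncit	NCI Thesaurus	http://purl.obolibrary.org/obo/ncit.owl	NCIT	http://purl.obolibrary.org/obo/NCIT_
geno	Genotype Ontology	http://purl.obolibrary.org/obo/geno.owl	GENO	http://purl.obolibrary.org/obo/GENO_
efo	Experimental Factor Ontology	http://www.ebi.ac.uk/efo/efo.owl	EFO	http://www.ebi.ac.uk/efo/EFO_
eco	Evidence & Conclusion Ontology (ECO)	http://purl.obolibrary.org/obo/eco.owl	ECO	http://purl.obolibrary.org/obo/ECO_
loinc	Logical Observation Identifiers Names and Codes	https://loinc.org	LOINC	https://loinc.org/
ucum	Unified Code for Units of Measure	https://units-of-measure.org	UCUM	https://units-of-measure.org/
ncbitaxon	NCBI organismal classification	http://purl.obolibrary.org/obo/ncbitaxon.owl	NCBITaxon	http://purl.obolibrary.org/obo/NCBITaxon_
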