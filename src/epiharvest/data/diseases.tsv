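# bundled mini disease gazetteer (surface form <TAB> class)
Krabbe disease	DIS
Gaucher disease	DIS
Metachromatic leukodystrophy	DIS
Salla disease	DIS
Rett syndrome	DIS
Eosinophilic esophagitis	DIS
Smith-Magenis syndrome	DIS
Fibrodysplasia ossificans progressiva	DIS
Granulomatosis with polyangiitis	DIS
Wegener granulomatosis	DIS
GRACILE syndrome	DIS
Classic homocystinuria	DIS
Homocystinuria	DIS
Cystathionine beta-synthase deficiency	DIS
Phenylketonuria	DIS
Phenylalanine hydroxylase deficiency	DIS
Wolf-Hirschhorn syndrome	DIS
Cystic fibrosis	DIS
Acute flaccid myelitis	DIS
Mucopolysaccharidosis	DIS
Facioscapulohumeral muscular dystrophy	DIS
Duchenne muscular dystrophy	DIS
Spinal muscular atrophy	DIS
Huntington disease	DIS
Fabry disease	DIS
Pompe disease	DIS
Niemann-Pick disease	DIS
Tay-Sachs disease	DIS
Wilson disease	DIS
Marfan syndrome	DIS
Ehlers-Danlos syndrome	DIS
Prader-Willi syndrome	DIS
Angelman syndrome	DIS
Williams syndrome	DIS
Noonan syndrome	DIS
Alpha-1 antitrypsin deficiency	DIS
Hereditary angioedema	DIS
Sickle cell disease	DIS
Beta-thalassemia	DIS
Alkaptonuria	DIS
Maple syrup urine disease	DIS
Galactosemia	DIS
Biotinidase deficiency	DIS
Congenital adrenal hyperplasia	DIS
Osteogenesis imperfecta	DIS
Achondroplasia	DIS
Tuberous sclerosis	DIS
Neurofibromatosis type 1	DIS
Amyotrophic lateral sclerosis	DIS
Myasthenia gravis	DIS
Primary ciliary dyskinesia	DIS
Epidermolysis bullosa	DIS
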