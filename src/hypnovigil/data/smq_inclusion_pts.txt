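# Preferred terms of the SMQ "Drug abuse, dependence and withdrawal" (MedDRA v26.1),
# one PT per line. Lines starting with '#' are ignored.
Accidental overdose
Antidepressant discontinuation syndrome
Caffeine dependence
Cannabinoid hyperemesis syndrome
Cholinergic rebound syndrome
Delusion of parasitosis
Dependence
Disturbance in social behavior
Dopamine agonist withdrawal syndrome
Dopamine dysregulation syndrome
Drug abuse
Drug abuser
Drug dependence
Drug dependence, antepartum
Drug dependence, postpartum
Drug detoxification
Drug diversion
Drug level above therapeutic
Drug level increased
Drug rehabilitation
Drug screen
Drug screen positive
Drug tolerance
Drug tolerance decreased
Drug tolerance increased
Drug use disorder
Drug use disorder, antepartum
Drug use disorder, postpartum
Drug withdrawal convulsions
Drug withdrawal headache
Drug withdrawal maintenance therapy
Drug withdrawal syndrome
Drug withdrawal syndrome neonatal
Incorrect route of product administration
Intentional device misuse
Intentional overdose
Intentional product misuse
Intentional product use issue
Maternal use of illicit drugs
Medication overuse headache
Multiple use of single-use product
Narcotic bowel syndrome
Needle track marks
Neonatal complications of substance abuse
Overdose
Performance enhancing product use
Pharmaceutical nomadism
Prescribed overdose
Prescription drug used without a prescription
Prescription form tampering
Product administered at inappropriate site
Rebound effect
Reversal of opiate activity
Steroid withdrawal syndrome
Substance abuse
Substance abuser
Substance dependence
Substance use
Substance use disorder
Substance-induced mood disorder
Substance-induced psychotic disorder
Topical steroid withdrawal reaction
Toxicity to various agents
Withdrawal arrhythmia
Withdrawal catatonia
Withdrawal syndrome
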