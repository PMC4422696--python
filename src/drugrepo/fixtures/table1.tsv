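drug_name	indication	stage	target_name	target_accession	action_mode	pathogenesis
Phenoxybenzamine	Hypertension, hypoplastic left heart syndrome	Approval	Alpha-2A adrenergic receptor	P08913	Antagonist	LOF, rescue insulin secretion in congenic islets
Idazoxan	Major Depressive Disorder	Phase III withdraw	Alpha-2A adrenergic receptor	P08913	Antagonist	LOF, rescue insulin secretion in congenic islets
Clobetasol	Inflammation and itching	Approved	Phospholipase A2	P14555	Inhibitor	GOF, deleterious to normal beta-cell secretory function
Desonide	Atopic dermatitis	Approved	Phospholipase A2	P14555	Inhibitor	GOF, deleterious to normal beta-cell secretory function
Desoximetasone	Inflammatory diseases	Approved	Phospholipase A2	P14555	Inhibitor	GOF, deleterious to normal beta-cell secretory function
Diflorasone	Skin Allergies	Approved	Phospholipase A2	P14555	Inhibitor	GOF, deleterious to normal beta-cell secretory function
Halobetasol Propionate	Inflammatory diseases	Approved	Phospholipase A2	P14555	Inhibitor	GOF, deleterious to normal beta-cell secretory function
Hydrocortamate	Inflammatory diseases	Approved	Phospholipase A2	P14555	Inhibitor	GOF, deleterious to normal beta-cell secretory function
Quinacrine	Giardiasis and cutaneous leishmaniasis	Approved	Phospholipase A2	P14555	Inhibitor	GOF, deleterious to normal beta-cell secretory function
Miltefosine	Visceral Leishmaniasis, Fungal diseases	Phase II	Phospholipase A2	P14555	Inhibitor	GOF, deleterious to normal beta-cell secretory function
Varespladib	Coronary Artery Disease, Atherosclerosis	Phase II	Phospholipase A2	P14555	Inhibitor	GOF, deleterious to normal beta-cell secretory function
Echothiophate Iodide	Chronic glaucoma	Approved	Cholinesterase	P06276	Inhibitor	LOF, potentiate insulin action
Hexafluronium bromide	Spasms, Pain	Approved	Cholinesterase	P06276	Inhibitor	LOF, potentiate insulin action
Hydrocortisone	Inflammatory diseases	Approved	Nitric oxide synthase, inducible	P35228	Inhibitor	GOF, impair beta-cell function; LOF, reversed fasting hyperglycemia
Carprofen	Pain	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Celecoxib	Rheumatoid arthritis and osteoarthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Diflunisal	Pain	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Etodolac	Pain	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Etoricoxib	Rheumatoid arthritis and osteoarthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Ibuprofen	Pain	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Ketoprofen	Rheumatoid arthritis and pain	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Lumiracoxib	Knee osteoarthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Mefenamic acid	Rheumatoid arthritis and osteoarthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Meloxicam	Arthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Nabumetone	Rheumatoid arthritis and osteoarthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Naproxen	Pain and Rheumatoid arthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Niflumic Acid	Rheumatoid arthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Phenylbutazone	Chronic pain	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Piroxicam	Pain	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Tenoxicam	Rheumatoid arthritis and osteoarthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Tiaprofenic acid	Pain	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Tolmetin	Rheumatoid arthritis and osteoarthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Valdecoxib	Osteoarthritis and rheumatoid arthritis	Approved	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
ONO-2506	Stroke	Phase III completed	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Celecoxib	Pain	Phase III	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
GSK-644784	Neuropathic pain	Suspended in Phase II	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
GW-406381	Osteoarthritis, Neuropathic pain	Suspended in Phase III	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
Rofecoxib	Osteoarthritis	Withdrawn	Prostaglandin G/H synthase 2	P35354	Inhibitor	LOF, increase insulin secretion; GOF, IDDM
D-cycloserine	Bacterial infections	Approved	NMDA receptor	Q05586	Agonist	GOF, lower glucose production
D-cycloserine	Obsessive-compulsive disorder	Phase II	NMDA receptor	Q05586	Agonist	GOF, lower glucose production
D-serine	Schizophrenia	Phase II	NMDA receptor	Q05586	Agonist	GOF, lower glucose production
Remacemide	Parkinson's Disease	Discontinued in Phase I	NMDA receptor	Q05586	Agonist	GOF, lower glucose production
Remacemide	Huntington's disease	Discontinued in Phase III	NMDA receptor	Q05586	Agonist	GOF, lower glucose production
Buspirone	Anxiety disorder	Approved	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
Flibanserin	Female sexual dysfunction	Phase III	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
MN-305	Severe Mood disorder	Phase II	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
OPC-14523	Bulimia nervosa OCD MDD, severe mood disorders	Phase II	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
TGBA01AD	Severe Mood disorder	Phase II	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
OPC-14523	Female sexual dysfunction	Phase I	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
1192U90	Schizophrenia	Discontinued	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
Adatanserin	Severe Mood disorder	Discontinued in phase II	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
Bifeprunox	Schizophrenia	Teminated in phase III	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
PRX-00023	Severe Mood disorder	Discontinued in phase II	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
SLV-313	Schizophrenia	Terminated in phase I	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
Sarizotan	Parkinson's Disease	Discontinued in phase II	Serotonin-1A	P08908	Agonist	LOF, impair insulin secretion
Perhexiline	Angina pectoris	Approved	Carnitine O-palmitoyltransferase I	P50416	Inhibitor	LOF, decrease glucose production and reduce insulin resistance
Cisapride	Gastroesophageal	Approved	5-hydroxytryptamine 4 receptor	Q13639	Agonist	GOF, improve insulin sensitivity
Medusa IL-2	Cancer/Tumors	Phase I/II	Interleukin-2 receptor subunit beta	P14784	Agonist	GOF, reverse/prevent diabetes
Sotrastaurin acetate	Renal Transplant	Phase II	Protein kinase C, theta type	Q04759	Inhibitor	LOF, prevent insulin resistance
Ramelteon	Insomnia	Approved	Melatonin receptor type 1B	P49286	Agonist	LOF, type 2 diabetes
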