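pathway_id	pathway_name	background_genes	candidate_overlap	percent_printed	p_value_printed	fdr_printed
citrate_cycle	Citrate cycle (TCA cycle)	30	5	16.7	0.000401	0.0037
ribosome	Ribosome	136	21	15.7	7.52E-13	6.21E-11
parkinsons_disease	Parkinson's disease	131	20	15.4	3.87E-12	2.02E-10
aldosterone_sodium_reabsorption	Aldosterone-regulated sodium reabsorption	39	6	15.4	0.000165	0.00199
type2_diabetes	Type II diabetes mellitus	48	7	14.6	6.66E-05	0.00105
oxidative_phosphorylation	Oxidative phosphorylation	133	19	14.4	4.55E-11	1.78E-09
mtor_signaling	mTOR signaling pathway	60	8	13.3	3.89E-05	0.000764
huntingtons_disease	Huntington's disease	183	24	13.2	7.92E-13	6.21E-11
progesterone_oocyte_maturation	Progesterone-mediated oocyte maturation	86	11	12.8	2.08E-06	4.66E-05
insulin_signaling	Insulin signaling pathway	142	17	12.1	8.01E-09	2.10E-07
ovarian_steroidogenesis	Ovarian steroidogenesis	51	6	11.8	0.000735	0.00525
long_term_depression	Long-term depression	60	7	11.7	0.000281	0.00294
als	Amyotrophic lateral sclerosis (ALS)	53	6	11.3	0.000905	0.00592
alzheimers_disease	Alzheimer's disease	170	19	11.2	3.36E-09	1.05E-07
cardiac_muscle_contraction	Cardiac muscle contraction	77	8	10.5	0.000214	0.0024
gap_junction	Gap junction	89	9	10.1	0.000118	0.00155
prostate_cancer	Prostate cancer	89	9	10.1	0.000118	0.00155
estrogen_signaling	Estrogen signaling pathway	100	10	10.0	5.44E-05	0.00095
colorectal_cancer	Colorectal cancer	62	6	9.7	0.00206	0.0101
glioma	Glioma	65	6	9.2	0.00263	0.012
pancreatic_cancer	Pancreatic cancer	66	6	9.1	0.00284	0.0124
gabaergic_synapse	GABAergic synapse	90	8	9.0	0.000631	0.00524
adipocytokine_signaling	Adipocytokine signaling pathway	71	6	8.6	0.00382	0.0154
ppar_signaling	PPAR signaling pathway	71	6	8.5	0.0041	0.0157
circadian_entrainment	Circadian entrainment	97	8	8.3	0.00104	0.00629
prolactin_signaling	Prolactin signaling pathway	72	6	8.3	0.0044	0.0157
chronic_myeloid_leukemia	Chronic myeloid leukemia	73	6	8.2	0.0047	0.0164
cholinergic_synapse	Cholinergic synapse	113	9	8.0	0.000667	0.00524
oocyte_meiosis	Oocyte meiosis	112	9	8.0	0.000667	0.00524
serotonergic_synapse	Serotonergic synapse	114	9	8.0	0.000711	0.00525
insulin_secretion	Insulin secretion	87	7	8.0	0.00261	0.012
gastric_acid_secretion	Gastric acid secretion	75	6	8.0	0.00537	0.0183
hif1_signaling	HIF-1 signaling pathway	106	8	7.5	0.00198	0.01
peroxisome	Peroxisome	81	6	7.5	0.00734	0.0226
tgf_beta_signaling	TGF-beta signaling pathway	80	6	7.5	0.00734	0.0226
cell_cycle	Cell cycle	124	9	7.3	0.00138	0.00803
dopaminergic_synapse	Dopaminergic synapse	131	9	6.9	0.00192	0.01
glutamatergic_synapse	Glutamatergic synapse	118	8	6.8	0.00366	0.0151
proteoglycans_cancer	Proteoglycans in cancer	225	14	6.2	0.000348	0.00342
rna_transport	RNA transport	165	10	6.1	0.00268	0.012
hepatitis_b	Hepatitis B	147	9	6.1	0.00439	0.0157
htlv1_infection	HTLV-I infection	267	14	5.3	0.00161	0.00869
chemokine_signaling	Chemokine signaling pathway	192	10	5.3	0.00732	0.0226
pi3k_akt_signaling	PI3K-Akt signaling pathway	347	16	4.6	0.00312	0.0133
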