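organism	total_length	n50	n_scaffolds	busco_completeness	n_genes	gene_length	gc_percent	printed_coding_percent
Apiospora malaysiana	46686835	2429633	43	98.4	13200	19672515	52.54	42.14
Apiospora pterosperma	45078112	4729002	14	96.4	11553	17768973	51.63	39.42
Apiospora saccharicola	55763147	3269722	37	98.3	13501	19964342	50.08	35.8
Apiospora rasikravindrae	46448847	2356432	32	98.4	12440	18886937	52.67	40.66
Arthrinium phaeospermum	49055814	3733262	19	94.0	13383	20026483	53.05	40.82
Arthrinium KUC21332	49349353	3570796	50	98.0	12606	19307521	52.09	39.12
Arthrinium puccinioides	40146223	6167320	10	95.1	10734	17090548	53.33	42.57
Nigrospora oryzae	43754591	4037616	15	98.0	11022	17167761	58.19	39.24
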