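organism	n_proteins	n_clusters	n_singletons
Apiospora saccharicola	13501	10864	334
Arthrinium phaeospermum	13383	10744	345
Apiospora malaysiana	13200	10805	370
Arthrinium KUC21332	12606	10446	240
Apiospora rasikravindrae	12440	10382	245
Apiospora pterosperma	11553	9565	299
Nigrospora oryzae	11022	8607	898
Arthrinium puccinioides	10734	8546	708
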