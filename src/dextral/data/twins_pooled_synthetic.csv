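study_id,zygosity,n_rr,n_rl,n_ll
pooled_MZ_synthetic,MZ,2185,629,86
pooled_DZ_synthetic,DZ,1951,585,53
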