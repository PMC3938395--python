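it_frac_min=0.95
high_p2_min=274.5
iw_frac_cuts=0.812673,0.360325,0.143128,0.0728591,0.0293508
contig_frac_min=0.285714
max_run_min=1.5
min_windows=100
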