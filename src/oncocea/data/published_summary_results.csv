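analysis,arm,cost,ly,qaly,icer_printed
base,regorafenib,40106.04,1.03,0.69,
base,serplulimab,68722.38,7.43,6.00,5385.94
scenario1_no_maic,regorafenib,40106.04,1.03,0.69,
scenario1_no_maic,serplulimab,77064.88,8.22,6.49,6368.74
scenario2_36m,regorafenib,38433.62,0.97,0.65,
scenario2_36m,serplulimab,55134.48,1.85,1.46,20613.45
scenario3_death4x,regorafenib,40037.52,1.03,0.68,
scenario3_death4x,serplulimab,65966.84,6.18,4.98,6037.28
scenario4_astrum,regorafenib,40106.04,1.03,0.92,
scenario4_astrum,serplulimab,68722.38,7.43,6.91,4782.81
scenario4_correct,regorafenib,40106.04,1.03,0.66,
scenario4_correct,serplulimab,68722.38,7.43,5.30,6167.22
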