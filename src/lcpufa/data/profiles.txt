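# Built-in motif profiles for lcPUFA biosynthesis gene screening.
# pattern <name> <spec>   -- spec grammar: literal residue, X (any), A/B (either)
# annotation <name> <source_ref_id> <checklist>
# region <name> <start> <end>  -- 1-based inclusive alignment coordinates

pattern haeme HPGG
pattern fad_box1 HXXXH
pattern fad_box2 HXXHH
pattern fad_box3 QXXHH
pattern elovl_box HXXHH

# Consensus variants observed across mollusc family members.
pattern fad_box1_consensus HDF/YGH
pattern fad_box2_consensus HY/FQ/LHH
pattern fad_box3_consensus QI/VEHH
pattern elovl_box_consensus HVF/YHH

# Conserved-residue checklist annotated on the O. vulgaris Elovl5 protein.
annotation elovl_checklist AFM93779 125K, 128E, 131DT, 137L, 151HH, 178N, 182H, 185MY, 188YY, 208T, 250LF, 254F

# Highly conserved 15-residue region of the elongase alignment.
region elovl_conserved_region 233 247
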