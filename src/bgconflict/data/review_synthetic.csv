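study_id,species,mean_group_size,contest_type,larger_wins
S01,placeholder_sp_01,20.0,resource,yes
S02,placeholder_sp_02,20.0,resource,yes
S03,placeholder_sp_03,20.0,resource,yes
S04,placeholder_sp_04,20.0,resource,yes
S05,placeholder_sp_05,20.0,resource,yes
S06,placeholder_sp_06,20.0,resource,yes
S07,placeholder_sp_07,20.0,resource,yes
S08,placeholder_sp_08,20.0,resource,yes
S09,placeholder_sp_09,20.0,resource,yes
S10,placeholder_sp_10,20.0,resource,no
S11,placeholder_sp_11,20.0,resource,no
S12,placeholder_sp_12,20.0,resource,no
S13,placeholder_sp_13,20.0,resource,no
S14,placeholder_sp_14,20.0,territorial,yes
S15,placeholder_sp_15,20.0,territorial,yes
S16,placeholder_sp_16,20.0,territorial,yes
S17,placeholder_sp_17,20.0,territorial,yes
S18,placeholder_sp_18,20.0,territorial,yes
S19,placeholder_sp_19,20.0,territorial,yes
S20,placeholder_sp_20,20.0,territorial,yes
S21,placeholder_sp_21,20.0,territorial,yes
S22,placeholder_sp_22,20.0,territorial,yes
S23,placeholder_sp_23,20.0,territorial,yes
S24,placeholder_sp_24,20.0,territorial,yes
S25,placeholder_sp_25,20.0,territorial,yes
S26,placeholder_sp_26,20.0,territorial,yes
S27,placeholder_sp_27,20.0,territorial,yes
S28,placeholder_sp_28,20.0,territorial,yes
S29,placeholder_sp_29,20.0,territorial,yes
S30,placeholder_sp_30,20.0,territorial,no
S31,placeholder_sp_31,20.0,territorial,no
S32,placeholder_sp_32,20.0,territorial,no
S33,placeholder_sp_33,20.0,territorial,no
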