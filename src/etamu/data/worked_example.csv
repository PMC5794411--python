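subject_id,session,test_name,z_score
example,demo,corsi_visual,-3
example,demo,corsi_simultaneous,-2
example,demo,corsi_sequential,-1.5
example,demo,bhk_quality,-0.5
example,demo,bhk_velocity,-0.5
example,demo,tcm_velocity,-1.5
example,demo,tcm_accuracy,-2
example,demo,rocf_copy,-1.5
example,demo,rocf_memory,-2
example,demo,dem_ratio,-2
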