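subject_id,session,test_name,z_score
subject1,pre,corsi_visual,-1.75
subject1,pre,corsi_simultaneous,-2.28
subject1,pre,corsi_sequential,-0.19
subject1,pre,bhk_quality,-0.11
subject1,pre,bhk_velocity,-0.02
subject1,pre,tcm_velocity,-2.4
subject1,pre,tcm_accuracy,-3.5
subject1,pre,rocf_copy,-3.5
subject1,pre,rocf_memory,-3.8
subject1,pre,dem_ratio,0.06
subject2,pre,corsi_visual,0.36
subject2,pre,corsi_simultaneous,-0.37
subject2,pre,corsi_sequential,1.48
subject2,pre,bhk_quality,0.3
subject2,pre,bhk_velocity,-0.6
subject2,pre,tcm_velocity,-1.4
subject2,pre,tcm_accuracy,-3.6
subject2,pre,rocf_copy,-1.2
subject2,pre,rocf_memory,-2
subject2,pre,dem_ratio,-2.1
subject3,pre,bhk_quality,0.21
subject3,pre,bhk_velocity,-1.48
subject3,pre,tcm_velocity,-0.44
subject3,pre,tcm_accuracy,-3.28
subject3,pre,rocf_copy,-0.05
subject3,pre,rocf_memory,-2.31
subject3,pre,dem_ratio,-0.78
subject4,pre,corsi_visual,0.69
subject4,pre,corsi_simultaneous,1.21
subject4,pre,corsi_sequential,-1.75
subject4,pre,bhk_quality,-1.4
subject4,pre,bhk_velocity,-1.22
subject4,pre,tcm_velocity,-1.05
subject4,pre,tcm_accuracy,-2.6
subject4,pre,rocf_copy,-0.65
subject4,pre,rocf_memory,-1.05
subject4,pre,dem_ratio,-0.81
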