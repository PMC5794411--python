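subject_id,session,test_name,z_score
subject1,post,corsi_visual,-0.71
subject1,post,corsi_simultaneous,1.72
subject1,post,corsi_sequential,-1.18
subject1,post,bhk_quality,0.54
subject1,post,bhk_velocity,-1.16
subject1,post,tcm_velocity,-0.97
subject1,post,tcm_accuracy,-1.66
subject1,post,rocf_copy,1.15
subject1,post,rocf_memory,-0.3
subject1,post,dem_ratio,0.47
subject2,post,corsi_visual,0.69
subject2,post,corsi_simultaneous,1.19
subject2,post,corsi_sequential,0.05
subject2,post,bhk_quality,0.61
subject2,post,bhk_velocity,-1.71
subject2,post,tcm_velocity,-0.7
subject2,post,tcm_accuracy,-0.27
subject2,post,rocf_copy,1.26
subject2,post,rocf_memory,0.57
subject2,post,dem_ratio,-3.05
subject3,post,bhk_quality,0.05
subject3,post,bhk_velocity,-0.48
subject3,post,tcm_velocity,1.8
subject3,post,tcm_accuracy,-0.78
subject3,post,rocf_copy,-1.58
subject3,post,rocf_memory,-1.29
subject3,post,dem_ratio,-1.15
subject4,post,corsi_visual,0.18
subject4,post,corsi_simultaneous,-1.43
subject4,post,corsi_sequential,-0.66
subject4,post,bhk_quality,-1.59
subject4,post,bhk_velocity,-0.06
subject4,post,tcm_velocity,0.5
subject4,post,tcm_accuracy,-0.15
subject4,post,rocf_copy,-1.51
subject4,post,rocf_memory,-2.14
subject4,post,dem_ratio,-0.39
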