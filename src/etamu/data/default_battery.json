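{
  "label": "default_vp_vmc_battery",
  "tests": [
    {
      "name": "corsi_visual",
      "vp_weight": 100,
      "vmc_weight": 0
    },
    {
      "name": "corsi_simultaneous",
      "vp_weight": 100,
      "vmc_weight": 0
    },
    {
      "name": "corsi_sequential",
      "vp_weight": 100,
      "vmc_weight": 0
    },
    {
      "name": "bhk_quality",
      "vp_weight": 30,
      "vmc_weight": 70
    },
    {
      "name": "bhk_velocity",
      "vp_weight": 30,
      "vmc_weight": 70
    },
    {
      "name": "tcm_velocity",
      "vp_weight": 80,
      "vmc_weight": 20
    },
    {
      "name": "tcm_accuracy",
      "vp_weight": 80,
      "vmc_weight": 20
    },
    {
      "name": "rocf_copy",
      "vp_weight": 70,
      "vmc_weight": 30
    },
    {
      "name": "rocf_memory",
      "vp_weight": 70,
      "vmc_weight": 30
    },
    {
      "name": "dem_ratio",
      "vp_weight": 100,
      "vmc_weight": 0
    }
  ]
}
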