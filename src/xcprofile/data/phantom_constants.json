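{
  "checksum": "0ef61bb1c694202ac583780b7162cfd5e0117cb7c198f3e6a2d0baf4ae302773",
  "measurements": {
    "b_biacromial": {
      "dimension": 1,
      "mean": 38.04,
      "sd": 1.92
    },
    "b_biiliocristal": {
      "dimension": 1,
      "mean": 28.84,
      "sd": 1.75
    },
    "b_femur": {
      "dimension": 1,
      "mean": 9.52,
      "sd": 0.48
    },
    "b_humerus": {
      "dimension": 1,
      "mean": 6.48,
      "sd": 0.35
    },
    "b_wrist": {
      "dimension": 1,
      "mean": 5.21,
      "sd": 0.28
    },
    "g_arm_flexed": {
      "dimension": 1,
      "mean": 29.41,
      "sd": 2.37
    },
    "g_arm_relaxed": {
      "dimension": 1,
      "mean": 26.89,
      "sd": 2.33
    },
    "g_calf": {
      "dimension": 1,
      "mean": 35.25,
      "sd": 2.3
    },
    "g_chest": {
      "dimension": 1,
      "mean": 87.86,
      "sd": 5.18
    },
    "g_forearm": {
      "dimension": 1,
      "mean": 25.13,
      "sd": 1.41
    },
    "g_head": {
      "dimension": 1,
      "mean": 56.0,
      "sd": 1.44
    },
    "g_hip": {
      "dimension": 1,
      "mean": 94.67,
      "sd": 5.58
    },
    "g_thigh": {
      "dimension": 1,
      "mean": 55.82,
      "sd": 4.23
    },
    "g_waist": {
      "dimension": 1,
      "mean": 71.91,
      "sd": 4.45
    },
    "sf_abdominal": {
      "dimension": 1,
      "mean": 25.4,
      "sd": 7.78
    },
    "sf_front_thigh": {
      "dimension": 1,
      "mean": 27.0,
      "sd": 8.33
    },
    "sf_medial_calf": {
      "dimension": 1,
      "mean": 16.0,
      "sd": 4.67
    },
    "sf_subscapular": {
      "dimension": 1,
      "mean": 17.2,
      "sd": 5.07
    },
    "sf_supraspinale": {
      "dimension": 1,
      "mean": 15.4,
      "sd": 4.47
    },
    "sf_triceps": {
      "dimension": 1,
      "mean": 15.4,
      "sd": 4.47
    }
  },
  "notes": "Phantom-reference constants for the five-way tissue fractionation. Measurement means/SDs are the unisex phantom reference values (stature 170.18 cm, mass 64.58 kg). Tissue indicator assignments are a simplified uncorrected-measurement scheme: adipose <- six skinfolds; muscle <- limb/trunk girths; bone <- breadths + head girth; residual <- trunk girths; skin <- surface-area proxies (head/forearm girth, wrist breadth). Tissue mass means are phantom-consistent (they sum to the phantom body mass); SDs are calibrated so that typical lean endurance athletes land in published adiposity bands. Site-mapping simplifications relative to the original method (no skinfold girth corrections, no separate head bone term) are deliberate and documented here rather than resolved silently.",
  "phantom": {
    "height_cm": 170.18,
    "mass_kg": 64.58
  },
  "tissues": {
    "adipose": {
      "indicators": [
        "sf_triceps",
        "sf_subscapular",
        "sf_supraspinale",
        "sf_abdominal",
        "sf_front_thigh",
        "sf_medial_calf"
      ],
      "mass_mean_kg": 16.41,
      "mass_sd_kg": 1.6
    },
    "bone": {
      "indicators": [
        "b_biacromial",
        "b_biiliocristal",
        "b_humerus",
        "b_femur",
        "b_wrist",
        "g_head"
      ],
      "mass_mean_kg": 7.36,
      "mass_sd_kg": 0.98
    },
    "muscle": {
      "indicators": [
        "g_arm_relaxed",
        "g_forearm",
        "g_chest",
        "g_thigh",
        "g_calf"
      ],
      "mass_mean_kg": 25.55,
      "mass_sd_kg": 3.4
    },
    "residual": {
      "indicators": [
        "g_waist",
        "g_hip"
      ],
      "mass_mean_kg": 11.64,
      "mass_sd_kg": 1.55
    },
    "skin": {
      "indicators": [
        "g_head",
        "g_forearm",
        "b_wrist"
      ],
      "mass_mean_kg": 3.62,
      "mass_sd_kg": 0.48
    }
  },
  "version": "1.0"
}
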