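{
  "provenance": "published",
  "description": "Radiomics risk score: linear combination of 15 standardized features (arterial-phase CT; N = raw, G = Gaussian-filtered, LOG = Laplacian-of-Gaussian-filtered image).",
  "terms": [
    {"feature_id": "VOI|N|morph|volume", "coefficient": -0.047},
    {"feature_id": "VOI|N|morph|flatness", "coefficient": -0.075},
    {"feature_id": "AP|N|firstorder|maximum", "coefficient": -0.027},
    {"feature_id": "AP|N|firstorder|percentile25", "coefficient": -0.196},
    {"feature_id": "AP|LOG|firstorder|median", "coefficient": 0.049},
    {"feature_id": "AP|LOG|firstorder|robust_mad", "coefficient": -0.069},
    {"feature_id": "AP|N|glcm|cluster_shade", "coefficient": 0.085},
    {"feature_id": "AP|N|glcm|difference_entropy", "coefficient": -0.106},
    {"feature_id": "AP|N|glcm|joint_entropy", "coefficient": 0.656},
    {"feature_id": "AP|N|glszm|large_zone_high_gray_level_emphasis", "coefficient": 0.104},
    {"feature_id": "AP|LOG|glcm|cluster_shade", "coefficient": 0.251},
    {"feature_id": "AP|LOG|glcm|contrast", "coefficient": 0.028},
    {"feature_id": "AP|LOG|glszm|zone_size_variance", "coefficient": -0.013},
    {"feature_id": "AP|G|gldzm|large_distance_high_gray_level_emphasis", "coefficient": 0.116},
    {"feature_id": "AP|LOG|ngldm|high_dependence_high_gray_level_emphasis", "coefficient": -0.112}
  ]
}
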