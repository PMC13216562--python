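{
  "extraversion":           {"n_items": 6,  "response_min": 1, "response_max": 5,  "reverse_items": [2, 5],              "aggregation": "mean"},
  "agreeableness":          {"n_items": 6,  "response_min": 1, "response_max": 5,  "reverse_items": [1, 4],              "aggregation": "mean"},
  "conscientiousness":      {"n_items": 6,  "response_min": 1, "response_max": 5,  "reverse_items": [3, 6],              "aggregation": "mean"},
  "neuroticism":            {"n_items": 6,  "response_min": 1, "response_max": 5,  "reverse_items": [2, 4],              "aggregation": "mean"},
  "openness":               {"n_items": 6,  "response_min": 1, "response_max": 5,  "reverse_items": [1, 5],              "aggregation": "mean"},
  "need_to_belong":         {"n_items": 10, "response_min": 1, "response_max": 5,  "reverse_items": [1, 3, 7],           "aggregation": "mean"},
  "cognitive_reflection":   {"n_items": 7,  "response_min": 0, "response_max": 1,  "reverse_items": [],                  "aggregation": "sum"},
  "bullshit_receptivity":   {"n_items": 10, "response_min": 1, "response_max": 5,  "reverse_items": [],                  "aggregation": "mean"},
  "conspiracy_mentality":   {"n_items": 5,  "response_min": 0, "response_max": 10, "reverse_items": [],                  "aggregation": "mean"},
  "self_esteem":            {"n_items": 10, "response_min": 1, "response_max": 4,  "reverse_items": [2, 5, 6, 8, 9],     "aggregation": "mean"},
  "narcissism":             {"n_items": 16, "response_min": 0, "response_max": 1,  "reverse_items": [],                  "aggregation": "sum"},
  "intellectual_humility":  {"n_items": 6,  "response_min": 1, "response_max": 5,  "reverse_items": [],                  "aggregation": "mean"},
  "aot":                    {"n_items": 13, "response_min": 1, "response_max": 6,  "reverse_items": [10, 11, 12, 13],    "aggregation": "mean"},
  "need_to_evaluate":       {"n_items": 16, "response_min": 1, "response_max": 5,  "reverse_items": [2, 5, 8, 11, 14, 16], "aggregation": "mean"},
  "likeminded_identification": {"n_items": 10, "response_min": 1, "response_max": 5, "reverse_items": [], "aggregation": "difference_of_means"}
}
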