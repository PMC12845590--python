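"""Published group-level cumulative relevance tables (numeric fixture).

Per attribution method (Gradient × Input, Integrated Gradients) and task
dimension: per-feature cumulative relevance over the Low and High class
and the printed Total, all rounded to three decimals as published.
"""

# (feature, low, high, total)
GXI_VALENCE = [
    ("TD_PermEn", 2.102, 1.803, 3.905),
    ("TD_PFD", 1.304, 1.023, 2.327),
    ("β1a", 2.114, 1.671, 3.785),
    ("α2r", 0.965, 1.056, 2.021),
    ("β3a", 0.537, 0.525, 1.062),
    ("TD_ZCR", 1.304, 1.626, 2.930),
    ("θr", 1.798, 2.353, 4.151),
    ("Hjorth_Complexity", 2.770, 2.730, 5.499),
    ("Hjorth_Mobility", 2.687, 2.940, 5.628),
    ("β3r", 1.545, 1.349, 2.894),
    ("TD_HFD", 3.294, 3.287, 6.581),
    ("γ2r", 3.016, 2.944, 5.960),
    ("α2a", 2.701, 2.703, 5.405),
    ("β2r", 3.837, 3.745, 7.582),
    ("TD_LZC", 3.676, 3.956, 7.632),
    ("TD_SampEn", 3.846, 3.663, 7.509),
]

GXI_AROUSAL = [
    ("ABR", 2.271, 1.950, 4.221),
    ("AGR", 0.994, 1.125, 2.119),
    ("β2a", 1.526, 1.474, 3.000),
    ("β3a", 1.180, 1.007, 2.186),
    ("δa", 0.545, 0.730, 1.275),
    ("γ1a", 0.951, 1.112, 2.063),
    ("γ2a", 2.265, 2.579, 4.845),
    ("θa", 0.581, 0.644, 1.225),
    ("Hjorth_Complexity", 2.184, 2.314, 4.498),
    ("α1r", 0.926, 1.015, 1.941),
    ("α2r", 1.741, 1.850, 3.591),
    ("β1r", 0.906, 0.820, 1.726),
    ("β2r", 1.847, 1.686, 3.533),
    ("γ1r", 0.795, 0.896, 1.691),
    ("γ2r", 2.966, 3.004, 5.970),
    ("θr", 2.371, 2.908, 5.278),
    ("TD_HFD", 4.190, 4.292, 8.482),
    ("TD_Kurtosis", 1.213, 1.055, 2.268),
    ("TD_LZC", 3.289, 3.447, 6.736),
    ("TD_PFD", 0.905, 0.753, 1.658),
    ("TD_PermEn", 0.919, 0.904, 1.824),
    ("TD_SampEn", 3.722, 3.378, 7.099),
]

IG_VALENCE = [
    ("ABR", 2.756, 2.992, 5.748),
    ("β2a", 3.121, 2.375, 5.497),
    ("δa", 2.215, 3.064, 5.279),
    ("Hjorth_Complexity", 3.129, 2.757, 5.886),
    ("TD_PermEn", 3.415, 3.174, 6.589),
    ("TD_PFD", 3.647, 3.172, 6.819),
    ("β1r", 3.264, 2.664, 5.928),
    ("β3a", 3.623, 2.941, 6.565),
    ("TD_LZC", 4.570, 4.231, 8.800),
    ("TD_SampEn", 3.927, 4.740, 8.667),
    ("TD_HFD", 5.475, 6.144, 11.619),
    ("θr", 5.398, 5.971, 11.370),
]

IG_AROUSAL = [
    ("ABR", 1.050, 1.635, 2.685),
    ("AGR", 1.912, 1.628, 3.540),
    ("θr", 1.466, 1.280, 2.746),
    ("TD_HFD", 1.537, 1.634, 3.171),
    ("βa", 1.051, 0.691, 1.742),
    ("α1a", 1.441, 1.309, 2.750),
    ("β3a", 1.662, 1.407, 3.069),
    ("TD_ZCR", 1.386, 1.478, 2.864),
    ("Hjorth_Complexity", 2.128, 1.618, 3.746),
    ("α1r", 2.051, 2.334, 4.385),
    ("β2r", 1.908, 1.475, 3.383),
    ("γr", 2.596, 1.929, 4.525),
    ("TD_PermEn", 1.944, 1.418, 3.362),
    ("TD_PFD", 1.626, 1.215, 2.841),
    ("γ2r", 2.843, 3.199, 6.041),
    ("δr", 1.993, 1.483, 3.476),
    ("θa", 2.403, 2.481, 4.884),
    ("γ1a", 2.399, 1.629, 4.027),
    ("γa", 3.012, 2.778, 5.790),
    ("β3r", 3.874, 1.818, 5.692),
    ("β1a", 3.214, 4.007, 7.221),
    ("γ2a", 3.474, 4.917, 8.391),
    ("TD_LZC", 4.219, 3.712, 7.931),
    ("TD_SampEn", 4.604, 4.148, 8.752),
]

ALL_TABLES = {
    ("gxi", "valence"): GXI_VALENCE,
    ("gxi", "arousal"): GXI_AROUSAL,
    ("ig", "valence"): IG_VALENCE,
    ("ig", "arousal"): IG_AROUSAL,
}

# Published screening-score rows (arousal, mid-vs-high contrast):
# (feature, consistency, normalized effect size, median p, printed score)
SCREENING_ROWS = [
    ("βa", 0.86, 1.63, 8.93e-49, 16.80),
    ("γa", 0.75, 1.55, 4.10e-52, 13.94),
    ("γ2a", 0.75, 1.53, 2.52e-42, 13.79),
]
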