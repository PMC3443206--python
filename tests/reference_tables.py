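"""Frozen published summary tables from a national cross-sectional
disability-health survey (adults in households), used as
arithmetic-consistency fixtures: the printed estimates must be mutually
consistent under the package's own formulas (ratios, column sums, rounding
of prevented-case counts)."""

N_ADULT_POPULATION = 47_524_123
N_CHRONIC_POPULATION = 38_837_743

# condition -> (estimated count, printed % of chronic population,
#               printed % of overall adult population)
CONDITION_ESTIMATES = {
    "cancer": (923_096, 2.4, 1.9),
    "cardiovascular": (10_095_211, 26.0, 21.2),
    "dermatological": (2_957_850, 7.6, 6.2),
    "digestive": (2_179_675, 5.6, 4.6),
    "endocrine": (8_932_739, 23.0, 18.8),
    "musculoskeletal": (13_656_107, 35.2, 28.7),
    "neurological": (4_796_960, 12.4, 10.1),
    "psychiatric": (2_983_786, 7.7, 6.3),
    "respiratory": (5_443_578, 14.0, 11.5),
    "sensorial": (31_098_284, 80.1, 65.4),
    "sequelae_of_injury": (1_683_703, 4.3, 3.5),
    "urological": (2_289_618, 5.9, 4.8),
}

# disabled population counts by age class for the three disability
# definitions, plus the printed overall prevalence (% of adult population)
DISABLED_COUNTS = {
    "disability": {
        "18-40": 143_859, "40-65": 534_675, ">65": 1_158_219,
        "total": 1_836_753, "printed_prevalence": 3.9,
    },
    "severe": {
        "18-40": 67_681, "40-65": 112_254, ">65": 493_264,
        "total": 673_199, "printed_prevalence": 1.4,
    },
    "self_reported": {
        "18-40": 804_615, "40-65": 2_440_944, ">65": 2_473_309,
        "total": 5_718_868, "printed_prevalence": 12.0,
    },
}

# printed AAF columns (%) and their printed sums
AAF_COLUMNS = {
    ("disability", "18-40"): ([27.4, 17.6, 11.0, 10.0, 8.7, 7.6, 2.8, 1.4, 0.1], 86.6),
    ("disability", "40-65"): ([20.9, 13.6, 13.3, 10.2, 7.1, 6.1, 4.8, 2.0, 1.7], 79.7),
    ("disability", ">65"): ([21.0, 12.4, 10.9, 10.3, 5.5, 5.2, 1.4, 0.9, 0.0], 67.6),
    # the printed total-population sum (75.3) reflects unrounded entries and
    # is deliberately absent here (see the sums-row mode documentation)
    ("severe", "18-40"): ([40.3, 16.0, 15.4, 12.5, 3.7, 3.5, 3.1, 0.0, 0.0], 94.5),
    ("severe", "40-65"): ([29.7, 15.4, 14.6, 7.6, 7.4, 7.0, 3.1, 0.2, 0.0], 85.0),
    ("severe", ">65"): ([33.6, 19.9, 12.4, 4.2, 1.7, 1.6, 0.7, 0.0, 0.0], 74.1),
    ("severe", "total"): ([31.0, 17.5, 9.7, 7.6, 3.4, 3.2, 1.7, 0.0, 0.0], 74.1),
    ("self_reported", "18-40"): ([23.8, 17.5, 13.5, 6.6, 6.2, 3.5, 3.5, 3.3, 0.5], 78.4),
    ("self_reported", "40-65"): ([15.8, 13.1, 10.2, 10.0, 7.2, 6.9, 6.5, 5.9, 5.9], 81.5),
    ("self_reported", ">65"): ([13.6, 11.9, 9.3, 6.1, 5.7, 5.4, 5.2, 3.0, 0.3], 60.5),
    ("self_reported", "total"): ([15.4, 13.2, 9.7, 8.5, 8.0, 7.0, 5.5, 3.7, 2.4], 73.4),
}

# (AAF as proportion, disabled count, quoted prevented count) pairs whose
# quoted counts reproduce under nearest-10,000 rounding of AAF x N
PREVENTED_COUNT_QUOTES = [
    (0.174, 1_836_753, 320_000),   # disability, total, top condition
    (0.210, 1_158_219, 240_000),   # disability, >65
    (0.274, 143_859, 40_000),      # disability, 18-40
    (0.310, 673_199, 210_000),     # severe, total, top condition
    (0.403, 67_681, 30_000),       # severe, 18-40
    (0.154, 5_718_868, 880_000),   # self-reported, total, top condition
    (0.132, 5_718_868, 750_000),   # self-reported, total, 2nd
    (0.097, 5_718_868, 550_000),   # self-reported, total, 3rd
]
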