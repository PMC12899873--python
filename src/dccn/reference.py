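"""Published reference tables from the Korean prospective-cohort study.

Small printed summaries carried as package data: per-cohort counts
(participants, cases, person-years, quartile case counts) and the top-five
centrality rows of each differential subnetwork. They serve as fixed inputs
for arithmetic cross-checks and for validating the role-classification
rules; nothing here is produced by this package.
"""

from __future__ import annotations

import pandas as pd

# Cohort-level summary counts (rural discovery cohort, urban validation
# cohort).
COHORT_SUMMARY = {
    "discovery": {
        "n_participants": 16_665,
        "n_men": 6_162,
        "n_women": 10_503,
        "n_incident_cases": 953,
        "total_person_years": 96_605,
        "quartile_cases": (190, 201, 231, 331),
        "quartile_person_years": (22_787, 23_926, 24_566, 25_327),
    },
    "validation": {
        "n_participants": 51_206,
        "n_men": 16_536,
        "n_women": 34_670,
        "n_incident_cases": 2_190,
        "total_person_years": 205_454,
        "quartile_cases": (429, 492, 546, 723),
    },
}

# Top hub food in the non-diabetic full network: consumers / group size.
CONSUMER_COUNTS = {
    ("non_diabetic", "Total rice"): (12_066, 15_712),
    ("diabetic", "Total rice"): (721, 953),
}

# Top-five centrality rows per differential subnetwork: integrated
# centrality, the five raw measures, rank, and the published role label.
_ROLE_COLS = [
    "network", "food", "rank", "integrated", "degree", "betweenness",
    "eigenvector", "closeness", "strength", "role",
]
_ROLE_ROWS = [
    ("non_diabetic", "Cuttlefish", 1, 3.510, 6, 0.173, 1.000, 1.968, 1.393,
     "primary_hub"),
    ("non_diabetic", "Cheese/Fast", 2, 3.423, 5, 0.377, 0.754, 2.169, 1.067,
     "hub_food"),
    ("non_diabetic", "Mushroom", 3, 3.323, 5, 0.260, 0.870, 2.021, 1.166,
     "hub_food"),
    ("non_diabetic", "Poultry", 4, 2.662, 4, 0.156, 0.692, 1.637, 0.916,
     "bridge"),
    ("non_diabetic", "ImpFruit", 5, 2.536, 4, 0.294, 0.184, 1.770, 0.832,
     "bridge"),
    ("diabetic", "Bread", 1, 4.073, 5, 0.122, 1.000, 1.442, 1.146,
     "primary_hub"),
    ("diabetic", "DumplTeok", 2, 3.319, 4, 0.151, 0.428, 1.815, 0.852,
     "hub_food"),
    ("diabetic", "Egg", 3, 2.496, 2, 0.119, 0.594, 1.612, 0.463,
     "hub_food"),
    ("diabetic", "Poultry", 4, 2.432, 2, 0.127, 0.443, 1.769, 0.458,
     "connector"),
    ("diabetic", "SaltFood", 5, 2.221, 3, 0.061, 0.172, 1.303, 0.636,
     "connector"),
]


def reference_centrality_table() -> pd.DataFrame:
    """The ten published top-centrality rows as a DataFrame."""
    return pd.DataFrame(_ROLE_ROWS, columns=_ROLE_COLS)
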