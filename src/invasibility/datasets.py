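"""Published summary data for the Portuguese river-type fish survey.

Two small, printed datasets are bundled as plain Python structures:

* the morpho-climatic characterisation (mean, SD) of the 12 river types
  defined for continental Portugal under the Water Framework Directive,
  together with the number of sites sampled per type (380 in total,
  182 undisturbed and 198 disturbed), and

* the per-river-type summary of the national survey's non-native fish
  community: frequency of occurrence and mean density cells for the ten
  river types where non-native species occurred, used to reconstruct
  survey-wide pooled statistics.

These are summary statistics, not raw data: the underlying site-level
survey was never deposited, which is why the package ships a simulator
(:mod:`invasibility.simulate`) rather than the survey itself.
"""

from __future__ import annotations

import pandas as pd

# (name, temperature °C, precipitation mm, altitude m, drainage km², n sites)
# each climate entry is (mean, SD)
RIVER_TYPE_TABLE: list[tuple[str, tuple[float, float], tuple[float, float],
                             tuple[float, float], tuple[float, float], int]] = [
    ("M",      (11.0, 1.5), (1944, 379), (506, 300), (24.8, 17),  28),
    ("N1<100", (12.4, 1.3), (1190, 358), (413, 242), (33, 23),    60),
    ("N1>100", (12.6, 1.2), (1196, 374), (274, 205), (549, 65),   68),
    ("N2",     (13.1, 1.0), (596, 81),   (300, 141), (960, 1115), 20),
    ("N3",     (13.0, 0.8), (671, 134),  (432, 160), (32, 23),    28),
    ("N4",     (14.1, 0.7), (1065, 168), (280, 122), (151, 361),  16),
    ("L",      (14.8, 0.3), (941, 118),  (44, 44),   (180, 671),  33),
    ("S1<100", (15.7, 0.9), (628, 86),   (183, 75),  (30, 21),    26),
    ("S1>100", (15.8, 0.9), (587, 84),   (137, 68),  (439, 579),  33),
    ("S2",     (15.4, 0.3), (743, 85),   (175, 147), (60, 87),    22),
    ("S3",     (15.6, 0.4), (730, 118),  (54, 46),   (388, 1081), 37),
    ("S4",     (16.9, 0.5), (632, 60),   (54, 57),   (67, 89),    9),
]

RIVER_TYPE_NAMES = [row[0] for row in RIVER_TYPE_TABLE]
SITES_PER_TYPE = {row[0]: row[5] for row in RIVER_TYPE_TABLE}
TOTAL_SITES = sum(SITES_PER_TYPE.values())

N_UNDISTURBED = 182
N_DISTURBED = 198

# The ten non-native species recorded by the survey.
NONNATIVE_SPECIES = [
    "Lepomis gibbosus",
    "Gobio lozanoi",
    "Gambusia holbrooki",
    "Cyprinus carpio",
    "Carassius auratus",
    "Micropterus salmoides",
    "Herichthys facetum",
    "Ameiurus melas",
    "Sander lucioperca",
    "Alburnus alburnus",
]

# River types with any non-native occurrence (two types, M and S4, had none).
TYPES_WITH_NNS = ["N1<100", "N1>100", "N2", "N3", "N4", "L",
                  "S1<100", "S1>100", "S2", "S3"]

# Frequency of occurrence of any non-native species, all sites pooled per type.
NNS_FOC_BY_TYPE = {
    "N1<100": 0.1, "N1>100": 0.4, "N2": 0.7, "N3": 0.07, "N4": 0.2,
    "L": 0.5, "S1<100": 0.4, "S1>100": 0.7, "S2": 0.3, "S3": 0.5,
}

# Survey-wide frequency of occurrence of any NNS, undisturbed vs disturbed.
NNS_FOC_UNDISTURBED = 0.18
NNS_FOC_DISTURBED = 0.46

# Per-type mean densities (ind./100 m², all sites pooled) of the three most
# frequent and abundant non-native species.
FOCAL_MEAN_DENSITY_BY_TYPE = {
    "Lepomis gibbosus": {
        "N1<100": 0.1, "N1>100": 1.1, "N2": 0.6, "N3": 0.01, "N4": 0.3,
        "L": 0.8, "S1<100": 2.3, "S1>100": 2.1, "S2": 0.06, "S3": 2.3,
    },
    "Gobio lozanoi": {
        "N1<100": 2.2, "N1>100": 3.4, "N2": 0.6, "N3": 0.07, "N4": 0.0,
        "L": 7.5, "S1<100": 0.0, "S1>100": 0.0, "S2": 0.0, "S3": 1.6,
    },
    "Gambusia holbrooki": {
        "N1<100": 0.0, "N1>100": 0.03, "N2": 0.0, "N3": 0.0, "N4": 0.01,
        "L": 0.7, "S1<100": 1.1, "S1>100": 2.7, "S2": 0.9, "S3": 1.1,
    },
}


def river_type_frame() -> pd.DataFrame:
    """Morpho-climatic characterisation of the 12 river types as a frame."""
    rows = []
    for name, temp, precip, alt, area, n in RIVER_TYPE_TABLE:
        rows.append({
            "river_type": name,
            "temperature_mean": temp[0], "temperature_sd": temp[1],
            "precipitation_mean": precip[0], "precipitation_sd": precip[1],
            "altitude_mean": alt[0], "altitude_sd": alt[1],
            "drainage_area_mean": area[0], "drainage_area_sd": area[1],
            "n_sites": n,
        })
    return pd.DataFrame(rows).set_index("river_type")
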