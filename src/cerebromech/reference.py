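"""Published study inputs used as fixed reference data.

Donor ages per pathology group, the study-wide media/adventitia
area-fraction statistics behind the empty-band threshold, and the
per-group collagen composition profiles (mean and SD of each collagen
type's percentage of total collagen) for the control and advanced-AD
groups.  These printed values serve as inputs: summary-statistics checks,
the pooled band threshold, and realistic defaults for the abundance-table
simulator.
"""

from __future__ import annotations

# Donor ages (years) by neuropathology group
DONOR_AGES: dict[str, list[int]] = {
    "control": [59, 72, 83, 72],
    "early_ad": [66, 61, 80, 72],
    "intermediate_ad": [77, 79, 69],
    "advanced_ad": [63, 78, 61, 62, 63, 95, 83, 79],
}

# Study-pooled elastic-fiber area fractions (mean, SD), as fractions of 1
MEDIA_AREA_FRACTION = (0.318, 0.085)
ADVENTITIA_AREA_FRACTION = (0.478, 0.164)

# Collagen composition profiles: type -> (mean %, SD %) of total collagen
COLLAGEN_PROFILE_CONTROL: dict[str, tuple[float, float]] = {
    "I": (43.52, 16.42),
    "II": (0.26, 0.08),
    "III": (26.98, 4.43),
    "IV": (23.11, 10.47),
    "V": (0.07, 0.01),
    "VI": (4.52, 1.77),
    "VIII": (0.76, 0.30),
    "XII": (0.01, 0.005),  # printed SD 0.00 at 2 decimals; a strictly positive stand-in
    "XIV": (0.20, 0.10),
    "XVI": (0.22, 0.05),
    "XVIII": (0.30, 0.14),
    "XXI": (0.03, 0.01),
}

COLLAGEN_PROFILE_AD: dict[str, tuple[float, float]] = {
    "I": (54.14, 17.38),
    "II": (0.33, 0.17),
    "III": (24.10, 4.35),
    "IV": (16.32, 15.59),
    "V": (0.10, 0.03),
    "VI": (3.51, 3.02),
    "VIII": (0.81, 0.58),
    "XII": (0.02, 0.02),
    "XIV": (0.10, 0.09),
    "XVI": (0.24, 0.15),
    "XVIII": (0.30, 0.26),
    "XXI": (0.04, 0.03),
}

# Proteomics sample sizes (control vs advanced AD)
N_PROTEOMICS = {"control": 5, "advanced_ad": 6}
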