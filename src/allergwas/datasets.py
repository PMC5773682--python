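"""Reference tables bundled with the package.

Two kinds of constants live here:

* Control-cohort HLA allele frequency spectra for ``HLA-DRB1``, ``HLA-DQB1``
  and ``HLA-DPB1`` observed in a large Japanese female control sample.  These
  seed the synthetic cohort generator's default allele spectra, so simulated
  HLA data has a realistic multi-allelic frequency profile.

* Worked-example inputs for the shrimp- and peach-allergy HLA association
  signals: the published per-sampleset odds ratios with 95% confidence
  intervals for the two top SNPs, and the step-0 case/control allele
  frequency columns of the stepwise (RPE) HLA-DRB1 analyses.  The package's
  meta-analysis and RPE arithmetic can be checked end-to-end against the
  published pooled/step-1 values using only these printed inputs.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Control allele-frequency spectra (two-field alleles, frequencies as printed
# to 3 decimals; "99:01" aggregates the residual rare-allele mass so each
# spectrum sums to ~1 before internal renormalization).
# ---------------------------------------------------------------------------

CONTROL_HLA_FREQS: dict[str, dict[str, float]] = {
    "DRB1": {
        "09:01": 0.148, "14:05": 0.020, "15:01": 0.077, "15:02": 0.107,
        "14:03": 0.015, "08:03": 0.082, "04:05": 0.131, "14:54": 0.031,
        "12:02": 0.020, "01:01": 0.060, "08:02": 0.045, "11:01": 0.027,
        "13:02": 0.070, "04:06": 0.036, "14:06": 0.016, "04:10": 0.015,
        "12:01": 0.035, "04:03": 0.034, "04:01": 0.009, "16:02": 0.008,
        "13:01": 0.006, "99:01": 0.008,
    },
    "DQB1": {
        "03:03": 0.160, "06:02": 0.072, "05:03": 0.040, "06:01": 0.185,
        "04:01": 0.131, "05:02": 0.023, "05:01": 0.063, "06:04": 0.064,
        "04:02": 0.035, "03:01": 0.115, "03:02": 0.101, "06:03": 0.005,
        "99:01": 0.006,
    },
    "DPB1": {
        "05:01": 0.392, "02:01": 0.247, "04:02": 0.100, "09:01": 0.095,
        "03:01": 0.054, "04:01": 0.050, "02:02": 0.028, "13:01": 0.018,
        "14:01": 0.009, "19:01": 0.006, "06:01": 0.001,
    },
}

# Common DRB1 -> DQB1 haplotype partners in the Japanese population; the
# simulator couples the two loci through this map so that two-locus
# haplotype analyses see realistic linkage.
DRB1_DQB1_PARTNERS: dict[str, str] = {
    "09:01": "03:03", "04:05": "04:01", "15:01": "06:02", "14:05": "05:03",
    "15:02": "06:01", "08:03": "06:01", "01:01": "05:01", "13:02": "06:04",
    "12:02": "03:01", "04:06": "03:02", "14:54": "05:02", "08:02": "04:02",
    "11:01": "03:01", "14:03": "03:01", "12:01": "03:01", "04:03": "03:02",
    "04:10": "04:02", "04:01": "03:01", "16:02": "05:02", "14:06": "03:01",
    "13:01": "06:03", "99:01": "99:01",
}

# ---------------------------------------------------------------------------
# Worked-example inputs: per-sampleset OR [95% CI] for the two top SNPs.
# ---------------------------------------------------------------------------

TOP_SNP_SET_ESTIMATES: dict[str, dict[str, tuple[float, float, float]]] = {
    # food -> sampleset -> (OR, CI low, CI high)
    "peach": {"LL01": (1.70, 1.34, 2.14), "LL02": (1.91, 1.51, 2.40)},
    "shrimp": {"LL01": (2.27, 1.84, 2.80), "LL02": (1.58, 1.27, 1.97)},
}

TOP_SNP_RSID = {"peach": "rs28359884", "shrimp": "rs74995702"}

# ---------------------------------------------------------------------------
# Step-0 HLA-DRB1 allele frequency columns (controls, cases) of the stepwise
# RPE analyses for peach and shrimp allergy.
# ---------------------------------------------------------------------------

RPE_DRB1_STEP0: dict[str, dict[str, tuple[float, float]]] = {
    "peach": {
        "09:01": (0.148, 0.225), "14:05": (0.020, 0.042),
        "15:01": (0.077, 0.111), "15:02": (0.107, 0.134),
        "14:03": (0.015, 0.021), "08:03": (0.082, 0.080),
        "04:05": (0.131, 0.077), "14:54": (0.031, 0.034),
        "12:02": (0.020, 0.008), "01:01": (0.060, 0.034),
        "08:02": (0.045, 0.041), "11:01": (0.027, 0.016),
        "13:02": (0.070, 0.059), "04:06": (0.036, 0.023),
        "14:06": (0.016, 0.010), "04:10": (0.015, 0.010),
        "12:01": (0.035, 0.026), "04:03": (0.034, 0.026),
        "04:01": (0.009, 0.007), "16:02": (0.008, 0.010),
    },
    "shrimp": {
        "04:05": (0.131, 0.232), "15:01": (0.077, 0.101),
        "12:02": (0.020, 0.007), "16:02": (0.008, 0.002),
        "08:02": (0.045, 0.048), "04:01": (0.009, 0.012),
        "09:01": (0.148, 0.112), "12:01": (0.035, 0.023),
        "14:06": (0.016, 0.017), "14:54": (0.031, 0.030),
        "08:03": (0.082, 0.075), "13:02": (0.070, 0.063),
        "14:03": (0.015, 0.014), "14:05": (0.020, 0.018),
        "01:01": (0.060, 0.052), "15:02": (0.107, 0.091),
        "11:01": (0.027, 0.023), "04:06": (0.036, 0.030),
        "04:10": (0.015, 0.013), "04:03": (0.034, 0.029),
        "13:01": (0.006, 0.005),
    },
}

# ---------------------------------------------------------------------------
# Food questionnaire universe: 27 foods grouped as in the questionnaire
# (fruits, legumes/grains, nuts, vegetables/mushrooms, eggs/dairy, meats,
# fish, shellfish).  Group membership drives the shared-liability component
# of the simulator and hence the cross-reactivity block structure.
# ---------------------------------------------------------------------------

FOOD_GROUPS: dict[str, tuple[str, ...]] = {
    "fruit": ("apple", "peach", "kiwi", "banana", "orange", "strawberry", "melon"),
    "grain": ("wheat", "buckwheat", "soy"),
    "nut": ("peanut", "walnut", "almond"),
    "vegetable": ("chinese_yam", "tomato", "mushroom"),
    "egg_dairy": ("egg", "milk", "cheese"),
    "meat": ("beef", "pork"),
    "fish": ("mackerel", "salmon", "sardine"),
    "shellfish": ("shrimp", "crab", "squid"),
}

FOODS: tuple[str, ...] = tuple(f for group in FOOD_GROUPS.values() for f in group)

FOOD_TO_GROUP: dict[str, str] = {
    food: group for group, foods in FOOD_GROUPS.items() for food in foods
}

assert len(FOODS) == 27
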