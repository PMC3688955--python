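"""Published ITS heterogeneity measurements for Ephydatia fluviatilis.

Direct-sequencing ITS profile measurements for 13 freshwater-sponge
specimens from Estonian rivers (samples K1-K2, L, Pe1-Pe2, Pi, R, V1-V6),
as printed in the original study of this method.  These tables are inputs
for replicate statistics, joint-deletion inference and strain comparisons;
they are not produced by this package.

All values are percentages.  ITS1 substitution columns are keyed by
(position, base) with the base observed against the GenBank consensus.
"""

from __future__ import annotations

from .profiling import ITSProfile

# Repeatability experiments: one V2 DNA extraction amplified under varying PCR
# conditions. Columns: ITS1 253-nt %, 254-nt %, base A % and T % at ITS1
# position 169.  The first three rows are the 100 ng replicates.
V2_PCR_CONDITIONS = [
    "100ng_1",
    "100ng_2",
    "100ng_3",
    "primers_2to1",
    "primers_1to2",
    "10ng",
    "1ng",
]
V2_REPLICATES = {
    "len253": [25.49, 24.76, 24.84, 25.41, 24.68, 26.17, 27.29],
    "len254": [74.51, 75.24, 75.16, 74.59, 75.32, 73.83, 72.71],
    "sub169_A": [34, 35, 36, 34, 37, 36, 38],
    "sub169_T": [66, 65, 64, 66, 63, 64, 62],
}
V2_REFERENCE_SUBSET = [0, 1, 2]  # the three 100 ng replicates

# ITS1 length percentages in five samples cut from different parts of one
# individual (V3). Sample 3 failed noise QC (>10%) and is excluded from the
# quantitative comparison.
V3_SITE_SAMPLES = [1, 2, 3, 4, 5]
V3_SITES = {
    252: [6, 7, 10, 8, 8],
    253: [31, 30, 31, 32, 31],
    254: [57, 56, 51, 54, 55],
    255: [5, 6, 8, 6, 6],
}
V3_QC_FAILED_SAMPLE = 3

# Per-individual ITS1 profiles: length percentages and substitution
# percentages (position, base vs consensus).
ITS1_PROFILES = {
    "K1": {"len": {252: 0, 253: 23, 254: 77, 255: 0}, "sub": {(163, "G"): 0, (169, "A"): 52, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0}},
    "K2": {"len": {252: 0, 253: 34, 254: 34, 255: 32}, "sub": {(163, "G"): 0, (169, "A"): 63, (173, "A"): 17, (174, "A"): 0, (180, "T"): 0}},
    "L": {"len": {252: 0, 253: 42, 254: 5, 255: 52}, "sub": {(163, "G"): 0, (169, "A"): 83, (173, "A"): 43, (174, "A"): 48, (180, "T"): 43}},
    "Pe1": {"len": {252: 0, 253: 6, 254: 35, 255: 59}, "sub": {(163, "G"): 0, (169, "A"): 74, (173, "A"): 0, (174, "A"): 49, (180, "T"): 41}},
    "Pe2": {"len": {252: 0, 253: 6, 254: 32, 255: 62}, "sub": {(163, "G"): 0, (169, "A"): 75, (173, "A"): 0, (174, "A"): 54, (180, "T"): 41}},
    "Pi": {"len": {252: 0, 253: 12, 254: 33, 255: 56}, "sub": {(163, "G"): 0, (169, "A"): 68, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0}},
    "R": {"len": {252: 0, 253: 7, 254: 88, 255: 5}, "sub": {(163, "G"): 0, (169, "A"): 97, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0}},
    "V1": {"len": {252: 0, 253: 82, 254: 10, 255: 8}, "sub": {(163, "G"): 0, (169, "A"): 79, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0}},
    "V2": {"len": {252: 0, 253: 25, 254: 75, 255: 0}, "sub": {(163, "G"): 0, (169, "A"): 35, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0}},
    "V3": {"len": {252: 7, 253: 31, 254: 56, 255: 6}, "sub": {(163, "G"): 0, (169, "A"): 0, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0}},
    "V4": {"len": {252: 0, 253: 19, 254: 81, 255: 0}, "sub": {(163, "G"): 0, (169, "A"): 48, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0}},
    "V5": {"len": {252: 0, 253: 18, 254: 82, 255: 0}, "sub": {(163, "G"): 0, (169, "A"): 61, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0}},
    "V6": {"len": {252: 0, 253: 19, 254: 81, 255: 0}, "sub": {(163, "G"): 17, (169, "A"): 63, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0}},
}

# Per-individual ITS2 profiles (lengths and substitutions); V4 was not
# reported for ITS2.
ITS2_PROFILES = {
    "K1": {"len": {321: 32, 322: 29, 323: 39}, "sub": {(151, "A"): 51, (244, "A"): 0, (268, "G"): 0}},
    "K2": {"len": {321: 21, 322: 62, 323: 17}, "sub": {(151, "A"): 17, (244, "A"): 28, (268, "G"): 0}},
    "Pe1": {"len": {321: 54, 322: 19, 323: 27}, "sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0}},
    "Pe2": {"len": {321: 48, 322: 36, 323: 13}, "sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0}},
    "Pi": {"len": {321: 0, 322: 70, 323: 29}, "sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0}},
    "R": {"len": {321: 10, 322: 73, 323: 17}, "sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 32}},
    "V1": {"len": {321: 87, 322: 8, 323: 5}, "sub": {(151, "A"): 0, (244, "A"): 86, (268, "G"): 0}},
    "V2": {"len": {321: 20, 322: 25, 323: 55}, "sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0}},
    "V3": {"len": {321: 5, 322: 7, 323: 88}, "sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0}},
    "V5": {"len": {321: 0, 322: 8, 323: 92}, "sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0}},
    "V6": {"len": {321: 0, 322: 7, 323: 93}, "sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0}},
}

# Strain-comparison tables (same-strain pair Pe1/Pe2 vs different-strain pair
# V1/V2), including per-site ITS2 deletion percentages.  The site-247 values
# were measured directly with the proportion model; the site-13 values derive
# from the total-length distribution via the joint-deletion identity.  Note
# the published comparison table carries 38 for Pe2 ITS2 322 nt where the
# per-individual table above carries 36.
STRAIN_COMPARISON = {
    "Pe1": {
        "ITS1_len": {252: 0, 253: 6, 254: 35, 255: 59},
        "ITS1_sub": {(169, "A"): 74, (173, "A"): 0, (174, "A"): 49, (180, "T"): 41, (163, "G"): 0},
        "ITS2_len": {321: 54, 322: 19, 323: 27},
        "ITS2_sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0},
        "ITS2_del": {13: 65, 247: 62},
    },
    "Pe2": {
        "ITS1_len": {252: 0, 253: 6, 254: 32, 255: 62},
        "ITS1_sub": {(169, "A"): 75, (173, "A"): 0, (174, "A"): 54, (180, "T"): 41, (163, "G"): 0},
        "ITS2_len": {321: 48, 322: 38, 323: 13},
        "ITS2_sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0},
        "ITS2_del": {13: 70, 247: 64},
    },
    "V1": {
        "ITS1_len": {252: 0, 253: 82, 254: 10, 255: 8},
        "ITS1_sub": {(169, "A"): 79, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0, (163, "G"): 0},
        "ITS2_len": {321: 87, 322: 8, 323: 5},
        "ITS2_sub": {(151, "A"): 0, (244, "A"): 86, (268, "G"): 0},
        "ITS2_del": {13: 95, 247: 87},
    },
    "V2": {
        "ITS1_len": {252: 0, 253: 25, 254: 75, 255: 0},
        "ITS1_sub": {(169, "A"): 35, (173, "A"): 0, (174, "A"): 0, (180, "T"): 0, (163, "G"): 0},
        "ITS2_len": {321: 20, 322: 25, 323: 55},
        "ITS2_sub": {(151, "A"): 0, (244, "A"): 0, (268, "G"): 0},
        "ITS2_del": {13: 32, 247: 33},
    },
}


def strain_profile(sample_id: str) -> ITSProfile:
    """The strain-comparison measurements for one specimen as an ITSProfile."""
    d = STRAIN_COMPARISON[sample_id]
    return ITSProfile(
        sample_id=sample_id,
        length_pct={"ITS1": dict(d["ITS1_len"]), "ITS2": dict(d["ITS2_len"])},
        substitution_pct={
            "ITS1": {k: v for k, v in d["ITS1_sub"].items() if v > 0},
            "ITS2": {k: v for k, v in d["ITS2_sub"].items() if v > 0},
        },
        deletion_pct={"ITS2": dict(d["ITS2_del"])},
        thresholds_applied=True,
    )


def individual_profile(sample_id: str) -> ITSProfile:
    """The per-individual profile measurements for one specimen."""
    prof = ITSProfile(sample_id=sample_id, thresholds_applied=True)
    if sample_id in ITS1_PROFILES:
        d = ITS1_PROFILES[sample_id]
        prof.length_pct["ITS1"] = dict(d["len"])
        prof.substitution_pct["ITS1"] = {k: v for k, v in d["sub"].items() if v > 0}
    if sample_id in ITS2_PROFILES:
        d = ITS2_PROFILES[sample_id]
        prof.length_pct["ITS2"] = dict(d["len"])
        prof.substitution_pct["ITS2"] = {k: v for k, v in d["sub"].items() if v > 0}
    return prof
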