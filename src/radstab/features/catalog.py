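"""The canonical 91-feature catalog.

Non-shape handcrafted radiomic features in six families: 18 first-order
intensity statistics and five gray-level texture-matrix families (22 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM). Families appear in that fixed
order; names are alphabetical within a family. Deprecated duplicates
(GLCM Dissimilarity, SumVariance and SumAverage — linear functions of
DifferenceAverage, ClusterTendency and JointAverage on a symmetric
matrix) are excluded, which is what brings the GLCM family to 22 and the
total to 91.
"""

from __future__ import annotations

FIRSTORDER = sorted(
    [
        "10Percentile",
        "90Percentile",
        "Energy",
        "Entropy",
        "InterquartileRange",
        "Kurtosis",
        "Maximum",
        "Mean",
        "MeanAbsoluteDeviation",
        "Median",
        "Minimum",
        "Range",
        "RobustMeanAbsoluteDeviation",
        "RootMeanSquared",
        "Skewness",
        "TotalEnergy",
        "Uniformity",
        "Variance",
    ]
)

GLCM = sorted(
    [
        "Autocorrelation",
        "ClusterProminence",
        "ClusterShade",
        "ClusterTendency",
        "Contrast",
        "Correlation",
        "DifferenceAverage",
        "DifferenceEntropy",
        "DifferenceVariance",
        "Id",
        "Idm",
        "Idmn",
        "Idn",
        "Imc1",
        "Imc2",
        "InverseVariance",
        "JointAverage",
        "JointEnergy",
        "JointEntropy",
        "MCC",
        "MaximumProbability",
        "SumEntropy",
    ]
)

GLRLM = sorted(
    [
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance",
        "HighGrayLevelRunEmphasis",
        "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis",
        "RunEntropy",
        "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized",
        "RunPercentage",
        "RunVariance",
        "ShortRunEmphasis",
        "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ]
)

GLSZM = sorted(
    [
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance",
        "HighGrayLevelZoneEmphasis",
        "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis",
        "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized",
        "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis",
        "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy",
        "ZonePercentage",
        "ZoneVariance",
    ]
)

GLDM = sorted(
    [
        "DependenceEntropy",
        "DependenceNonUniformity",
        "DependenceNonUniformityNormalized",
        "DependenceVariance",
        "GrayLevelNonUniformity",
        "GrayLevelVariance",
        "HighGrayLevelEmphasis",
        "LargeDependenceEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ]
)

NGTDM = sorted(["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"])

FAMILIES: dict[str, list[str]] = {
    "firstorder": FIRSTORDER,
    "glcm": GLCM,
    "glrlm": GLRLM,
    "glszm": GLSZM,
    "gldm": GLDM,
    "ngtdm": NGTDM,
}

#: canonical order of the 91 columns: family order, alphabetical within
FEATURE_NAMES: list[str] = [
    f"{fam}_{name}" for fam, names in FAMILIES.items() for name in names
]

assert len(FEATURE_NAMES) == 91
assert len(set(FEATURE_NAMES)) == 91


def catalog_rows() -> list[tuple[str, str, str]]:
    """(full name, family, short name) rows, canonical order."""
    return [
        (f"{fam}_{name}", fam, name)
        for fam, names in FAMILIES.items()
        for name in names
    ]
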