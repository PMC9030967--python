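"""Reference constants from the EOTRH radiographic texture study.

The study screened 9 filters x 93 features on 472 graded maxillary incisor
radiographs and reported, per texture family, the features whose trend with
disease grade was reproducible across every filter (criterion 2).  Those
published selections are kept here as reference data: the package can
recompute the per-family selection percentages the study derived from them,
and synthetic-cohort results can be compared against the reported direction
structure.
"""

from .texture_engine import FAMILY_NAMES

#: Features reported to pass criterion 2 (trend reproducible across all nine
#: filters), by family, in canonical snake_case names.
CRITERION2_FEATURES = {
    "FOS": ["variance", "range", "maximum", "skewness"],
    "GLCM": [
        "autocorrelation",
        "cluster_prominence",
        "cluster_shade",
        "contrast",
        "difference_average",
        "difference_entropy",
        "difference_variance",
        "joint_average",
        "sum_average",
    ],
    "NGTDM": ["complexity"],
    "GLDM": [
        "gray_level_variance",
        "high_gray_level_emphasis",
        "large_dependence_high_gray_level_emphasis",
        "large_dependence_low_gray_level_emphasis",
        "low_gray_level_emphasis",
    ],
    "GLRLM": [
        "gray_level_variance",
        "high_gray_level_run_emphasis",
        "long_run_high_gray_level_emphasis",
        "gray_level_non_uniformity_normalized",
        "long_run_low_gray_level_emphasis",
        "low_gray_level_run_emphasis",
    ],
    "GLSZM": [
        "gray_level_variance",
        "high_gray_level_zone_emphasis",
        "gray_level_non_uniformity_normalized",
    ],
}

#: Study cohort bookkeeping: graded teeth per EOTRH class 0-3, and exclusions.
CLASS_SIZES = (105, 195, 111, 61)
N_EXCLUDED = 8


def criterion2_percentages() -> dict[str, float]:
    """Percent of each family's features passing criterion 2, to 0.1%.

    Computed arithmetically from the reported per-family selections and the
    canonical family sizes (18/24/5/14/16/16).
    """
    for family, names in CRITERION2_FEATURES.items():
        unknown = set(names) - set(FAMILY_NAMES[family])
        if unknown:  # guard against drift between lists and the manifest
            raise ValueError(f"{family}: unknown feature names {sorted(unknown)}")
    return {
        family: round(100.0 * len(names) / len(FAMILY_NAMES[family]), 1)
        for family, names in CRITERION2_FEATURES.items()
    }
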