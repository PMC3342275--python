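"""Bundled example data: published summary statistics from a zebrafish
coding-exon enhancer reporter screen.

The screen scored GFP expression in ten anatomies for a minimal-promoter
control cohort and for candidate conserved coding exons (four example
constructs are tabulated here): raw expressing fractions, one-sided
two-proportion p-values against the control, mean rank-sum p-values over
three shuffling runs, and which (construct, anatomy) cells were marked
significant under the dual rule. Cohort-level counts from the same screen
(activity, specificity, chromatin-mark overlap) are included for the
comparison analyses. These numbers serve as reference inputs for examples
and regression checks; the raw embryo data behind them is emulated by
:mod:`exonhancer.synthetic`.
"""

from __future__ import annotations

import pandas as pd

ANATOMIES: tuple[str, ...] = (
    "Forebrain",
    "Midbrain/Hindbrain",
    "Eye",
    "Ear/AboveHeart",
    "Heart",
    "Notochord",
    "Yolk/YolkExtension",
    "MidTrunk/AboveYolk",
    "Muscle",
    "TailRegion",
)

CONTROL_N = 161
CONTROL_PROPORTIONS: dict[str, float] = {
    "Forebrain": 0.3354,
    "Midbrain/Hindbrain": 0.2546,
    "Eye": 0.1800,
    "Ear/AboveHeart": 0.0680,
    "Heart": 0.3160,
    "Notochord": 0.1610,
    "Yolk/YolkExtension": 0.1550,
    "MidTrunk/AboveYolk": 0.0800,
    "Muscle": 0.1800,
    "TailRegion": 0.1240,
}

# Per-construct: embryo count, expressing fractions, both p-value sets, the
# significant (dual-rule marked) anatomies, and the printed fold ratios.
CCES: dict[str, dict] = {
    "rab11fip4a": {
        "n": 53,
        "proportions": {
            "Forebrain": 0.4340, "Midbrain/Hindbrain": 0.1509, "Eye": 0.2264,
            "Ear/AboveHeart": 0.0189, "Heart": 0.2264, "Notochord": 0.6038,
            "Yolk/YolkExtension": 0.2075, "MidTrunk/AboveYolk": 0.0943,
            "Muscle": 0.1509, "TailRegion": 0.1887,
        },
        "p_prop": {
            "Forebrain": 0.1289, "Midbrain/Hindbrain": 0.9147, "Eye": 0.2941,
            "Ear/AboveHeart": 0.8445, "Heart": 0.8595, "Notochord": 5.14e-10,
            "Yolk/YolkExtension": 0.2512, "MidTrunk/AboveYolk": 0.4904,
            "Muscle": 0.6094, "TailRegion": 0.1725,
        },
        "p_ranksum": {
            "Forebrain": 0.1964, "Midbrain/Hindbrain": 0.9497, "Eye": 0.2282,
            "Ear/AboveHeart": 0.9744, "Heart": 0.9047, "Notochord": 0.0058,
            "Yolk/YolkExtension": 0.2801, "MidTrunk/AboveYolk": 0.5277,
            "Muscle": 0.7513, "TailRegion": 0.4191,
        },
        "significant": {"Notochord"},
        "ratios": {"Notochord": 3.8},
    },
    "abca1a": {
        "n": 43,
        "proportions": {
            "Forebrain": 0.3488, "Midbrain/Hindbrain": 0.3953, "Eye": 0.4419,
            "Ear/AboveHeart": 0.0698, "Heart": 0.0000, "Notochord": 0.3953,
            "Yolk/YolkExtension": 0.3953, "MidTrunk/AboveYolk": 0.0930,
            "Muscle": 0.3488, "TailRegion": 0.1163,
        },
        "p_prop": {
            "Forebrain": 0.5000, "Midbrain/Hindbrain": 0.0519, "Eye": 0.0003,
            "Ear/AboveHeart": 0.5000, "Heart": 1.0000, "Notochord": 0.0009,
            "Yolk/YolkExtension": 0.0006, "MidTrunk/AboveYolk": 0.5000,
            "Muscle": 0.0146, "TailRegion": 0.5000,
        },
        "p_ranksum": {
            "Forebrain": 0.5680, "Midbrain/Hindbrain": 0.1371, "Eye": 0.0460,
            "Ear/AboveHeart": 0.7036, "Heart": 0.9981, "Notochord": 0.0057,
            "Yolk/YolkExtension": 0.0276, "MidTrunk/AboveYolk": 0.5800,
            "Muscle": 0.0524, "TailRegion": 0.5419,
        },
        "significant": {"Eye", "Notochord", "Yolk/YolkExtension"},
        "ratios": {"Eye": 2.5, "Notochord": 2.5, "Yolk/YolkExtension": 2.6},
    },
    "odz3": {
        "n": 39,
        "proportions": {
            "Forebrain": 0.8205, "Midbrain/Hindbrain": 0.0256, "Eye": 0.0769,
            "Ear/AboveHeart": 0.2821, "Heart": 0.1538, "Notochord": 0.0769,
            "Yolk/YolkExtension": 0.1282, "MidTrunk/AboveYolk": 0.1538,
            "Muscle": 0.5128, "TailRegion": 0.2051,
        },
        "p_prop": {
            "Forebrain": 5.48e-08, "Midbrain/Hindbrain": 0.9983, "Eye": 0.9089,
            "Ear/AboveHeart": 0.0002, "Heart": 0.9660, "Notochord": 0.8627,
            "Yolk/YolkExtension": 0.5694, "MidTrunk/AboveYolk": 0.1373,
            "Muscle": 1.84e-05, "TailRegion": 0.1470,
        },
        "p_ranksum": {
            "Forebrain": 0.0053, "Midbrain/Hindbrain": 0.9961, "Eye": 0.9572,
            "Ear/AboveHeart": 0.0287, "Heart": 0.9758, "Notochord": 0.9847,
            "Yolk/YolkExtension": 0.7832, "MidTrunk/AboveYolk": 0.2014,
            "Muscle": 0.0205, "TailRegion": 0.1681,
        },
        "significant": {"Forebrain", "Ear/AboveHeart", "Muscle"},
        "ratios": {"Forebrain": 2.4, "Ear/AboveHeart": 4.1, "Muscle": 2.8},
    },
    "rfx2": {
        "n": 48,
        "proportions": {
            "Forebrain": 0.3750, "Midbrain/Hindbrain": 0.1250, "Eye": 0.1667,
            "Ear/AboveHeart": 0.0208, "Heart": 0.1042, "Notochord": 0.1042,
            "Yolk/YolkExtension": 0.2708, "MidTrunk/AboveYolk": 0.0000,
            "Muscle": 0.6875, "TailRegion": 0.1667,
        },
        "p_prop": {
            "Forebrain": 0.3693, "Midbrain/Hindbrain": 0.9546, "Eye": 0.5000,
            "Ear/AboveHeart": 0.8127, "Heart": 0.9969, "Notochord": 0.7732,
            "Yolk/YolkExtension": 0.0539, "MidTrunk/AboveYolk": 0.9547,
            "Muscle": 2.44e-11, "TailRegion": 0.3028,
        },
        "p_ranksum": {
            "Forebrain": 0.5038, "Midbrain/Hindbrain": 0.9711, "Eye": 0.7784,
            "Ear/AboveHeart": 0.9525, "Heart": 0.9950, "Notochord": 0.8387,
            "Yolk/YolkExtension": 0.1060, "MidTrunk/AboveYolk": 0.9966,
            "Muscle": 0.0051, "TailRegion": 0.2205,
        },
        "significant": {"Muscle"},
        "ratios": {"Muscle": 3.8},
    },
}

# Cohort-level counts from the screen and its companion noncoding screen.
COHORT_COUNTS = {
    "cce_active": (24, 31),           # constructs driving clear expression
    "cne_active": (105, 147),
    "cce_specific": (14, 24),         # anatomy-specific among active
    "cne_specific": (50, 105),
    "cce_h3k4me1": (9, 24),           # active constructs with an H3K4me1 mark
    "cne_h3k4me1": (34, 81),
    "host_other_exons_h3k4me1": (37, 358),
    "exons_genomewide_h3k4me1": (8874, 110461),
    "dev_gene_exons_h3k4me1": (942, 6741),
    "dev_genes_marked_exon": (517, 813),
    "genes_marked_exon": (6362, 13588),
    "p300_peaks_on_ccds": (172, 5118),
    "tf_bound_exons": (24095, 326254),
    "host_overlap": (12, 20),         # activity overlapping host-gene expression
    "upstream_overlap": (4, 20),
    "downstream_overlap": (2, 20),
}

#: Reported permutation-null summary for 100 random sets of 20 genes.
RANDOM_GENE_NULL = {"mean": 3.6, "sd": 1.8, "n_iter": 100, "n_genes": 20}


def table1_frame() -> pd.DataFrame:
    """Tidy frame of the example expression table: one row per
    (construct, anatomy) with proportion, both p-values, significance mark
    and printed fold ratio (NaN where unmarked)."""
    rows = []
    for construct, entry in CCES.items():
        for anatomy in ANATOMIES:
            rows.append(
                {
                    "construct_id": construct,
                    "anatomy": anatomy,
                    "n": entry["n"],
                    "p_hat": entry["proportions"][anatomy],
                    "p_control": CONTROL_PROPORTIONS[anatomy],
                    "n_control": CONTROL_N,
                    "p_prop": entry["p_prop"][anatomy],
                    "p_ranksum": entry["p_ranksum"][anatomy],
                    "marked": anatomy in entry["significant"],
                    "ratio": entry["ratios"].get(anatomy, float("nan")),
                }
            )
    return pd.DataFrame(rows)
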