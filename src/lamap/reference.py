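"""Reference cohort parameters for the Atp7b-null (Wilson's disease model) study.

Regional wet-weight concentrations (mean, SD in μg g⁻¹) of Fe, Cu, Zn and Mn
measured by LA-ICP-MS in control and Atp7b⁻/⁻ ("WD") mouse brains.  These
values parameterize the synthetic phantom cohorts: per-animal truths are drawn
from the group mean ± SD of each region × element cell.

The three periventricular regions were reported for Cu only; Fe/Zn/Mn there
are filled from the entire-section values when a complete simulator
parameterization is requested (see :func:`lamap.phantom.default_group_params`).
"""

from __future__ import annotations

ELEMENTS = ("Fe", "Cu", "Zn", "Mn")

CONTROL_N = 8
WD_N = 9

GROUPS = ("control", "wd")

# region -> element -> {"control": (mean, sd), "wd": (mean, sd)}
LARGE_REGION_PARAMS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "cortex": {
        "Fe": {"control": (12.4, 2.2), "wd": (12.1, 0.8)},
        "Cu": {"control": (2.7, 0.7), "wd": (5.5, 1.2)},
        "Zn": {"control": (13.9, 3.0), "wd": (17.7, 0.8)},
        "Mn": {"control": (0.23, 0.06), "wd": (0.26, 0.04)},
    },
    "corpus_callosum": {
        "Fe": {"control": (7.8, 1.1), "wd": (7.6, 0.6)},
        "Cu": {"control": (1.5, 0.5), "wd": (2.9, 0.8)},
        "Zn": {"control": (8.2, 2.1), "wd": (9.5, 1.4)},
        "Mn": {"control": (0.11, 0.03), "wd": (0.13, 0.04)},
    },
    "cerebellum_cu_rich": {
        "Fe": {"control": (17.4, 3.8), "wd": (17.4, 2.1)},
        "Cu": {"control": (6.6, 1.6), "wd": (10.9, 1.7)},
        "Zn": {"control": (13.0, 2.9), "wd": (16.0, 2.0)},
        "Mn": {"control": (0.28, 0.09), "wd": (0.28, 0.04)},
    },
    "cerebellum_cu_poor": {
        "Fe": {"control": (17.8, 3.5), "wd": (16.3, 3.8)},
        "Cu": {"control": (3.8, 0.9), "wd": (7.5, 1.6)},
        "Zn": {"control": (12.3, 2.7), "wd": (13.8, 3.1)},
        "Mn": {"control": (0.30, 0.08), "wd": (0.27, 0.06)},
    },
    "cerebellar_white_matter": {
        "Fe": {"control": (8.4, 1.9), "wd": (6.9, 1.9)},
        "Cu": {"control": (1.7, 0.3), "wd": (4.0, 1.2)},
        "Zn": {"control": (6.8, 1.4), "wd": (7.9, 1.2)},
        "Mn": {"control": (0.15, 0.04), "wd": (0.13, 0.06)},
    },
    "colliculus_superior": {
        "Fe": {"control": (13.8, 2.2), "wd": (13.3, 1.1)},
        "Cu": {"control": (3.3, 0.7), "wd": (6.1, 0.5)},
        "Zn": {"control": (9.8, 2.0), "wd": (11.4, 0.4)},
        "Mn": {"control": (0.31, 0.07), "wd": (0.34, 0.07)},
    },
    "colliculus_inferior": {
        "Fe": {"control": (15.7, 3.4), "wd": (12.1, 1.5)},
        "Cu": {"control": (3.6, 0.9), "wd": (5.4, 0.7)},
        "Zn": {"control": (9.5, 2.1), "wd": (11.2, 1.7)},
        "Mn": {"control": (0.36, 0.10), "wd": (0.35, 0.09)},
    },
    "lateral_ventricles": {
        "Cu": {"control": (39.0, 17.0), "wd": (17.0, 3.0)},
    },
    "third_ventricle": {
        "Cu": {"control": (50.0, 28.0), "wd": (22.0, 4.0)},
    },
    "fourth_ventricle": {
        "Cu": {"control": (67.0, 22.0), "wd": (19.0, 5.0)},
    },
}

HIPPOCAMPAL_PARAMS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "moleculare": {
        "Fe": {"control": (13.1, 2.1), "wd": (14.6, 1.2)},
        "Cu": {"control": (5.2, 1.2), "wd": (8.9, 1.2)},
        "Zn": {"control": (14.0, 3.7), "wd": (19.4, 1.3)},
        "Mn": {"control": (0.34, 0.10), "wd": (0.32, 0.07)},
    },
    "granulare": {
        "Fe": {"control": (18.4, 3.4), "wd": (16.3, 2.1)},
        "Cu": {"control": (4.1, 1.1), "wd": (7.6, 1.0)},
        "Zn": {"control": (25.0, 7.0), "wd": (32.0, 3.0)},
        "Mn": {"control": (0.39, 0.14), "wd": (0.39, 0.09)},
    },
    "multiforme": {
        "Fe": {"control": (12.9, 1.7), "wd": (13.2, 0.8)},
        "Cu": {"control": (4.1, 1.2), "wd": (8.0, 1.5)},
        "Zn": {"control": (47.0, 14.0), "wd": (59.0, 9.0)},
        "Mn": {"control": (0.48, 0.28), "wd": (0.48, 0.14)},
    },
    "oriens": {
        "Fe": {"control": (10.8, 1.2), "wd": (10.6, 1.0)},
        "Cu": {"control": (3.8, 0.8), "wd": (6.6, 1.4)},
        "Zn": {"control": (18.0, 4.0), "wd": (20.8, 3.8)},
        "Mn": {"control": (0.26, 0.06), "wd": (0.32, 0.08)},
    },
    "ca3": {
        "Fe": {"control": (11.3, 1.9), "wd": (12.3, 1.4)},
        "Cu": {"control": (4.6, 1.4), "wd": (7.0, 1.2)},
        "Zn": {"control": (33.0, 10.0), "wd": (38.0, 5.5)},
        "Mn": {"control": (0.45, 0.20), "wd": (0.48, 0.13)},
    },
    "ca1_2": {
        "Fe": {"control": (19.0, 3.7), "wd": (15.1, 1.5)},
        "Cu": {"control": (3.5, 1.0), "wd": (5.9, 0.9)},
        "Zn": {"control": (20.9, 4.8), "wd": (24.4, 3.4)},
        "Mn": {"control": (0.27, 0.07), "wd": (0.33, 0.06)},
    },
    "radiatum": {
        "Fe": {"control": (10.5, 1.5), "wd": (10.2, 0.7)},
        "Cu": {"control": (3.2, 0.8), "wd": (6.3, 1.2)},
        "Zn": {"control": (21.8, 4.9), "wd": (23.8, 3.0)},
        "Mn": {"control": (0.25, 0.06), "wd": (0.31, 0.08)},
    },
    "lacunosum_moleculare": {
        "Fe": {"control": (12.8, 2.1), "wd": (12.2, 1.3)},
        "Cu": {"control": (3.6, 0.9), "wd": (5.6, 1.0)},
        "Zn": {"control": (14.1, 3.7), "wd": (18.4, 1.5)},
        "Mn": {"control": (0.28, 0.08), "wd": (0.29, 0.06)},
    },
    "subiculum": {
        "Fe": {"control": (14.4, 2.3), "wd": (12.9, 1.4)},
        "Cu": {"control": (3.4, 0.9), "wd": (5.9, 1.1)},
        "Zn": {"control": (15.4, 4.1), "wd": (17.4, 1.6)},
        "Mn": {"control": (0.23, 0.06), "wd": (0.27, 0.03)},
    },
    "praesubiculum": {
        "Fe": {"control": (13.9, 3.2), "wd": (13.8, 1.5)},
        "Cu": {"control": (4.8, 1.4), "wd": (7.8, 1.4)},
        "Zn": {"control": (13.1, 3.0), "wd": (16.3, 1.0)},
        "Mn": {"control": (0.23, 0.07), "wd": (0.26, 0.05)},
    },
}

# Whole-section averages; used to fill the unreported periventricular
# Fe/Zn/Mn cells in the simulator defaults.
ENTIRE_SECTION_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "Fe": {"control": (14.1, 2.5), "wd": (14.1, 1.0)},
    "Cu": {"control": (4.2, 1.4), "wd": (6.7, 1.5)},
    "Zn": {"control": (13.2, 3.1), "wd": (15.8, 1.7)},
    "Mn": {"control": (0.25, 0.07), "wd": (0.26, 0.05)},
}

REGION_PARAMS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    **LARGE_REGION_PARAMS,
    **HIPPOCAMPAL_PARAMS,
}

PERIVENTRICULAR_REGIONS = ("lateral_ventricles", "third_ventricle", "fourth_ventricle")

# 21 regions of the default multiple-testing family: 20 drawn regions
# plus the entire section.
N_FAMILY_REGIONS = 21
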