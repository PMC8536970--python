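"""Bundled reference fixtures.

Small plain-data tables used in examples and tests, kept in-source so
the package works fully offline.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["reference_loadings", "REFERENCE_ENV_VARIABLES", "REFERENCE_SELECTION_AXES", "REFERENCE_DISPERSAL_AXES"]

#: Environmental rows of the reference loading table.
REFERENCE_ENV_VARIABLES = ["Moisture", "NH4", "ORP", "pH", "TN", "TOC"]

#: Axes retained by betaNTI model selection in the reference analysis.
REFERENCE_SELECTION_AXES = ["PC2", "PC24", "PC8"]

#: Axes retained by RC_bray (but not betaNTI) model selection.
REFERENCE_DISPERSAL_AXES = ["PC9", "PC5", "PC11"]

_LOADINGS = {
    #            PC2      PC24     PC8      PC9      PC5      PC11
    "Moisture": (-0.1060, -0.0086,  0.0457, -0.0512, -0.7764, -0.0177),
    "NH4":      (-0.6505,  0.0077, -0.0378, -0.0210,  0.3524,  0.0147),
    "ORP":      (-0.1505, -0.0074, -0.0674, -0.0279, -0.3272, -0.0171),
    "pH":       (-0.7301,  0.0036, -0.0538,  0.0329, -0.1329,  0.0037),
    "TN":       (-0.0044,  0.0097, -0.2756, -0.0019, -0.0968, -0.0316),
    "TOC":      (-0.0033, -0.0055,  0.3042, -0.0048,  0.3193,  0.0386),
    "OTU1":     (-0.0339, -0.1206,  0.5251,  0.3698, -0.1035, -0.0057),
    "OTU1764":  ( 0.0034,  0.2667, -0.0029, -0.0150, -0.0196,  0.0396),
    "OTU18":    ( 0.0327,  0.1811, -0.1745,  0.1694, -0.0149, -0.2999),
    "OTU1866":  (-0.0083,  0.2450,  0.0360,  0.0331, -0.0024, -0.0653),
    "OTU209":   ( 0.0139, -0.0688, -0.1956,  0.2805,  0.0142,  0.1885),
    "OTU4":     ( 0.0177, -0.0827, -0.0212, -0.5950, -0.0233, -0.0096),
    "OTU44":    ( 0.0207, -0.0469, -0.2507,  0.0377,  0.0344, -0.4426),
    "OTU47":    ( 0.0132, -0.3834, -0.1244,  0.1284,  0.0185, -0.2602),
    "OTU890":   (-0.0058, -0.0061, -0.0207,  0.0891,  0.0257, -0.2895),
}


def reference_loadings() -> pd.DataFrame:
    """Published retained-axis loading table from a benthic sediment study.

    Six sediment chemistry variables and nine keystone OTUs against the
    six PCA axes retained by betaNTI / RC_bray model selection; used as
    a fixed input for driver-attribution examples and tests.
    """
    axes = REFERENCE_SELECTION_AXES + REFERENCE_DISPERSAL_AXES
    return pd.DataFrame.from_dict(_LOADINGS, orient="index", columns=axes)
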