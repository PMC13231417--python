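"""Published reference values for the BNT141/BNT142/mRNA-1944 programs.

These are the printed multispecies estimates and observed-vs-predicted
human exposure comparisons for three intravenously administered mRNA-LNP
products encoding antibodies: BNT141 (RiboMab01, full IgG1), BNT142
(RiboMab02.1, bispecific Fab-scFv T-cell engager) and mRNA-1944 (CHKV-24,
full IgG1).  They serve as default parameter sets, as generating values
for synthetic studies, and as inputs to the report workflows.
"""

from __future__ import annotations

from .kinetics import ScalingConfig, TranslationalParams

__all__ = [
    "RIBOMAB01_PARAMS",
    "RIBOMAB02_PARAMS",
    "PARAM_RSE_PCT",
    "MULTISPECIES_EXPONENTS",
    "GENERALIZED_EXPONENTS",
    "GRID_RANGES",
    "SCALING_FROM_MOUSE",
    "SCALING_FROM_NHP",
    "ALLOMETRY_COMPARISON",
    "MODEL_COMPARISON",
]

#: Multispecies translational-model estimates for RiboMab01 (BNT141):
#: 2-compartment antibody disposition, V1/V2 fixed to the reference-protein
#: (zolbetuximab) estimates, volume exponents fixed at 1.
RIBOMAB01_PARAMS = TranslationalParams(
    k_elim_mrna=0.041, alpha_k_elim=-0.14,
    k_translate=0.27, alpha_k_translate=-0.43,
    cl_ab=0.28, alpha_cl=0.79,
    v1=40.1, alpha_v1=1.0,
    v2=45.6, alpha_v2=1.0,
    q_ab=1.02, alpha_q=1.03,
)

#: Multispecies estimates for RiboMab02.1 (BNT142): only one elimination
#: phase was observed, so disposition is 1-compartment (no V2/Q).
RIBOMAB02_PARAMS = TranslationalParams(
    k_elim_mrna=0.0282, alpha_k_elim=-0.042,
    k_translate=0.043, alpha_k_translate=-0.59,
    cl_ab=7.68, alpha_cl=0.80,
    v1=58.4, alpha_v1=1.0,
)

#: Reported relative standard errors (%) of the estimates above; fixed
#: parameters carry None.
PARAM_RSE_PCT = {
    "ribomab01": {
        "k_elim_mrna": 13, "alpha_k_elim": 42,
        "k_translate": 12, "alpha_k_translate": 8,
        "cl_ab": 10, "alpha_cl": 5,
        "v1": None, "alpha_v1": None, "v2": None, "alpha_v2": None,
        "q_ab": 17, "alpha_q": 21,
    },
    "ribomab02": {
        "k_elim_mrna": 2, "alpha_k_elim": 13,
        "k_translate": 19, "alpha_k_translate": 8,
        "cl_ab": 21, "alpha_cl": 6,
        "v1": None, "alpha_v1": None,
    },
}

#: Multispecies log-log regression exponents of dose-normalized exposure.
MULTISPECIES_EXPONENTS = {
    "bnt141": {"dcmax": -1.29, "dauc": -1.13},
    "bnt142": {"dcmax": -1.42, "dauc": -1.38},
}

#: Generalized single-species exponents for human exposure prediction.
GENERALIZED_EXPONENTS = {"mouse": -1.26, "nhp": -0.75}

#: Exponent ranges explored when selecting the generalized exponents.
GRID_RANGES = {"mouse": (-1.3, -1.0), "nhp": (-0.9, -0.6)}

#: Projection exponents for single-species translational-model scaling.
#: From mouse the translation rate is scaled with the cross-program average
#: exponent (−0.51); from NHP it is left unadjusted (exponent 0) because
#: translational efficiency is comparable between NHP and human.
SCALING_FROM_MOUSE = ScalingConfig(
    exponents={"k_elim_mrna": -0.10, "k_translate": -0.51, "cl_ab": 0.80,
               "v1": 1.0, "v2": 1.0, "q_ab": 0.65},
    source_species="mouse",
)
SCALING_FROM_NHP = ScalingConfig(
    exponents={"k_elim_mrna": -0.10, "k_translate": 0.0, "cl_ab": 0.80,
               "v1": 1.0, "v2": 1.0, "q_ab": 0.65},
    source_species="nhp",
)

#: Observed human exposure vs allometric single-species predictions
#: (generalized exponents −1.26 from mouse, −0.75 from NHP).
#: rows: (compound, parameter, observed, predicted_from_mouse, predicted_from_nhp);
#: DCmax in 1/mL, DAUC in h/mL; None where no source data exist.
ALLOMETRY_COMPARISON = [
    ("bnt141", "dcmax", 6.96e-4, 5.72e-4, 1.15e-3),
    ("bnt141", "dauc", 0.28, 0.063, 0.18),
    ("bnt142", "dcmax", 1.93e-5, 5.70e-5, 2.23e-5),
    ("bnt142", "dauc", 1.29e-3, 2.6e-3, 1.10e-3),
    ("mrna-1944", "dcmax", 3.02e-4, None, 5.23e-4),
    ("mrna-1944", "dauc", 0.42, None, 0.19),
]

#: Observed human exposure vs translational-model single-species projections.
MODEL_COMPARISON = [
    ("bnt141", "dauc", 0.28, 0.078, 0.33),
    ("bnt141", "dcmax", 6.96e-4, 2.13e-4, 8.00e-4),
    ("bnt142", "dauc", 0.0013, 0.0035, 0.0012),
    ("bnt142", "dcmax", 1.93e-5, 3.63e-5, 1.45e-5),
    ("mrna-1944", "dauc", 0.42, None, 0.28),
    ("mrna-1944", "dcmax", 3.02e-4, None, 2.23e-4),
]
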