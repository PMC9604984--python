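"""Named positive parameter sets for the kinetic model.

The default schema for the full TNFa network has 81 entries: 34 basal
interconversion rates (one activation and one deactivation rate per
entity), 26 edge rate-law constants across 14 mass-action, 10
Michaelis-Menten and 1 Hill interaction, 2 stimulus coupling constants,
3 marker scaling constants and 5 inhibitor constants.

Units: concentrations are dimensionless fractions of each entity's total
(inactive + active = 1), time is hours, stimulus couplings are per dose
unit (ng/ml for TNFa, nM for TPL) per hour, and inhibitor constants are
nM^-1 as printed.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

__all__ = ["ParameterSet", "default_truth", "INHIBITOR_CONSTANTS"]

#: phenomenological inhibitor constants (nM^-1)
INHIBITOR_CONSTANTS = {
    "Ki_wort_PI3K_AKT": 0.001,
    "Ki_wort_MKK47_JNK": 0.02,
    "Ki_wort_NFkB_XG": 0.00005,
    "Ki_sp6_Bcl2_AKT": 0.0002,
    "Ki_sp6_MKK47_JNK": 0.005,
}


class ParameterSet(dict):
    """An ordered mapping of strictly positive named parameters.

    Behaves as a plain dict; ``id`` tags the set (used by fit results and
    trajectory provenance).
    """

    def __init__(self, values: Mapping[str, float], id: str = ""):
        for name, v in values.items():
            if not v > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {v}")
        super().__init__(values)
        self.id = id

    def replace(self, updates: Mapping[str, float], id: str | None = None) -> "ParameterSet":
        merged = dict(self)
        merged.update(updates)
        return ParameterSet(merged, id=self.id if id is None else id)

    def to_array(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self[n] for n in names], dtype=float)

    def from_array(self, names: Iterable[str], values: np.ndarray,
                   id: str | None = None) -> "ParameterSet":
        return self.replace(dict(zip(names, map(float, values))), id=id)


# Ground-truth parameter values for the default network.  These define the
# synthetic study conditions: with a 100 ng/ml TNFa stimulus NFkB rises and
# holds Caspase3 near its resting level; arresting NFkB with 60 nM TPL
# de-represses the apoptotic arm so Caspase3 climbs in the late phase.
# Scaling constants equal the reciprocal resting active levels of the three
# markers, so fold change is exactly 1 at the unstimulated steady state
# (values below are frozen from a converged pre-equilibration).
_TRUTH = {
    # basal activation / deactivation (h^-1)
    "k_act_TNFR1": 0.02, "k_inact_TNFR1": 1.0,
    "k_act_NFkB": 0.4, "k_inact_NFkB": 0.5,
    "k_act_PTEN": 0.5, "k_inact_PTEN": 0.5,
    "k_act_PI3K": 0.4, "k_inact_PI3K": 0.6,
    "k_act_AKT": 0.3, "k_inact_AKT": 0.8,
    "k_act_Bcl2": 0.4, "k_inact_Bcl2": 0.5,
    "k_act_XG": 0.03, "k_inact_XG": 0.15,
    "k_act_Ceramide": 0.05, "k_inact_Ceramide": 0.4,
    "k_act_C1P": 0.05, "k_inact_C1P": 0.5,
    "k_act_CAPP": 0.05, "k_inact_CAPP": 0.25,
    "k_act_MKK47": 0.2, "k_inact_MKK47": 0.6,
    "k_act_ROS": 0.1, "k_inact_ROS": 0.8,
    "k_act_JNK": 0.2, "k_inact_JNK": 0.9,
    "k_act_RAF": 0.1, "k_inact_RAF": 0.7,
    "k_act_ERK12": 0.2, "k_inact_ERK12": 0.8,
    "k_act_Casp8": 0.02, "k_inact_Casp8": 0.3,
    "k_act_Casp3": 0.02, "k_inact_Casp3": 0.05,
    # mass-action edges (h^-1, bilinear in the two species fractions)
    "k_TNFR1_NFkB": 3.0,
    "k_TNFR1_PI3K": 1.5,
    "k_TNFR1_Ceramide": 2.0,
    "k_TNFR1_RAF": 1.0,
    "k_TNFR1_Casp8": 0.25,
    "k_Ceramide_C1P": 2.0,
    "k_Ceramide_CAPP": 1.0,
    "k_C1P_JNK": 2.0,
    "k_JNK_ROS": 1.2,
    "k_ROS_MKK47": 2.0,
    "k_RAF_ERK12": 2.0,
    "k_ERK12_JNK": 1.5,
    "k_XG_JNK": 2.5,
    "k_Casp8_Casp3": 0.15,
    # Michaelis-Menten edges (Vmax h^-1, Km fraction)
    "V_NFkB_PTEN": 2.5, "Km_NFkB_PTEN": 0.3,
    "V_NFkB_XG": 0.8, "Km_NFkB_XG": 0.3,
    "V_NFkB_Bcl2": 2.5, "Km_NFkB_Bcl2": 0.3,
    "V_AKT_Casp3": 1.6, "Km_AKT_Casp3": 0.3,
    "V_PTEN_PI3K": 3.0, "Km_PTEN_PI3K": 0.3,
    "V_PI3K_AKT": 3.0, "Km_PI3K_AKT": 0.4,
    "V_Bcl2_AKT": 0.4, "Km_Bcl2_AKT": 0.4,
    "V_JNK_AKT": 0.4, "Km_JNK_AKT": 0.4,
    "V_CAPP_AKT": 1.8, "Km_CAPP_AKT": 0.4,
    "V_MKK47_JNK": 1.5, "Km_MKK47_JNK": 0.4,
    # Hill edge
    "V_JNK_Casp3": 0.3, "Km_JNK_Casp3": 0.45, "n_JNK_Casp3": 2.0,
    # stimulus couplings
    "k_stim_tnfa": 0.04,  # (ng/ml)^-1 h^-1
    "k_stim_tpl": 0.25,   # nM^-1 h^-1
    # marker scaling constants (set to 1/baseline; frozen, see module doc)
    "s_pAKT": np.float64(2.5785182975385568),
    "s_pJNK": np.float64(2.802107851399376),
    "s_Casp3": np.float64(14.983237932500078),
}
_TRUTH.update(INHIBITOR_CONSTANTS)


def default_truth() -> ParameterSet:
    """Ground-truth parameter set used by the synthetic-data generator."""
    return ParameterSet(dict(_TRUTH), id="truth")
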