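"""Canonical recording conditions: emission levels, rate constants, designs.

Emission levels derive from the reported residual-current percentages of the
four conformational levels together with the open-pore current
I_O = -433.3 pA (I = I_RES/100 * I_O):

    M   46.0 %  -> -199.3 pA (fully open)
    M1  48.7 %  -> -211.0 pA (NMP closed)
    M2  51.0 %  -> -221.0 pA (LID closed)
    M3  53.8 %  -> -233.1 pA (both closed)
    M0          -> -180.0 pA (sporadic shallow excursions)

The reference rate vector is anchored to the directly measured kinetic
constants (M2 association 2.2 uM^-1 s^-1; binary-complex LID opening
693.4 s^-1; apo NMP closing/opening 4.66/55.2 s^-1; NMP closing 200 s^-1;
M3 exit 3.4e3 s^-1) with the remaining rates chosen so that the simulated
aggregate kinetics reproduce the reported aggregate LID closing rate of
~1000 s^-1 at 1 mM ATP and ternary LID opening of ~120 s^-1 at 1 mM ATP +
1 mM AMP.
"""

from __future__ import annotations

from .kinetic_model import LigandConcentrations, RateVector

__all__ = [
    "OPEN_PORE_PA",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_GROUP_SIGMAS",
    "REFERENCE_RATES",
    "ATP_AMP_CONDITIONS",
    "ADP_CONDITIONS_MM",
    "default_emission_model",
]

OPEN_PORE_PA = -433.3

DEFAULT_GROUP_MEANS = {
    "M0": -180.0,
    "M": -199.3,
    "M1": -211.0,
    "M2": -221.0,
    "M3": -233.1,
}

DEFAULT_GROUP_SIGMAS = {g: 8.0 for g in DEFAULT_GROUP_MEANS}

# Frozen reference rates (s^-1; k1/k2 in s^-1 mM^-1).
REFERENCE_RATES = RateVector(
    c1=100.0, c2=100.0, c3=100.0, c4=100.0,
    c_m1=2.0, c_m2=2.0, c_m3=2.0, c_m4=2.0,
    k1=2200.0, k_m1=300.0,
    k2=3000.0, k_m2=300.0,
    b1=4.66, b_m1=55.2,
    b2=200.0, b_m2=3400.0,
    r1=1300.0, r_m1=693.4,
    r3=2000.0, r_m3=50.0,
    r4=1000.0, r_m4=25.0,
)

# The six ATP/AMP concentration pairs of the estimation design (mM).
ATP_AMP_CONDITIONS = (
    (0.01, 0.00),
    (0.10, 0.00),
    (1.00, 0.00),
    (1.00, 0.01),
    (1.00, 0.10),
    (1.00, 1.00),
)

# The seven ADP concentrations of the estimation design (mM).
ADP_CONDITIONS_MM = (0.01, 0.02, 0.05, 0.10, 0.20, 0.50, 1.00)


def default_emission_model():
    from .hmm_core import EmissionModel

    return EmissionModel(dict(DEFAULT_GROUP_MEANS), dict(DEFAULT_GROUP_SIGMAS))


def atp_amp_concentrations() -> list[LigandConcentrations]:
    return [LigandConcentrations(atp_mM=a, amp_mM=b) for a, b in ATP_AMP_CONDITIONS]


def adp_concentrations() -> list[LigandConcentrations]:
    return [LigandConcentrations(adp_mM=c) for c in ADP_CONDITIONS_MM]
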