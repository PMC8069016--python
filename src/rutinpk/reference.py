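"""Final published population models for the rat studies.

These are the estimated population parameters for (a) rutin after an IV
bolus of the pure compound or of *Physalis peruviana* calyx extract and
(b) total quercetin conjugates (Q3OG + Q3OS, measured as quercetin after
deconjugation) after oral dosing.  They serve two purposes: as the
generating models for the synthetic-study module and as a worked reference
for the estimation machinery.

Covariate coding
----------------
IV axis ``source``: reference ``RU`` (pure rutin, pooled doses) vs ``GEXT``
(extract matrix).  Oral axis ``dose_group``: reference ``D100`` (pure rutin
100 mg/kg) vs ``D75`` (pure rutin 75 mg/kg) and the extract doses ``D500``,
``D750``, ``D1000`` (mg/kg of extract; administered amounts are the
rutin-equivalents).
"""

from __future__ import annotations

from .population import (
    CovariateEffect,
    PopulationModel,
    RandomEffectsSpec,
    ResidualErrorModel,
)

__all__ = ["iv_reference_model", "oral_reference_model"]


def iv_reference_model() -> PopulationModel:
    """Final IV two-compartment model for rutin (V logit-normal, rates
    lognormal; combined residual error, correlated eta_V/eta_k)."""
    return PopulationModel(
        structural="iv",
        fixed_effects={"V": 0.0646, "k": 1.47, "k12": 2.6, "k21": 13.6},
        covariate_axis="source",
        levels=("RU", "GEXT"),
        effects=(
            CovariateEffect("V", "GEXT", 0.478),
            CovariateEffect("k", "GEXT", 0.395),
        ),
        random_effects=RandomEffectsSpec(
            sd={"V": 0.306, "k": 0.147},
            corr={("V", "k"): -0.701},
        ),
        error=ResidualErrorModel(a=38.9, b=0.128),
    )


def oral_reference_model() -> PopulationModel:
    """Final oral double-absorption model for quercetin conjugates.

    Dose-group covariates act on ka1, Tlag2, V and k; random effects on
    ka1, ka2, F1 and V only (no correlations)."""
    return PopulationModel(
        structural="oral",
        fixed_effects={
            "ka1": 0.104, "ka2": 0.411, "F1": 0.565, "Tlag2": 3.91,
            "V": 13.2, "k": 1.42, "k12": 0.279, "k21": 0.268,
        },
        covariate_axis="dose_group",
        levels=("D100", "D75", "D500", "D750", "D1000"),
        effects=(
            CovariateEffect("ka1", "D75", 0.281),
            CovariateEffect("ka1", "D500", 1.94),
            CovariateEffect("ka1", "D750", 3.15),
            CovariateEffect("ka1", "D1000", 3.77),
            CovariateEffect("Tlag2", "D75", -0.0177),
            CovariateEffect("Tlag2", "D500", 0.149),
            CovariateEffect("Tlag2", "D750", -0.695),
            CovariateEffect("Tlag2", "D1000", -1.17),
            CovariateEffect("V", "D75", 0.251),
            CovariateEffect("V", "D500", -0.645),
            CovariateEffect("V", "D750", 0.245),
            CovariateEffect("V", "D1000", 1.09),
            CovariateEffect("k", "D75", -0.225),
            CovariateEffect("k", "D500", -1.3),
            CovariateEffect("k", "D750", -2.13),
            CovariateEffect("k", "D1000", -3.57),
        ),
        random_effects=RandomEffectsSpec(
            sd={"ka1": 0.189, "ka2": 0.236, "F1": 0.214, "V": 0.0819},
        ),
        error=ResidualErrorModel(a=8.87, b=0.0457),
    )
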