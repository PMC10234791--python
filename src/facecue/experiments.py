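"""Replicated simulation experiments over the model pipeline.

Two canned experiments support validity claims about the analysis:

* :func:`null_calibration` — with the generator's dimorphism effects at
  zero, the focal dimorphism test should reject at the nominal alpha
  level and its Bayes factors should typically favour the null.
* :func:`recovery_experiment` — a known true standardized effect
  injected by the generator should be recovered, on average, by the
  fitted standardized beta.

Both use the generator's fast tabular path (the statistical equivalent
of the landmark pipeline; see :func:`facecue.simulate
.simulate_analysis_table`) so thousands of replicates stay cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import AnalysisConfig, PaternalInvolvementModel
from .simulate import GeneratorConfig, simulate_analysis_table

__all__ = ["null_calibration", "recovery_experiment"]


def _child_rngs(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def null_calibration(
    n_replicates: int = 2000,
    seed: int = 0,
    cfg: GeneratorConfig | None = None,
    outcome: str = "nfs",
    predictor: str = "objective_dimorphism",
) -> pd.DataFrame:
    """p value and BF10 of the focal dimorphism effect per replicate.

    The default generator has zero true dimorphism effects, so the
    returned p values should be uniform (5% below .05) and the median
    BF10 should fall below 1.
    """
    cfg = cfg or GeneratorConfig()
    acfg = AnalysisConfig(
        samples=("full",), predictors=(predictor,), outcomes=(outcome,)
    )
    rows = []
    for ss in _child_rngs(seed, n_replicates):
        tab = simulate_analysis_table(cfg, np.random.default_rng(ss))
        res = PaternalInvolvementModel(tab, acfg).fit()
        focal = res.effects[res.effects["predictor"] == predictor].iloc[0]
        rows.append((focal["beta"], focal["p"], focal["bf10"]))
    return pd.DataFrame(rows, columns=["beta", "p", "bf10"])


def recovery_experiment(
    true_beta: float = -0.44,
    n_replicates: int = 200,
    seed: int = 0,
    cfg: GeneratorConfig | None = None,
    outcome: str = "perceived_paternal_involvement",
    effect_predictor: str = "attractiveness",
) -> np.ndarray:
    """Fitted standardized betas for a known injected effect.

    By default the attractiveness -> perceived-involvement effect is
    set to ``true_beta`` and the fitted attractiveness coefficient from
    the dimorphism model (focal predictor + attractiveness covariate)
    is collected per replicate.
    """
    cfg = (cfg or GeneratorConfig()).with_(
        true_effects={(outcome, effect_predictor): true_beta}
    )
    acfg = AnalysisConfig(
        samples=("full",),
        predictors=("objective_dimorphism",),
        outcomes=(outcome,),
    )
    betas = []
    for ss in _child_rngs(seed, n_replicates):
        tab = simulate_analysis_table(cfg, np.random.default_rng(ss))
        res = PaternalInvolvementModel(tab, acfg).fit()
        row = res.effects[res.effects["predictor"] == effect_predictor].iloc[0]
        betas.append(row["beta"])
    return np.asarray(betas)
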