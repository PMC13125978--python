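"""Parameter-based transfer learning for the parametric engine.

The pretrained 26-parameter vector initializes a derivative-free local
optimization whose objective is the 5-year integrated calibration index on
the target cohort; the result is a fine-tuned vector of the same shape.
Records that are invalid under the mandatory-input rule contribute nothing
to the objective (validity depends only on missingness, never on the
parameter values, so the excluded subset is constant across evaluations).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import optimize

from .cohort import Cohort
from .engine import AssumptionScenario, ParamVector, apply_assumptions, \
    _predict_frame, make_scenario
from .metrics import ici

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FinetuneConfig:
    optimizer: str = "nelder_mead"     # or "powell"
    max_iter: int = 2000
    tol: float = 1e-5
    bounds: list[tuple[float, float]] | None = None
    runs_to_average: int = 10

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.optimizer not in ("nelder_mead", "powell"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def ici_objective(params: ParamVector, cohort: Cohort,
                  scenario: AssumptionScenario | None = None,
                  _filled=None) -> float:
    """ICI of the engine's 5-year predictions over the valid subset."""
    scenario = scenario or make_scenario()
    df = _filled if _filled is not None else apply_assumptions(cohort.df, scenario)
    p, invalid, _ = _predict_frame(df, params)
    if invalid.all():
        raise ValueError("all predictions invalid under this cohort")
    return float(ici(p, cohort).point)


def finetune(params0: ParamVector, cohort: Cohort,
             cfg: FinetuneConfig | None = None,
             scenario: AssumptionScenario | None = None) -> ParamVector:
    """Local re-estimation of the 26 parameters, initialized at ``params0``.

    Guaranteed not to end worse than the initialization: if the optimizer
    fails or drifts, the better of (initial, optimized) is returned, with a
    warning flag in the log for the failure case.
    """
    cfg = cfg or FinetuneConfig()
    scenario = scenario or make_scenario()
    filled = apply_assumptions(cohort.df, scenario)
    trace: list[float] = []

    def objective(values: np.ndarray) -> float:
        val = ici_objective(params0.replace_values(values), cohort, scenario,
                            _filled=filled)
        trace.append(val)
        return val

    f0 = objective(params0.values)
    method = {"nelder_mead": "Nelder-Mead", "powell": "Powell"}[cfg.optimizer]
    try:
        options = {"maxiter": cfg.max_iter, "maxfev": cfg.max_iter}
        if cfg.optimizer == "nelder_mead":
            options.update(fatol=cfg.tol, xatol=1e-4)
        else:
            options.update(ftol=cfg.tol, xtol=1e-4)
        res = optimize.minimize(
            objective, params0.values.copy(), method=method,
            bounds=cfg.bounds, options=options)
        values, f1 = res.x, float(res.fun)
    except Exception as exc:   # optimizer failure -> keep the initialization
        logger.warning("finetune: optimizer failed (%s); returning params0", exc)
        return params0
    logger.info("finetune: %d evaluations, objective %.6f -> %.6f",
                len(trace), f0, f1)
    if f1 > f0 + cfg.tol:
        logger.warning("finetune: optimizer did not improve the objective; "
                       "returning params0")
        return params0
    return params0.replace_values(values)


def average_param_vectors(vectors: list[ParamVector]) -> ParamVector:
    """Element-wise arithmetic mean of fine-tuned vectors (same names/order)."""
    if not vectors:
        raise ValueError("need at least one vector")
    ref = vectors[0]
    for v in vectors[1:]:
        if v.names != ref.names:
            raise ValueError("parameter vectors have mismatched names/order")
    mean = np.mean([v.values for v in vectors], axis=0)
    return ref.replace_values(mean)
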