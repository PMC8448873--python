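"""Model fitting entry points and the mass-univariate decision table."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import (
    ModelSpec,
    beta_ispc_model,
    ordinal_familiarity_model,
    student_t_pleasantness_model,
)
from .sampler import SamplerConfig, sample_posterior
from .summary import (
    NONZERO,
    ParameterSummary,
    PosteriorSummary,
    posthoc_contrasts,
    summarize_parameter,
)

__all__ = [
    "familiarity_long_format",
    "fit_ordinal_familiarity",
    "fit_student_t_pleasantness",
    "fit_beta_ispc",
    "mass_univariate",
    "DECISION_NONZERO",
    "DECISION_NULL",
    "DECISION_UNDECIDED",
    "DECISION_UNCONVERGED",
    "RHAT_THRESHOLD",
]

logger = logging.getLogger(__name__)

DECISION_NONZERO = NONZERO
DECISION_NULL = "practically-null"
DECISION_UNDECIDED = "undecided"
DECISION_UNCONVERGED = "unconverged"

#: Convergence is declared when split-R-hat of every reported coefficient is
#: at or below this (an operational reading of "split-R-hat equaling 1").
RHAT_THRESHOLD = 1.01


def _summarize(draws: dict[str, np.ndarray], rope_halfwidth: float,
               keys: tuple[str, ...]) -> PosteriorSummary:
    params = {
        name: summarize_parameter(name, d, rope_halfwidth=rope_halfwidth)
        for name, d in draws.items()
    }
    rhats = [params[k].rhat for k in keys if k in params]
    max_rhat = float(max(rhats)) if rhats else float("nan")
    return PosteriorSummary(
        parameters=params, converged=max_rhat <= RHAT_THRESHOLD, max_rhat=max_rhat
    )


def familiarity_long_format(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Reshape the trial table into (subject, condition, rating) rows.

    Old excerpts contribute their exposure-session rating (condition
    "exposure") and experimental-session rating (condition "old"); new
    excerpts contribute the experimental rating (condition "new").  Excerpts
    rejected as already-familiar are left out, mirroring their exclusion
    from every condition.
    """
    rows = []
    tab = trial_table[trial_table["rejection_reason"] != "familiar"]
    for _, r in tab.iterrows():
        if r["familiarity_condition"] == "old":
            if np.isfinite(r["familiarity_rating_exposure"]):
                rows.append((r["subject"], "exposure",
                             int(r["familiarity_rating_exposure"])))
            if np.isfinite(r["familiarity_rating_experimental"]):
                rows.append((r["subject"], "old",
                             int(r["familiarity_rating_experimental"])))
        else:
            if np.isfinite(r["familiarity_rating_experimental"]):
                rows.append((r["subject"], "new",
                             int(r["familiarity_rating_experimental"])))
    return pd.DataFrame(rows, columns=["subject", "condition", "rating"])


def fit_ordinal_familiarity(
    trial_table: pd.DataFrame,
    spec: ModelSpec | None = None,
    sampler_cfg: SamplerConfig | None = None,
    rope_halfwidth: float = 0.01,
) -> PosteriorSummary:
    """Did one exposure induce familiarity?  Cumulative-probit model.

    beta1 contrasts exposure-session ratings with the same (old) excerpts in
    the experimental session; beta2 contrasts new excerpts with old ones.
    Both are in latent-standard-deviation units; beta2 - beta1 is derived on
    the draws.
    """
    long = trial_table if "condition" in trial_table.columns \
        else familiarity_long_format(trial_table)
    model = ordinal_familiarity_model(long, spec)
    draws = sample_posterior(model, sampler_cfg)
    return _summarize(draws, rope_halfwidth,
                      keys=("beta1", "beta2", "beta2_minus_beta1"))


def fit_student_t_pleasantness(
    trial_table: pd.DataFrame,
    spec: ModelSpec | None = None,
    sampler_cfg: SamplerConfig | None = None,
    rope_halfwidth: float = 0.01,
) -> PosteriorSummary:
    """Old-vs-new difference in time-weighted pleasantness (student-t)."""
    model = student_t_pleasantness_model(trial_table, spec)
    draws = sample_posterior(model, sampler_cfg)
    return _summarize(draws, rope_halfwidth, keys=("beta0", "beta1"))


def fit_beta_ispc(
    rows: pd.DataFrame,
    spec: ModelSpec | None = None,
    sampler_cfg: SamplerConfig | None = None,
    rope_halfwidth: float = 0.01,
) -> PosteriorSummary:
    """Beta regression of one pair's ISPC on pleasantness x familiarity.

    Returns beta0..beta3 plus the post-hoc simple effects PH_new = beta1 and
    PH_old = beta1 + beta3 (computed on the draws).
    """
    model = beta_ispc_model(rows, spec)
    draws = sample_posterior(model, sampler_cfg)
    summary = _summarize(draws, rope_halfwidth,
                         keys=("beta0", "beta1", "beta2", "beta3"))
    contrasts = posthoc_contrasts(draws["beta1"], draws["beta3"],
                                  rope_halfwidth=rope_halfwidth)
    summary.parameters.update(contrasts)
    return summary


def mass_univariate(
    connectivity_table: pd.DataFrame,
    pairs: "list[str] | None" = None,
    spec: ModelSpec | None = None,
    sampler_cfg: SamplerConfig | None = None,
    rope_halfwidth: float = 0.01,
) -> pd.DataFrame:
    """Fit the beta model independently for every pair; flag reportable ones.

    A pair is *reportable* when its interaction coefficient beta3 is decided
    nonzero and at least one post-hoc simple effect (most-vs-least pleasant
    within a familiarity condition) is nonzero too.  Any fit whose
    coefficients' split-R-hat exceeds the convergence threshold is reported
    with decision "unconverged" rather than silently included.  Rows come
    back in lexicographic pair order.
    """
    cfg = sampler_cfg or SamplerConfig()
    if pairs is None:
        pairs = sorted(connectivity_table["pair"].unique())
    else:
        pairs = sorted(pairs)
    out = []
    for i, pair in enumerate(pairs):
        rows = connectivity_table[connectivity_table["pair"] == pair]
        if rows["subject"].nunique() < 2:
            raise ValueError(f"pair {pair}: need data from at least 2 subjects")
        fit = fit_beta_ispc(
            rows, spec, cfg.with_seed(cfg.seed + 1000 * i + 1),
            rope_halfwidth=rope_halfwidth,
        )
        # unlucky warmups happen; retry at the full budget (fresh seeds,
        # more conservative acceptance target) before declaring failure
        import dataclasses as _dc

        from .sampler import FULL

        for attempt in range(2):
            if fit.converged:
                break
            retry_cfg = _dc.replace(FULL, target_accept=0.9,
                                    seed=cfg.seed + 1000 * i + 7 + 13 * attempt)
            logger.info("pair %s: retrying at full budget (R-hat %.3f)",
                        pair, fit.max_rhat)
            fit = fit_beta_ispc(rows, spec, retry_cfg,
                                rope_halfwidth=rope_halfwidth)
        b3, ph_new, ph_old = fit["beta3"], fit["PH_new"], fit["PH_old"]
        if not fit.converged:
            decision = DECISION_UNCONVERGED
            reportable = False
            logger.warning("pair %s: unconverged (max R-hat %.3f)", pair, fit.max_rhat)
        else:
            decision = b3.decision
            reportable = b3.decision == NONZERO and (
                ph_new.decision == NONZERO or ph_old.decision == NONZERO
            )
        rec = {"pair": pair, "reportable": reportable, "decision": decision,
               "max_rhat": fit.max_rhat, "n_obs": len(rows)}
        for nm, p in (("beta3", b3), ("PH_new", ph_new), ("PH_old", ph_old)):
            rec[f"{nm}_mode"] = p.mode
            rec[f"{nm}_hdi_low"] = p.hdi_low
            rec[f"{nm}_hdi_high"] = p.hdi_high
            rec[f"{nm}_decision"] = p.decision
        out.append(rec)
    columns = ["pair", "reportable", "decision", "max_rhat", "n_obs"] + [
        f"{nm}_{f}" for nm in ("beta3", "PH_new", "PH_old")
        for f in ("mode", "hdi_low", "hdi_high", "decision")
    ]
    return pd.DataFrame(out, columns=columns)
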