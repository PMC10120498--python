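"""Stage 1: counterfactual CATE estimation from a jointly-fit BART model.

A single BART (continuous for DAWOLS, binary for mortality) is fitted to
(covariates, treatment indicator z) on the outcome-complete rows.  For every
individual in the dataset two counterfactual rows are formed — covariates
fixed, z set to 1 and to 0 — and each posterior draw supplies a CATE draw

    tau_d(x_i) = f_d(x_i, z=1) - f_d(x_i, z=0),

a mean difference in days for DAWOLS or a risk difference for mortality
(12 mg/d minus 6 mg/d throughout).  Per-individual posteriors are summarized
by the mean and the equal-tailed 95% credible interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bart import BartConfig, PAPER_PROFILE, PosteriorDraws, fit_bart, predict
from .bart_binary import BinaryPosteriorDraws, fit_bart_binary, predict_prob
from .trial_data import TrialDataset, destandardize_value

__all__ = ["CateResult", "CateFit", "PartialDependenceCurve", "QuartileSummary",
           "estimate_cate", "partial_dependence", "quartile_summary"]

OUTCOMES = {"dawols": "dawols90", "mortality": "mort90"}


@dataclass
class CateResult:
    """Per-individual CATE posterior summaries plus the full draw matrix."""

    ids: np.ndarray              # (n,) record ids
    mean: np.ndarray             # (n,) posterior mean tau(x_i)
    lower: np.ndarray            # (n,) 2.5th percentile
    upper: np.ndarray            # (n,) 97.5th percentile
    draws: np.ndarray            # (n_kept, n) CATE draws
    scale: str                   # "days" | "risk_difference"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"id": self.ids, "cate_mean": self.mean, "cri_lower": self.lower,
             "cri_upper": self.upper}
        )
        df["cate_rank"] = df["cate_mean"].rank(method="first").astype(int)
        return df


@dataclass
class CateFit:
    """A fitted stage-1 model: the posterior draws plus everything needed for
    partial dependence and subgroup summaries."""

    outcome: str
    dataset: TrialDataset
    draws: PosteriorDraws | BinaryPosteriorDraws
    result: CateResult
    arm1_draws: np.ndarray       # (n_kept, n) counterfactual outcome, z=1
    arm0_draws: np.ndarray       # (n_kept, n) counterfactual outcome, z=0
    feature_names: list[str]


@dataclass
class PartialDependenceCurve:
    covariate: str
    grid: np.ndarray             # original units, strictly increasing
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    scale: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.covariate: self.grid, "cate_mean": self.mean,
             "cri_lower": self.lower, "cri_upper": self.upper}
        )


@dataclass
class QuartileSummary:
    """Per CATE-quartile group: mean counterfactual outcome under each arm and
    the group-mean CATE with a 95% credible interval (from group-averaged
    draws)."""

    groups: pd.DataFrame         # rows Q1..Q4
    scale: str


def _counterfactual_design(ds: TrialDataset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    X, names = ds.design_matrix(include_arm=True)
    X1 = X.copy()
    X1[:, -1] = 1.0
    X0 = X.copy()
    X0[:, -1] = 0.0
    return X, np.vstack([X1, X0]), names


def estimate_cate(
    ds: TrialDataset,
    outcome: str,
    cfg: BartConfig = PAPER_PROFILE,
    link: str = "probit",
) -> CateFit:
    """Fit the stage-1 model for one outcome and derive per-individual CATEs.

    Rows with a missing outcome are dropped from fitting (complete-case
    primary analysis) but still receive CATE predictions, since their
    covariates are complete.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {sorted(OUTCOMES)}")
    if not ds.standardized:
        raise ValueError("dataset must be standardized before model fitting")
    col = OUTCOMES[outcome]
    mask, yvals = ds.outcome_vector(col)
    if mask.sum() == 0:
        raise ValueError(f"outcome {col!r} is entirely missing")

    X_all, X_cf, names = _counterfactual_design(ds)
    X_fit = X_all[mask]

    if outcome == "dawols":
        draws = fit_bart(X_fit, yvals, cfg, X_test=X_cf, feature_names=names)
        scale = "days"
    else:
        draws = fit_bart_binary(X_fit, yvals, cfg, link=link, X_test=X_cf, feature_names=names)
        scale = "risk_difference"

    n = ds.n
    arm1 = draws.test_preds[:, :n]
    arm0 = draws.test_preds[:, n:]
    cate_draws = arm1 - arm0
    result = CateResult(
        ids=ds.df["id"].to_numpy(),
        mean=cate_draws.mean(axis=0),
        lower=np.percentile(cate_draws, 2.5, axis=0),
        upper=np.percentile(cate_draws, 97.5, axis=0),
        draws=cate_draws,
        scale=scale,
    )
    return CateFit(
        outcome=outcome, dataset=ds, draws=draws, result=result,
        arm1_draws=arm1, arm0_draws=arm0, feature_names=names,
    )


def partial_dependence(fit: CateFit, covariate: str, grid_size: int = 25) -> PartialDependenceCurve:
    """Partial-dependence of the CATE on one continuous covariate.

    For each grid value g (quantile-spaced over the observed range) the
    covariate is set to g for every individual, both counterfactual arms are
    re-scored under every retained forest draw, and the CATE draws are
    averaged over individuals within a draw.  The grid is reported in
    original units.
    """
    ds = fit.dataset
    if covariate not in ds.schema.continuous:
        raise ValueError(f"{covariate!r} is not a continuous covariate")
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    _, X_cf, names = _counterfactual_design(ds)
    j = names.index(covariate)
    xvals = ds.df[covariate].to_numpy(dtype=float)
    if grid_size == 1:
        grid_std = np.array([np.median(xvals)])
    else:
        grid_std = np.unique(np.quantile(xvals, np.linspace(0.02, 0.98, grid_size)))

    is_binary_outcome = isinstance(fit.draws, BinaryPosteriorDraws)
    n = ds.n
    means, los, his = [], [], []
    for g in grid_std:
        Xg = X_cf.copy()
        Xg[:, j] = g
        pred = predict_prob(fit.draws, Xg) if is_binary_outcome else predict(fit.draws, Xg)
        cate = (pred[:, :n] - pred[:, n:]).mean(axis=1)  # average over individuals per draw
        means.append(cate.mean())
        los.append(np.percentile(cate, 2.5))
        his.append(np.percentile(cate, 97.5))

    if ds.std_params is not None and covariate in ds.std_params.center:
        grid_out = np.array([destandardize_value(covariate, g, ds.std_params) for g in grid_std])
    else:
        grid_out = grid_std
    return PartialDependenceCurve(
        covariate=covariate, grid=grid_out, mean=np.asarray(means),
        lower=np.asarray(los), upper=np.asarray(his), scale=fit.result.scale,
    )


def quartile_summary(fit: CateFit) -> QuartileSummary:
    """Summaries for subgroups defined by quartile of posterior-mean CATE.

    Individuals are ranked by posterior-mean CATE (ties broken by stable id
    order) and cut into four groups whose sizes differ by at most one.  Group
    credible intervals come from group-averaged draws.
    """
    res = fit.result
    n = len(res.mean)
    if n < 4:
        raise ValueError("need at least 4 individuals for quartile groups")
    order = np.argsort(res.mean, kind="stable")
    parts = np.array_split(order, 4)
    rows = []
    for qi, part in enumerate(parts, start=1):
        gd = res.draws[:, part].mean(axis=1)
        rows.append(
            {
                "group": f"Q{qi}",
                "n": len(part),
                "mean_outcome_arm1": float(fit.arm1_draws[:, part].mean()),
                "mean_outcome_arm0": float(fit.arm0_draws[:, part].mean()),
                "cate_mean": float(gd.mean()),
                "cri_lower": float(np.percentile(gd, 2.5)),
                "cri_upper": float(np.percentile(gd, 97.5)),
            }
        )
    return QuartileSummary(groups=pd.DataFrame(rows), scale=res.scale)
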