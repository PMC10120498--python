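"""Best/worst- and worst/best-case imputation sensitivity analyses.

Missing outcomes are bounded by extreme fills that favor one arm and
disfavor the other, then the whole two-stage analysis is rerun:

* ``best_worst`` — missing outcomes in the 12 mg/d arm are set to the most
  favorable values (alive at 90 days, 90 days without life support) and in
  the 6 mg/d arm to the least favorable (dead, 0 days);
* ``worst_best`` — the mirror image.

Only missing outcomes are touched; covariates, arm and observed outcomes are
immutable.  Because the fills are extremal, the raw 12-minus-6 arm
difference in mortality under ``best_worst`` is a lower bound and under
``worst_best`` an upper bound for the complete-case difference (and the
reverse ordering holds for DAWOLS).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bart import BartConfig, FAST_PROFILE
from .cate import estimate_cate
from .subgroup_tree import fit_subgroup_tree, render_tree
from .trial_data import TrialDataset

__all__ = ["impute_extreme", "run_sensitivity", "SensitivityReport"]

# (mort fill, dawols fill) per arm under each direction
_FILLS = {
    "best_worst": {1: (0, 90), 0: (1, 0)},
    "worst_best": {1: (1, 0), 0: (0, 90)},
}


def impute_extreme(ds: TrialDataset, direction: str) -> TrialDataset:
    """Fill missing outcomes with the extreme values for ``direction``."""
    if direction not in _FILLS:
        raise ValueError("direction must be 'best_worst' or 'worst_best'")
    out = ds.copy()
    df = out.df
    for arm, (mort_fill, daw_fill) in _FILLS[direction].items():
        in_arm = df["arm"] == arm
        df.loc[in_arm & df["mort90"].isna(), "mort90"] = mort_fill
        df.loc[in_arm & df["dawols90"].isna(), "dawols90"] = daw_fill
    return out


@dataclass
class SensitivityReport:
    """Primary and sensitivity trees per outcome, with split-set comparisons."""

    trees: dict                 # outcome -> {analysis_name -> SubgroupTree}
    comparisons: pd.DataFrame   # outcome, analysis, split_vars, first_split, matches_primary

    def to_json(self) -> str:
        import json

        payload = {
            outcome: {name: render_tree(tree, "json") for name, tree in by_name.items()}
            for outcome, by_name in self.trees.items()
        }
        return json.dumps(
            {"trees": {k: {n: __import__("json").loads(v) for n, v in d.items()}
                       for k, d in payload.items()},
             "comparison": self.comparisons.to_dict(orient="records")},
            indent=2,
        )


def run_sensitivity(
    ds: TrialDataset,
    outcomes: tuple[str, ...] = ("dawols", "mortality"),
    cfg: BartConfig = FAST_PROFILE,
    link: str = "probit",
    max_depth: int = 3,
    min_leaf: int = 20,
    cp: float = 0.01,
) -> SensitivityReport:
    """Re-run stage 1 + stage 2 under each extreme imputation.

    ``ds`` is the raw (unstandardized) dataset; each analysis standardizes
    its own copy so imputed values flow through identically to observed ones.
    The report lists each tree's split variables and whether they match the
    primary (complete-case) tree.
    """
    from .trial_data import standardize_covariates

    analyses = {
        "primary": ds,
        "best_worst": impute_extreme(ds, "best_worst"),
        "worst_best": impute_extreme(ds, "worst_best"),
    }
    trees: dict = {o: {} for o in outcomes}
    rows = []
    for outcome in outcomes:
        primary_splits: list[str] | None = None
        for name, data in analyses.items():
            sds = standardize_covariates(data)
            fit = estimate_cate(sds, outcome, cfg, link=link)
            tree = fit_subgroup_tree(sds, fit.result, max_depth=max_depth,
                                     min_leaf=min_leaf, cp=cp)
            trees[outcome][name] = tree
            splits = tree.split_variables()
            first = splits[0] if splits else None
            if name == "primary":
                primary_splits = splits
            rows.append(
                {
                    "outcome": outcome,
                    "analysis": name,
                    "split_vars": ",".join(splits),
                    "first_split": first,
                    "matches_primary": splits == primary_splits,
                }
            )
    return SensitivityReport(trees=trees, comparisons=pd.DataFrame(rows))
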