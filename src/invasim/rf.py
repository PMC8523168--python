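"""Random-forest regressions of invader survival and permutation importance.

Invader survival (log10(cells/mL + 1)) is regressed on composition
features plus the 14 phenotype measurements and the three diversity
variables.  Variable importance is the out-of-bag (OOB) permutation
importance familiar from regression forests: for each tree, the MSE on
its OOB samples is compared with the MSE after permuting one feature's
OOB values, and the increase is averaged over trees.  Explanatory power
is the pseudo-R^2, 1 - MSE_oob / var(y), from pooled OOB predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .data import PHENOTYPE_COLUMNS, PhenotypeTable
from .preprocess import TransformSpec


def assemble_features(group_features: pd.DataFrame,
                      phenotypes: PhenotypeTable,
                      diversity: pd.DataFrame,
                      invader: str,
                      transform: TransformSpec | None = None) -> pd.DataFrame:
    """Composition + phenotype + diversity design matrix for one invader.

    With the 19+1 functional-group representation this reproduces the
    37-column design (20 group features + 14 phenotypes + Simpson + Rao +
    invader-specific distance).  All variables except the three diversity
    indices are log10-transformed.  Raises when the tables do not share
    identical community ids.
    """
    phen = phenotypes.values
    for name, other in (("phenotypes", phen), ("diversity", diversity)):
        missing = set(group_features.index) - set(other.index)
        extra = set(other.index) - set(group_features.index)
        if missing or extra:
            raise ValueError(
                f"community ids of {name} do not match composition features: "
                f"missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]}")
    ids = group_features.index
    dist_col = f"invader_distance_{invader}"
    if dist_col not in diversity.columns:
        raise ValueError(f"diversity table lacks column {dist_col!r}")
    div = diversity.loc[ids, ["simpson", "rao_q", dist_col]]
    X = pd.concat([group_features, phen.loc[ids], div], axis=1)
    spec = transform or TransformSpec()
    return spec.transform_explanatory(X)


@dataclass
class ImportanceResult:
    """Permutation importances and pseudo-R^2 of one forest."""

    importance: pd.DataFrame  # feature, inc_mse_pct (raw), inc_mse_norm
    pseudo_r2: float
    metadata: dict = field(default_factory=dict)

    def top_features(self, n: int = 5) -> list[str]:
        return list(self.importance.sort_values("inc_mse_pct", ascending=False)
                    .head(n)["feature"])


def _sample_indices(forest: RandomForestRegressor, n: int):
    try:
        return forest.estimators_samples_
    except AttributeError:  # pragma: no cover - older sklearn
        from sklearn.ensemble._forest import _generate_sample_indices
        return [_generate_sample_indices(est.random_state, n, n)
                for est in forest.estimators_]


def rf_variable_importance(X: pd.DataFrame, y: pd.Series | np.ndarray,
                           n_trees: int = 500, seed: int = 0,
                           min_samples: int = 30) -> ImportanceResult:
    """Fit a regression forest and compute OOB permutation importance.

    Raw %IncMSE for feature j is 100 * mean over trees of
    (MSE_oob^perm_j - MSE_oob) / MSE_oob; the normalised variant divides
    the mean raw OOB error increase by its standard error over trees.
    mtry is floor(p / 3) (at least 1); pseudo-R^2 uses pooled OOB
    predictions.  Deterministic under a fixed seed.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if p == 0:
        raise ValueError("no features")
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    if np.ptp(yv) == 0:
        raise ValueError("response is constant")
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=max(1, p // 3) / p,
        bootstrap=True, random_state=seed, n_jobs=1)
    forest.fit(Xv, yv)
    rng = np.random.default_rng(seed)

    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    rel_inc = np.zeros((n_trees, p))
    abs_inc = np.zeros((n_trees, p))
    for t, (est, idx) in enumerate(zip(forest.estimators_,
                                       _sample_indices(forest, n))):
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        if not mask.any():
            continue
        Xo, yo = Xv[mask], yv[mask]
        pred = est.predict(Xo)
        oob_sum[mask] += pred
        oob_cnt[mask] += 1
        mse = np.mean((pred - yo) ** 2)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            mse_p = np.mean((est.predict(Xp) - yo) ** 2)
            abs_inc[t, j] = mse_p - mse
            rel_inc[t, j] = (mse_p - mse) / mse if mse > 0 else 0.0
    seen = oob_cnt > 0
    oob_pred = oob_sum[seen] / oob_cnt[seen]
    mse_oob = np.mean((oob_pred - yv[seen]) ** 2)
    pseudo_r2 = 1.0 - mse_oob / np.var(yv[seen])

    mean_abs = abs_inc.mean(axis=0)
    se = abs_inc.std(axis=0, ddof=1) / np.sqrt(n_trees)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(se > 0, mean_abs / se, 0.0)
    imp = pd.DataFrame({
        "feature": list(X.columns) if isinstance(X, pd.DataFrame) else
                   [f"x{j}" for j in range(p)],
        "inc_mse_pct": 100.0 * rel_inc.mean(axis=0),
        "inc_mse_raw": mean_abs,
        "inc_mse_norm": norm,
    })
    return ImportanceResult(importance=imp, pseudo_r2=float(pseudo_r2),
                            metadata={"n_trees": n_trees, "seed": seed,
                                      "n_features": p, "n_samples": n})


def compare_reductions(reductions: dict[str, pd.DataFrame],
                       responses: dict[tuple[str, int], pd.Series],
                       n_trees: int = 500, seed: int = 0,
                       transform: TransformSpec | None = None) -> pd.DataFrame:
    """Composition-only forests for every reduction x invader x time.

    ``responses`` maps (invader, time_h) to the transformed survival
    vector.  Returns a table with pseudo_r2 and n_features per cell, a
    per-reduction mean, a Pareto-efficiency flag (no other reduction has
    both >= mean pseudo_r2 and <= n features, one strictly) and a
    ``selected`` flag on the Pareto point with the highest mean
    pseudo_r2.
    """
    if not reductions:
        raise ValueError("no reductions given")
    spec = transform or TransformSpec()
    rows = []
    for name, feats in reductions.items():
        # ordination coordinates are signed and already scale-free; only
        # non-negative abundance-style tables get the log transform
        if (feats.to_numpy() < 0).any():
            tx = feats
        else:
            tx = spec.transform_explanatory(feats)
        for (invader, time_h), y in responses.items():
            y = y.loc[feats.index]
            res = rf_variable_importance(tx, y, n_trees=n_trees, seed=seed)
            rows.append({"reduction": name, "invader": invader,
                         "time_h": time_h, "pseudo_r2": res.pseudo_r2,
                         "n_features": feats.shape[1]})
    table = pd.DataFrame(rows)
    summary = (table.groupby("reduction")
               .agg(mean_pseudo_r2=("pseudo_r2", "mean"),
                    n_features=("n_features", "first"))
               .reset_index())
    pareto = []
    for _, row in summary.iterrows():
        dominated = ((summary["mean_pseudo_r2"] >= row["mean_pseudo_r2"])
                     & (summary["n_features"] <= row["n_features"])
                     & ((summary["mean_pseudo_r2"] > row["mean_pseudo_r2"])
                        | (summary["n_features"] < row["n_features"]))).any()
        pareto.append(not dominated)
    summary["pareto"] = pareto
    best = summary.loc[summary["pareto"], "mean_pseudo_r2"].idxmax()
    summary["selected"] = False
    summary.loc[best, "selected"] = True
    return table.merge(summary, on="reduction", suffixes=("", "_summary"))
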