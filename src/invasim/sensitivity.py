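"""Permutation sensitivity analysis for below-detection invader survival.

Sub-threshold luminescence readings are indistinguishable from sterile
background, so their calibrated cell densities may be noise.  To test
whether the mediation model selection depends on them, the censored
values are shuffled among themselves (sampling without replacement,
within each invader x time endpoint column by default), the three
structural models are refitted on each shuffled dataset, and the
best-model frequencies and mean AICc shifts are tallied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sem import SemModelSpec, compare_models, fit_sem

logger = logging.getLogger(__name__)


def shuffle_below_detection(endpoints: pd.DataFrame, flags: pd.DataFrame,
                            n_perm: int = 999, seed: int = 0,
                            scope: str = "column"):
    """Yield ``n_perm`` copies of ``endpoints`` with flagged values permuted.

    ``endpoints`` is communities x endpoint columns (cells/mL scale);
    ``flags`` is a boolean frame of the same shape marking below-detection
    entries.  With ``scope="column"`` each endpoint column's flagged
    values are permuted among themselves; ``scope="global"`` pools all
    flagged values into one exchangeable set.  Unflagged values are never
    touched; each permutation preserves the multiset of flagged values.
    Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scope not in ("column", "global"):
        raise ValueError("scope must be 'column' or 'global'")
    flags = flags.loc[endpoints.index, endpoints.columns].to_numpy(dtype=bool)
    base = endpoints.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = base.copy()
        if scope == "column":
            for j in range(base.shape[1]):
                idx = np.flatnonzero(flags[:, j])
                if idx.size > 1:
                    perm[idx, j] = base[rng.permutation(idx), j]
        else:
            idx = np.flatnonzero(flags.ravel())
            if idx.size > 1:
                flat = perm.ravel()
                flat[idx] = base.ravel()[rng.permutation(idx)]
                perm = flat.reshape(base.shape)
        yield pd.DataFrame(perm, index=endpoints.index, columns=endpoints.columns)


@dataclass
class SensitivityResult:
    """Best-model tallies over permuted below-detection values."""

    n_permutations: int
    n_dropped: int
    best_model_freq: dict[str, float]          # percent of permutations
    mean_delta_aicc: dict[str, float]          # mean AICc - best per permutation
    mean_abs_aicc_shift: dict[str, float]      # |AICc_perm - AICc_unpermuted|
    unpermuted_best: str
    seed: int
    per_permutation: pd.DataFrame = field(repr=False, default=None)


def run_sensitivity(endpoints: pd.DataFrame, flags: pd.DataFrame,
                    specs: dict[str, SemModelSpec],
                    other_indicators: pd.DataFrame,
                    transform, n_perm: int = 999, seed: int = 0,
                    scope: str = "column",
                    max_dropped_frac: float = 0.1) -> SensitivityResult:
    """Refit the three SEMs on each permuted dataset and tally winners.

    ``endpoints`` holds the (averaged, cells/mL) invader-survival columns;
    ``other_indicators`` the remaining, already-transformed indicator
    columns; ``transform`` maps raw endpoint values to the model scale
    (the survival response transform, log10(x + 1)).  Permutations whose
    fits all fail are dropped with a logged count; more than
    ``max_dropped_frac`` dropped is an error.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    base_data = other_indicators.join(endpoints.apply(transform), how="inner")
    base_fits = {name: fit_sem(spec, base_data) for name, spec in specs.items()}
    base_cmp = compare_models(base_fits)
    base_aicc = {name: f.aicc for name, f in base_fits.items()}

    rows = []
    n_dropped = 0
    for k, perm in enumerate(shuffle_below_detection(endpoints, flags,
                                                     n_perm=n_perm, seed=seed,
                                                     scope=scope)):
        data = other_indicators.join(perm.apply(transform), how="inner")
        row = {"perm": k}
        try:
            for name, spec in specs.items():
                # warm-start from the unpermuted solution: a permutation
                # changes only the censored entries, so it is close
                row[name] = fit_sem(spec, data,
                                    warm_start=base_fits[name].params).aicc
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            n_dropped += 1
            logger.warning("permutation %d dropped: %s", k, exc)
            continue
        rows.append(row)
    if n_dropped > max_dropped_frac * n_perm:
        raise RuntimeError(f"{n_dropped}/{n_perm} permutations failed to fit")
    per_perm = pd.DataFrame(rows).set_index("perm")
    model_names = list(specs)
    winners = per_perm[model_names].idxmin(axis=1)
    freq = {name: 100.0 * float((winners == name).mean()) for name in model_names}
    deltas = per_perm[model_names].sub(per_perm[model_names].min(axis=1), axis=0)
    mean_delta = {name: float(deltas[name].mean()) for name in model_names}
    shift = {name: float((per_perm[name] - base_aicc[name]).abs().mean())
             for name in model_names}
    return SensitivityResult(
        n_permutations=len(per_perm), n_dropped=n_dropped,
        best_model_freq=freq, mean_delta_aicc=mean_delta,
        mean_abs_aicc_shift=shift, unpermuted_best=str(base_cmp["best_model"]),
        seed=seed, per_permutation=per_perm)
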