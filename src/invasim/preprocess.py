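"""Filtering, luminescence calibration, replicate averaging and transforms.

The preprocessing stage applies the study-design rules that turn raw
tables into analysis-ready variables:

* rare-OTU and low-depth community filtering (strict thresholds:
  prevalence < 10 samples, < 100 total reads, < 10,000 reads/community);
* calibration of invader luminescence against plate counts by log-log
  OLS over the log phase of a growth assay;
* conversion of each replicate luminescence reading to cells/mL, flagging
  of readings below the background detection threshold (12 lumens in the
  study design), then averaging over the four technical replicates;
* variable transforms: the response (invader survival) is log10(x + 1);
  explanatory phenotype/abundance variables are log10(x); diversity
  indices enter untransformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CalibrationModel, InvasionTable, OtuTable

logger = logging.getLogger(__name__)


def filter_otu_table(table: OtuTable,
                     min_sample_prevalence: int = 10,
                     min_total_reads: int = 100,
                     min_community_reads: int = 10000) -> OtuTable:
    """Remove extremely rare OTUs, then shallow communities.

    An OTU is removed when it occurs (count > 0) in fewer than
    ``min_sample_prevalence`` communities OR has fewer than
    ``min_total_reads`` reads summed over all communities.  Communities
    whose remaining row sum is below ``min_community_reads`` are then
    removed.  All comparisons are strict (<), so an OTU in exactly 10
    communities with exactly 100 reads is retained.  Idempotent:
    filtering a filtered table is a no-op.
    """
    counts = table.counts
    prevalence = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    keep_otus = (prevalence >= min_sample_prevalence) & (totals >= min_total_reads)
    n_dropped = int((~keep_otus).sum())
    if n_dropped:
        logger.info("filter_otu_table: dropping %d rare OTUs", n_dropped)
    counts = counts.loc[:, keep_otus]
    if counts.shape[1] == 0:
        raise ValueError("all OTUs removed by the rare-OTU filter")
    depth = counts.sum(axis=1)
    keep_comm = depth >= min_community_reads
    dropped = list(counts.index[~keep_comm])
    if dropped:
        logger.info("filter_otu_table: dropping %d shallow communities (e.g. %s)",
                    len(dropped), dropped[:5])
    counts = counts.loc[keep_comm]
    if counts.shape[0] == 0:
        raise ValueError("all communities removed by the depth filter")
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = table.taxonomy.loc[counts.columns]
    return OtuTable(counts=counts.copy(), taxonomy=taxonomy)


def _window_fit(sub: pd.DataFrame):
    res = stats.linregress(np.log10(sub["lux"]), np.log10(sub["cells"]))
    return res


def fit_lux_calibration(growth_assay: pd.DataFrame,
                        invader: str,
                        log_phase_window: tuple[float, float] | None = None,
                        min_points: int = 4) -> CalibrationModel:
    """Fit log10(cells) = a + b*log10(lux) over the log-phase window.

    ``growth_assay`` has columns invader, replicate, hours, lux, cells.
    Points with lux <= 0 or cells <= 0 are excluded (outside the sensitive
    range of the assay).  If no window is given, the contiguous window of
    assay hours (>= ``min_points`` in-window readings) maximising R^2 is
    used, since only "log phase" is specified by the assay design; the
    window used is reported on the model.
    """
    sub = growth_assay[growth_assay["invader"] == invader]
    sub = sub[(sub["lux"] > 0) & (sub["cells"] > 0)]
    if log_phase_window is not None:
        lo, hi = log_phase_window
        win = sub[(sub["hours"] >= lo) & (sub["hours"] <= hi)]
        if len(win) < 3:
            raise ValueError("fewer than 3 usable points in the calibration window")
        if np.ptp(np.log10(win["lux"])) == 0:
            raise ValueError("zero variance in luminescence within the window")
        res = _window_fit(win)
        return CalibrationModel(invader=invader, intercept=float(res.intercept),
                                slope=float(res.slope),
                                r_squared=float(res.rvalue ** 2),
                                window_hours=(float(lo), float(hi)),
                                n_points=len(win))
    hours = np.sort(sub["hours"].unique())
    if len(sub) < 3:
        raise ValueError("fewer than 3 usable calibration points")
    best = None
    for i in range(len(hours)):
        for j in range(i, len(hours)):
            win = sub[(sub["hours"] >= hours[i]) & (sub["hours"] <= hours[j])]
            if len(win) < min_points:
                continue
            if np.ptp(np.log10(win["lux"])) == 0:
                continue
            res = _window_fit(win)
            r2 = res.rvalue ** 2
            if best is None or r2 > best[0] + 1e-15:
                best = (r2, res, (float(hours[i]), float(hours[j])), len(win))
    if best is None:
        raise ValueError("no calibration window with enough usable variation")
    r2, res, window, n = best
    return CalibrationModel(invader=invader, intercept=float(res.intercept),
                            slope=float(res.slope), r_squared=float(r2),
                            window_hours=window, n_points=n)


def lux_to_cells(lux, cal: CalibrationModel):
    """Convert luminescence to cells/mL: 10^(a + b*log10(lux)); 0 maps to 0."""
    lux = np.asarray(lux, dtype=float)
    if (lux < 0).any():
        raise ValueError("negative luminescence")
    out = np.zeros_like(lux)
    pos = lux > 0
    out[pos] = 10.0 ** (cal.intercept + cal.slope * np.log10(lux[pos]))
    if out.ndim == 0:
        return float(out)
    return out


def detection_threshold(background_lux: Sequence[float]) -> float:
    """Detection threshold = maximum background luminescence of sterile blanks."""
    arr = np.asarray(list(background_lux), dtype=float)
    if arr.size == 0:
        raise ValueError("empty background sequence")
    return float(arr.max())


def convert_and_flag(invasion: InvasionTable,
                     calibrations: dict[str, CalibrationModel],
                     threshold_lux: float) -> InvasionTable:
    """Per-replicate lux -> cells/mL conversion with detection flagging.

    Flags are set on the lux scale (lux < threshold) before conversion,
    because the calibration is nonlinear in lux and sub-threshold readings
    are background noise regardless of their converted value.
    """
    d = invasion.data.copy()
    cells = np.empty(len(d))
    for inv, cal in calibrations.items():
        m = (d["invader"] == inv).to_numpy()
        cells[m] = lux_to_cells(d.loc[m, "lux"].to_numpy(), cal)
    unknown = ~d["invader"].isin(calibrations)
    if unknown.any():
        raise ValueError(f"no calibration for invaders {sorted(d.loc[unknown, 'invader'].unique())}")
    d["cells"] = cells
    d["below_detection"] = d["lux"].to_numpy() < threshold_lux
    return InvasionTable(d)


def average_replicates(invasion: InvasionTable) -> InvasionTable:
    """Arithmetic mean over technical replicates on the cells/mL scale.

    A community x invader x time mean is flagged below detection iff all
    contributing replicates were flagged.
    """
    if not invasion.has_replicates:
        raise ValueError("invasion table has no replicate column")
    d = invasion.data
    grouped = d.groupby(["community", "invader", "time_h"], sort=True)
    n = grouped.size()
    if (n < 1).any():  # pragma: no cover - groupby cannot emit empty groups
        raise ValueError("empty replicate cell")
    out = grouped.agg(lux=("lux", "mean"), cells=("cells", "mean"),
                      below_detection=("below_detection", "all")).reset_index()
    return InvasionTable(out)


@dataclass
class TransformSpec:
    """Variable transforms used throughout the statistical analysis.

    The response (invader survival, cells/mL) is log10(x + 1) so zero
    survivals are representable.  Explanatory phenotype and abundance
    variables are log10(x); zeros are mapped through a small pseudocount
    (default: half the smallest positive observed value per column).
    Diversity indices are left on their natural scale.
    """

    response_pseudocount: float = 1.0
    explanatory_zero_rule: str = "half_min_positive"
    diversity_columns: tuple[str, ...] = ("simpson", "rao_q", "invader_distance")

    def transform_response(self, y):
        y = np.asarray(y, dtype=float)
        if (y < 0).any():
            raise ValueError("negative response values")
        return np.log10(y + self.response_pseudocount)

    def transform_explanatory(self, x: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in x.columns:
            v = x[col].to_numpy(dtype=float)
            if any(col.startswith(d) for d in self.diversity_columns):
                out[col] = v
                continue
            if (v < 0).any():
                raise ValueError(f"negative values in explanatory column {col!r}")
            if (v == 0).any():
                pos = v[v > 0]
                pc = pos.min() / 2.0 if pos.size else 1.0
                v = v + np.where(v == 0, pc, 0.0)
            out[col] = np.log10(v)
        return pd.DataFrame(out, index=x.index)


def apply_transforms(response: pd.DataFrame | pd.Series | None,
                     explanatory: pd.DataFrame | None,
                     spec: TransformSpec | None = None):
    """Apply the standard transforms; either argument may be None."""
    spec = spec or TransformSpec()
    ty = None
    if response is not None:
        if isinstance(response, pd.Series):
            ty = pd.Series(spec.transform_response(response), index=response.index,
                           name=response.name)
        else:
            ty = response.apply(lambda c: spec.transform_response(c))
    tx = spec.transform_explanatory(explanatory) if explanatory is not None else None
    return ty, tx
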