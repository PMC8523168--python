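"""Domain containers and file I/O for the invasion-resistance pipeline.

The pipeline links three observational layers collected on the same set of
bacterial communities:

* starting composition — an OTU count table (communities x OTUs) with
  taxonomic annotations and a rooted 16S phylogeny over the OTUs plus the
  invader strains;
* realised phenotype — per-community productivity proxies (cell yield,
  respiration) and metabolic measurements (ATP, four enzyme activities) at
  days 7 and 14 of growth;
* invasion outcome — luminescence-based survival of two invader strains at
  three time points, in four technical replicates, with a detection
  threshold below which readings are background noise.

All tables are keyed by community id; tabular data live in pandas
DataFrames, trees in scikit-bio ``TreeNode`` objects.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

TAXONOMIC_RANKS = ("species", "genus", "family", "order", "class", "phylum")

#: Invader strain identifiers used throughout (lux-tagged Pseudomonas).
INVADERS = ("fluorescens", "putida")

#: Hours post-invasion at which invader survival is assayed.
TIMEPOINTS = (24, 96, 168)

#: The 14 per-community phenotype measurements (2 yields, 2 respirations,
#: 2 ATP, 4 enzymes x 2 days).
PHENOTYPE_COLUMNS = (
    "cell_yield_d7", "cell_yield_d14",
    "respiration_d7", "respiration_d14",
    "atp_d7", "atp_d14",
    "glucosidase_d7", "glucosidase_d14",
    "chitinase_d7", "chitinase_d14",
    "xylosidase_d7", "xylosidase_d14",
    "phosphatase_d7", "phosphatase_d14",
)

#: Yield columns that indicate latent productivity in the structural models.
PRODUCTIVITY_COLUMNS = ("cell_yield_d7", "cell_yield_d14")

FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """Raised when an input file violates the documented layout."""


@dataclass
class OtuTable:
    """Counts of 16S reads per OTU per community, with taxonomy.

    ``counts`` is communities (rows) x OTUs (columns), non-negative
    integers.  ``taxonomy`` maps each OTU id to labels at the six ranks
    species..phylum; missing labels are allowed and treated downstream as
    an explicit "unclassified" bucket.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise FormatError("duplicate community ids")
        if c.columns.has_duplicates:
            raise FormatError("duplicate OTU ids")
        arr = c.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError("non-finite counts")
        if (arr < 0).any():
            raise FormatError("negative counts")
        if not np.array_equal(arr, np.floor(arr)):
            raise FormatError("non-integer counts")
        self.counts = c.astype(np.int64)
        if self.taxonomy is not None:
            tax = self.taxonomy
            if set(tax.index) != set(c.columns):
                raise FormatError("taxonomy must be keyed by exactly the OTU ids present")
            missing = [r for r in TAXONOMIC_RANKS if r not in tax.columns]
            if missing:
                raise FormatError(f"taxonomy missing ranks: {missing}")
            self.taxonomy = tax.loc[c.columns, list(TAXONOMIC_RANKS)]

    @property
    def community_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundances(self) -> pd.DataFrame:
        """Per-community proportions p_i (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("cannot normalise a community with zero reads")
        return self.counts.div(totals, axis=0)


@dataclass
class PhenotypeTable:
    """The 14 phenotype measurements per community (all >= 0, complete)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.values.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns: {missing}")
        v = self.values[list(PHENOTYPE_COLUMNS)].astype(float)
        if v.isna().any().any():
            raise FormatError("phenotype table contains missing values")
        if (v.to_numpy() < 0).any():
            raise FormatError("phenotype values must be >= 0")
        if v.index.has_duplicates:
            raise FormatError("duplicate community ids")
        self.values = v

    @property
    def community_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class InvasionTable:
    """Invader-survival endpoints in long form.

    Columns: community, invader, time_h, replicate (optional after
    averaging), lux, cells, below_detection.  ``cells`` is the
    calibration-converted density (cells/mL); ``below_detection`` flags
    replicates whose luminescence fell under the background threshold.
    """

    data: pd.DataFrame

    REQUIRED = ("community", "invader", "time_h", "lux", "cells", "below_detection")

    def __post_init__(self) -> None:
        d = self.data
        missing = [c for c in self.REQUIRED if c not in d.columns]
        if missing:
            raise FormatError(f"invasion table missing columns: {missing}")
        if (d["cells"].to_numpy() < 0).any():
            raise FormatError("cells/mL must be >= 0")
        self.data = d.reset_index(drop=True)

    @property
    def has_replicates(self) -> bool:
        return "replicate" in self.data.columns

    def endpoint_wide(self, value: str = "cells") -> pd.DataFrame:
        """Pivot to communities x (invader, time) endpoint columns.

        Column names follow the deposited-data convention
        ``<invader>.cells.<hours>``.
        """
        d = self.data
        if self.has_replicates:
            raise ValueError("average replicates before pivoting to endpoints")
        wide = d.pivot(index="community", columns=["invader", "time_h"], values=value)
        wide.columns = [f"{inv}.{value}.{int(t)}" for inv, t in wide.columns]
        return wide

    def flags_wide(self) -> pd.DataFrame:
        d = self.data
        if self.has_replicates:
            raise ValueError("average replicates before pivoting to endpoints")
        wide = d.pivot(index="community", columns=["invader", "time_h"],
                       values="below_detection")
        wide.columns = [f"{inv}.cells.{int(t)}" for inv, t in wide.columns]
        return wide.astype(bool)


@dataclass
class CalibrationModel:
    """Log-log OLS calibration of plate counts against luminescence.

    log10(cells) = a + b * log10(lux), fitted over the log-phase window of
    a growth assay.
    """

    invader: str
    intercept: float
    slope: float
    r_squared: float
    window_hours: tuple[float, float]
    n_points: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("calibration slope must be finite")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, taxonomy_path: str | Path | None = None) -> OtuTable:
    """Read a TSV OTU count table (first column community id, one column
    per OTU), optionally with a companion taxonomy TSV (otu_id, species..phylum).

    Integer parsing is lossless; negative, non-integer or duplicated
    entries raise :class:`FormatError`.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        otu_cols = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(otu_cols)) != len(otu_cols):
        raise FormatError("duplicate OTU ids in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not all(df.dtypes.apply(lambda t: np.issubdtype(t, np.integer))):
        # re-check for floats that are really integers vs genuine bad input
        try:
            as_float = df.astype(float)
        except ValueError as exc:
            raise FormatError(f"non-numeric count in {path}: {exc}") from exc
        if not np.array_equal(as_float.to_numpy(), np.floor(as_float.to_numpy())):
            raise FormatError("non-integer counts")
        df = as_float
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
    return OtuTable(counts=df, taxonomy=taxonomy)


def read_tree(path_or_newick: str | Path, outgroup: str | None = None) -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    A basal trifurcation is taken as an unrooted tree and rejected unless
    ``outgroup`` names a tip to root by (the study tree is rooted on the
    archaeon Halobacterium salinarum).  Missing branch lengths on any
    non-root edge are an error.
    """
    src = str(path_or_newick)
    if src.lstrip().startswith("("):
        tree = TreeNode.read(StringIO(src), convert_underscores=False)
    else:
        tree = TreeNode.read(src, convert_underscores=False)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError("tree has edges without branch lengths")
        if node.length < 0:
            raise FormatError("negative branch length")
    if outgroup is not None:
        tips = {t.name for t in tree.tips()}
        if outgroup not in tips:
            raise FormatError(f"requested outgroup {outgroup!r} not in tree")
        tree = tree.root_by_outgroup([outgroup])
    elif len(tree.children) > 2:
        raise FormatError(
            "tree is unrooted (basal multifurcation); supply an outgroup to root it"
        )
    return tree


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the per-community phenotype CSV (first column community id)."""
    return PhenotypeTable(pd.read_csv(path, index_col=0))


def read_invasion(path: str | Path) -> InvasionTable:
    """Read the long-form invasion CSV."""
    df = pd.read_csv(path)
    if "below_detection" in df.columns:
        df["below_detection"] = df["below_detection"].astype(bool)
    return InvasionTable(df)


def read_calibration_assay(path: str | Path) -> pd.DataFrame:
    """Read a growth-assay CSV with columns invader, replicate, hours, lux, cells."""
    df = pd.read_csv(path)
    required = {"invader", "replicate", "hours", "lux", "cells"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"calibration assay missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_otu_table(table: OtuTable, path: str | Path,
                    taxonomy_path: str | Path | None = None) -> None:
    table.counts.to_csv(path, sep="\t", index_label="community")
    if taxonomy_path is not None and table.taxonomy is not None:
        table.taxonomy.to_csv(taxonomy_path, sep="\t", index_label="otu_id")


def _to_jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return _to_jsonable(obj.to_dict())
    return obj


def write_results(bundle: Mapping[str, object], outdir: str | Path) -> list[Path]:
    """Write a bundle of stage outputs to ``outdir``.

    DataFrames become ``<name>.csv`` (floats at 10 significant digits),
    dicts become ``<name>.json``.  File names are the bundle keys, so the
    layout is deterministic.  Returns the paths written; an empty bundle
    writes nothing and logs a warning.
    """
    outdir = Path(outdir)
    if not bundle:
        logger.warning("write_results called with an empty bundle; nothing written")
        return []
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, float_format=FLOAT_FORMAT)
        elif isinstance(obj, pd.Series):
            p = outdir / f"{name}.csv"
            obj.to_frame().to_csv(p, float_format=FLOAT_FORMAT)
        else:
            p = outdir / f"{name}.json"
            with open(p, "w", encoding="utf-8") as fh:
                json.dump(_to_jsonable(obj), fh, indent=2, sort_keys=True)
                fh.write("\n")
        written.append(p)
    return written


def align_communities(*tables: pd.DataFrame) -> tuple[list[str], list[pd.DataFrame]]:
    """Restrict a set of community-indexed tables to their shared ids.

    Returns the sorted intersection and the aligned tables; logs any ids
    dropped from each table so reductions of the sample set are auditable.
    """
    if not tables:
        raise ValueError("no tables given")
    shared = set(tables[0].index)
    for t in tables[1:]:
        shared &= set(t.index)
    if not shared:
        raise ValueError("community-id intersection is empty")
    order = sorted(shared)
    aligned = []
    for i, t in enumerate(tables):
        dropped = sorted(set(t.index) - shared)
        if dropped:
            logger.info("align_communities: table %d drops %d ids (e.g. %s)",
                        i, len(dropped), dropped[:5])
        aligned.append(t.loc[order])
    return order, aligned
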