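"""Per-slide aggregation of cell features.

A slide is summarised by the mean of each inherent property (SC, SN, EP,
NCR) together with its standard deviation across cells, which quantifies
the *atypia* — the within-slide morphological heterogeneity — of that
property.  Slides enter cohort analyses only when they carry at least
``min_cells`` segmented cells (default 500), mirroring the section
selection rule used when assembling stable whole-slide statistics.

SDs are sample standard deviations (n-1 denominator); SN and NCR
statistics are computed over nucleus-assigned cells only, so cells
without a detected nucleus still contribute to SC/EP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .morphometry import CellRecord

__all__ = [
    "SlideSummary",
    "DEFAULT_MIN_CELLS",
    "summarize_slide",
    "summarize_cohort",
    "histogram_data",
    "scatter3d_data",
]

DEFAULT_MIN_CELLS = 500

_FEATURES = ("sc", "sn", "ep", "ncr")


@dataclass
class SlideSummary:
    """Per-slide feature means, SD-based atypia, and the inclusion flag."""

    slide_id: Optional[str]
    n_cells: int
    n_with_nucleus: int
    sc_mean: float
    sc_sd: Optional[float]
    sn_mean: Optional[float]
    sn_sd: Optional[float]
    ep_mean: float
    ep_sd: Optional[float]
    ncr_mean: Optional[float]
    ncr_sd: Optional[float]
    included: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _mean_sd(values: np.ndarray) -> tuple[Optional[float], Optional[float]]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return None, None
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else None
    return mean, sd


def _records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sc": [r.sc for r in records],
            "sn": [np.nan if r.sn is None else r.sn for r in records],
            "ep": [r.ep for r in records],
            "ncr": [np.nan if r.ncr is None else r.ncr for r in records],
        }
    )


def summarize_slide(
    records: Sequence[CellRecord] | pd.DataFrame,
    min_cells: int = DEFAULT_MIN_CELLS,
    slide_id: str | None = None,
) -> SlideSummary:
    """Aggregate one slide's cell records into a :class:`SlideSummary`.

    Accepts either :class:`CellRecord` objects or a per-cell feature
    DataFrame with ``sc``/``sn``/``ep``/``ncr`` columns (``sn``/``ncr``
    NaN when no nucleus was assigned).  Errors on an empty slide; warns
    when SDs (single cell) or NCR statistics (no nuclei) are undefined.
    """
    df = records if isinstance(records, pd.DataFrame) else _records_to_frame(records)
    if len(df) == 0:
        raise ValueError("cannot summarise a slide with no cells")
    n = len(df)
    has_nuc = df["sn"].notna() if "sn" in df else pd.Series(False, index=df.index)
    n_nuc = int(has_nuc.sum())
    if n == 1:
        warnings.warn("single-cell slide: standard deviations are undefined", stacklevel=2)
    if n_nuc == 0:
        warnings.warn("no nucleus-assigned cells: SN/NCR statistics are null", stacklevel=2)

    sc_mean, sc_sd = _mean_sd(df["sc"].to_numpy(float))
    ep_mean, ep_sd = _mean_sd(df["ep"].to_numpy(float)) if "ep" in df else (None, None)
    sn_mean, sn_sd = _mean_sd(df["sn"].to_numpy(float)) if "sn" in df else (None, None)
    ncr_mean, ncr_sd = _mean_sd(df["ncr"].to_numpy(float)) if "ncr" in df else (None, None)

    return SlideSummary(
        slide_id=slide_id,
        n_cells=n,
        n_with_nucleus=n_nuc,
        sc_mean=sc_mean,
        sc_sd=sc_sd,
        sn_mean=sn_mean,
        sn_sd=sn_sd,
        ep_mean=ep_mean,
        ep_sd=ep_sd,
        ncr_mean=ncr_mean,
        ncr_sd=ncr_sd,
        included=n >= min_cells,
    )


def summarize_cohort(
    features: pd.DataFrame,
    min_cells: int = DEFAULT_MIN_CELLS,
    by: str = "slide_id",
) -> pd.DataFrame:
    """Per-slide summary table from a pooled per-cell feature table.

    ``by`` may name any grouping column, e.g. a patient key to pool
    multiple sections of one case.
    """
    if by not in features.columns:
        raise ValueError(f"feature table has no {by!r} column")
    rows = []
    for sid, grp in features.groupby(by, sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(summarize_slide(grp, min_cells=min_cells, slide_id=str(sid)).to_dict())
    return pd.DataFrame(rows)


def histogram_data(
    records: Sequence[CellRecord] | pd.DataFrame,
    feature: str,
    n_bins: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges and counts for one feature; counts sum to n non-null."""
    df = records if isinstance(records, pd.DataFrame) else _records_to_frame(records)
    if feature not in _FEATURES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {_FEATURES}")
    values = df[feature].to_numpy(float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError(f"no non-null values for feature {feature!r}")
    counts, edges = np.histogram(values, bins=n_bins)
    return edges, counts


def scatter3d_data(records: Sequence[CellRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-cell (SC, SN, NCR, EP) table over nucleus-assigned cells only,
    the coordinates of the 3-D scatter view of a slide's cell population."""
    df = records if isinstance(records, pd.DataFrame) else _records_to_frame(records)
    out = df.loc[df["sn"].notna(), ["sc", "sn", "ncr", "ep"]].reset_index(drop=True)
    return out
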