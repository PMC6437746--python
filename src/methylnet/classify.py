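"""Percentile-tail classification of differentially methylated regions.

Fold change at a DMR is the ratio of mean case methylation to mean control
methylation.  Low-methylated genes (LMGs) are DMRs whose fold change lies
strictly below the 5th percentile of the fold-change distribution;
high-methylated genes (HMGs) lie strictly above the 95th percentile.
Percentiles use linear interpolation between order statistics, so with 841
distinct fold values each tail contains exactly 42 DMRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedFoldError",
    "ClassDegeneracyError",
    "GeneClassSet",
    "compute_fold_change",
    "percentile_threshold",
    "classify_lmg_hmg",
    "write_class_file",
    "read_class_file",
]

logger = logging.getLogger(__name__)

#: Minimum number of finite fold values below which the 5%/95% tails degenerate.
MIN_RECORDS = 20


class UndefinedFoldError(ValueError):
    """Fold change is undefined because the control mean is zero."""


class ClassDegeneracyError(ValueError):
    """Too few usable records for percentile-tail classification."""


@dataclass
class GeneClassSet:
    """LMG/HMG membership with the realized percentile thresholds."""

    lmg: pd.DataFrame
    hmg: pd.DataFrame
    threshold_low: float
    threshold_high: float

    def __post_init__(self) -> None:
        overlap = set(self.lmg["node_id"]) & set(self.hmg["node_id"])
        if overlap:
            raise ValueError(f"LMG and HMG classes overlap: {sorted(overlap)[:5]}")


def compute_fold_change(mean_case: float, mean_ctrl: float) -> float:
    """Case/control ratio of group mean methylation levels."""
    if mean_ctrl == 0:
        raise UndefinedFoldError("fold change undefined for mean_ctrl = 0")
    return mean_case / mean_ctrl


def percentile_threshold(values: np.ndarray, q: float) -> float:
    """Empirical q-th percentile with linear interpolation between order
    statistics (rank h = (n-1) q/100 + 1 on the sorted values)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of an empty vector is undefined")
    if not 0 < q < 100:
        raise ValueError("q must lie strictly between 0 and 100")
    return float(np.percentile(values, q, method="linear"))


def classify_lmg_hmg(
    dmrs: pd.DataFrame, percentile_low: float = 5.0, percentile_high: float = 95.0
) -> GeneClassSet:
    """Split a DMR table into LMG and HMG percentile tails.

    Records with missing or non-finite fold change (e.g. zero control mean)
    are dropped with a warning before the thresholds are computed.  Membership
    uses strict inequalities, so values tied with a threshold belong to
    neither class.
    """
    if percentile_low >= percentile_high:
        raise ValueError("percentile_low must be below percentile_high")
    fold = pd.to_numeric(dmrs["fold_change"], errors="coerce")
    usable = dmrs[np.isfinite(fold)].copy()
    n_dropped = len(dmrs) - len(usable)
    if n_dropped:
        logger.warning("dropped %d DMRs with undefined fold change", n_dropped)
    if len(usable) < MIN_RECORDS:
        raise ClassDegeneracyError(
            f"need at least {MIN_RECORDS} records with finite fold change, got {len(usable)}"
        )
    fold = usable["fold_change"].to_numpy(dtype=float)
    lo = percentile_threshold(fold, percentile_low)
    hi = percentile_threshold(fold, percentile_high)
    lmg = usable[fold < lo].reset_index(drop=True)
    hmg = usable[fold > hi].reset_index(drop=True)
    logger.info(
        "classified %d LMGs (fold < %.4g) and %d HMGs (fold > %.4g) from %d DMRs",
        len(lmg), lo, len(hmg), hi, len(usable),
    )
    return GeneClassSet(lmg=lmg, hmg=hmg, threshold_low=lo, threshold_high=hi)


def write_class_file(classes: GeneClassSet, path) -> None:
    """Write the two-column (node_id, class) membership file."""
    rows = pd.concat(
        [
            pd.DataFrame({"node_id": classes.lmg["node_id"], "class": "LMG"}),
            pd.DataFrame({"node_id": classes.hmg["node_id"], "class": "HMG"}),
        ],
        ignore_index=True,
    )
    rows.to_csv(path, sep="\t", index=False)


def read_class_file(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"node_id": str, "class": str})
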