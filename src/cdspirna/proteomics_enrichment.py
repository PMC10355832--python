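"""Proximity-labeling (TurboID) spectral-count normalization and enrichment.

Raw spectral counts per protein and run receive a pseudo value of 0.5, are
normalized to the run's total adjusted counts, and bait-vs-control
enrichment is tested with a two-tailed unpaired t-test.  ``significant``
marks p < 0.01; a volcano *hit* additionally requires enrichment at or
above ``min_enrichment`` (default 2), the package's criterion for a
bait-specific interactor.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normalize_counts", "enrichment_test"]

PSEUDO = 0.5
P_CUTOFF = 0.01


def normalize_counts(
    count_table: pd.DataFrame,
    pseudo: float = PSEUDO,
    per_condition: dict[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Adjusted = raw + pseudo; normalized = adjusted / column total.

    Columns are runs, rows proteins; each normalized column sums to 1.
    With ``per_condition`` (condition → run columns) the denominator is the
    condition's pooled adjusted total instead of the per-run total.
    """
    if count_table.empty:
        raise ValueError("empty count table")
    if (count_table < 0).any().any():
        raise ValueError("counts must be >= 0")
    adjusted = count_table.astype(float) + pseudo
    if per_condition is None:
        return adjusted / adjusted.sum(axis=0)
    out = adjusted.copy()
    for runs in per_condition.values():
        runs = list(runs)
        total = adjusted[runs].to_numpy().sum()
        out[runs] = adjusted[runs] / total
    return out


def enrichment_test(
    normalized: pd.DataFrame,
    bait_runs: Sequence[str],
    control_runs: Sequence[str],
    welch: bool = False,
    p_cutoff: float = P_CUTOFF,
    min_enrichment: float = 2.0,
) -> pd.DataFrame:
    """Per-protein bait/control enrichment with a two-tailed unpaired t-test.

    enrichment = mean(bait) / mean(control) of normalized values; Student's
    pooled-variance test by default, Welch by flag.  Groups of fewer than
    two runs leave p undefined while enrichment is still reported.
    """
    bait = normalized[list(bait_runs)].to_numpy(float)
    ctrl = normalized[list(control_runs)].to_numpy(float)
    enr = bait.mean(axis=1) / ctrl.mean(axis=1)
    if bait.shape[1] >= 2 and ctrl.shape[1] >= 2:
        p = stats.ttest_ind(bait, ctrl, axis=1, equal_var=not welch).pvalue
        p = np.where(np.isnan(p), 1.0, p)
    else:
        p = np.full(len(enr), np.nan)
    df = pd.DataFrame(
        {
            "enrichment": enr,
            "p": p,
            "significant": p < p_cutoff,
            "hit": (p < p_cutoff) & (enr >= min_enrichment),
        },
        index=normalized.index,
    )
    return df
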