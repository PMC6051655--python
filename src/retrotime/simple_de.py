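"""Averaged-time-point differential expression by equal-variance t-test.

The alternative to the time-course fit: average the mid-starvation time
points (15, 30, 72 h) against the three control libraries, apply an
unpaired two-tailed pooled-variance Student's t-test per feature, and
threshold.  Repeat mode keeps p < 0.05 only; gene mode additionally
requires |fold change| > 2 and an average of at least 5 counts over the six
samples.  Up/down sets are split by the sign of the group-mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DESetResult", "averaged_t_test", "select_de"]

STARVED_DE_TIMES = (15.0, 30.0, 72.0)   # study's averaged starvation points
CONTROL_DE_TIMES = (6.0, 30.0, 120.0)


@dataclass
class DESetResult:
    table: pd.DataFrame              # mean_a, mean_b, log2fc, t, p, degenerate
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    filters: dict = field(default_factory=dict)
    n_nan_excluded: int = 0

    def write_lists(self, up_path: str | Path, down_path: str | Path) -> None:
        Path(up_path).write_text("".join(f"{x}\n" for x in self.up))
        Path(down_path).write_text("".join(f"{x}\n" for x in self.down))


def averaged_t_test(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature pooled-variance t-test of group_a (e.g. starved) vs
    group_b (controls).

    Returns a frame with group means, log2 fold change
    ``log2((mean_a + pc) / (mean_b + pc))``, the t statistic with
    ``n_a + n_b - 2`` degrees of freedom, and the two-tailed p.  Features
    where both groups are constant and equal get t=0, p=1; constant but
    unequal groups get p=0 and are flagged ``degenerate``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = values[group_a].to_numpy(dtype=float)
    b = values[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    df = na + nb - 2

    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        degenerate = (se == 0) & (diff != 0)
        zero_flat = (se == 0) & (diff == 0)
        t = np.where(zero_flat, 0.0, t)
        p = np.where(zero_flat, 1.0, p)
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
        p = np.where(degenerate, 0.0, p)
        # negative input values (allowed for generic matrices) yield NaN FC
        log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc,
         "t": t, "p": p, "degenerate": degenerate},
        index=values.index,
    )


def select_de(
    results: pd.DataFrame,
    p_max: float = 0.05,
    min_fc: float | None = None,
    min_avg_count: float | None = None,
    avg_counts: pd.Series | None = None,
) -> DESetResult:
    """Threshold the t-test table into up/down sets.

    Repeat mode (defaults): p < p_max only.  Gene mode: additionally
    |FC| > min_fc and, when *min_avg_count* is given, the feature's average
    count over the compared samples (supplied via *avg_counts*) >= that
    floor.  NaN p-values are excluded and counted.
    """
    table = results.copy()
    nan_mask = table["p"].isna()
    n_nan = int(nan_mask.sum())
    table = table[~nan_mask]

    keep = table["p"] < p_max
    if min_fc is not None:
        keep &= np.abs(table["log2fc"]) > np.log2(min_fc)
    if min_avg_count is not None:
        if avg_counts is None:
            raise ValueError("min_avg_count filter needs avg_counts")
        keep &= avg_counts.reindex(table.index) >= min_avg_count
    kept = table[keep]
    up = list(kept.index[kept["mean_a"] > kept["mean_b"]])
    down = list(kept.index[kept["mean_a"] < kept["mean_b"]])
    return DESetResult(
        table=results,
        up=up,
        down=down,
        filters={"p_max": p_max, "min_fc": min_fc, "min_avg_count": min_avg_count},
        n_nan_excluded=n_nan,
    )
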