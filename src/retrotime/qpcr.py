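"""Efficiency-corrected relative qPCR quantification (Pfaffl method).

The expression ratio of a target gene in a sample relative to a control,
normalized to a reference gene, is

    ratio = E_target ** (Ct_target(control) - Ct_target(sample))
          / E_reference ** (Ct_ref(control) - Ct_ref(sample))

where E is the primer amplification efficiency per cycle (E = 2 means
perfect doubling).  Ratios are computed per technical replicate and then
summarized (mean +/- SD, SEM, or range), with the control condition pinned
at fold change 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QpcrRecord",
    "pfaffl_ratio",
    "summarize_replicates",
    "quantify_qpcr_table",
]


@dataclass(frozen=True)
class QpcrRecord:
    sample: str
    condition: str
    gene: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (self.ct > 0 and math.isfinite(self.ct)):
            raise ValueError(f"Ct must be finite and > 0, got {self.ct}")


def _check_efficiency(e: float, label: str) -> None:
    if not 1.0 < e <= 2.0:
        raise ValueError(f"{label} efficiency must be in (1, 2], got {e}")


def pfaffl_ratio(
    ct_target_control: float,
    ct_target_sample: float,
    ct_ref_control: float,
    ct_ref_sample: float,
    e_target: float = 2.0,
    e_reference: float = 2.0,
) -> float:
    """Efficiency-corrected expression ratio of sample vs control."""
    _check_efficiency(e_target, "target")
    _check_efficiency(e_reference, "reference")
    for label, ct in (("target/control", ct_target_control),
                      ("target/sample", ct_target_sample),
                      ("reference/control", ct_ref_control),
                      ("reference/sample", ct_ref_sample)):
        if ct is None or not math.isfinite(ct):
            raise ValueError(f"missing or non-finite Ct for {label}")
    dct_target = ct_target_control - ct_target_sample
    dct_ref = ct_ref_control - ct_ref_sample
    # log-space for numerical stability at large |dCt|
    return math.exp(dct_target * math.log(e_target)
                    - dct_ref * math.log(e_reference))


def summarize_replicates(
    ratios: Sequence[float],
    scheme: str = "mean_sd",
) -> dict[str, float | None]:
    """Mean and dispersion of per-replicate fold-change ratios.

    ``mean_sd``: sample SD (ddof=1); ``mean_sem``: SD/sqrt(n) across
    independent experiments; ``mean_range``: half the max-min span.
    With a single replicate the dispersion is reported as absent (None).
    """
    if len(ratios) < 1:
        raise ValueError("need at least one replicate")
    arr = np.asarray(ratios, dtype=float)
    mean = float(arr.mean())
    if arr.size == 1:
        return {"mean": mean, "dispersion": None, "n": 1}
    if scheme == "mean_sd":
        disp = float(arr.std(ddof=1))
    elif scheme == "mean_sem":
        disp = float(arr.std(ddof=1) / math.sqrt(arr.size))
    elif scheme == "mean_range":
        disp = float((arr.max() - arr.min()) / 2.0)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return {"mean": mean, "dispersion": disp, "n": int(arr.size)}


def quantify_qpcr_table(
    records: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    efficiencies: Mapping[str, float] | None = None,
    scheme: str = "mean_sd",
) -> pd.DataFrame:
    """Fold changes vs control for every (condition, target gene) block.

    *records* is long-format with columns sample, condition, gene, ct,
    replicate.  Ratios are computed per replicate (pairing replicate i of
    the target with replicate i of the reference in both conditions), then
    summarized.  Genes without a supplied efficiency default to E = 2.
    """
    required = {"condition", "gene", "ct", "replicate"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    eff = dict(efficiencies or {})

    def e_of(gene: str) -> float:
        return eff.get(gene, 2.0)

    def ct_by_rep(condition: str, gene: str) -> dict[int, float]:
        block = records[(records["condition"] == condition)
                        & (records["gene"] == gene)]
        if block.empty:
            raise ValueError(f"no Ct rows for gene {gene!r} in condition {condition!r}")
        return dict(zip(block["replicate"], block["ct"]))

    targets = sorted(set(records["gene"]) - {reference_gene})
    conditions = [c for c in pd.unique(records["condition"])]
    ref_ctrl = ct_by_rep(control_condition, reference_gene)
    rows = []
    for gene in targets:
        tgt_ctrl = ct_by_rep(control_condition, gene)
        for cond in conditions:
            tgt = ct_by_rep(cond, gene)
            ref = ct_by_rep(cond, reference_gene)
            reps = sorted(set(tgt) & set(ref) & set(tgt_ctrl) & set(ref_ctrl))
            if not reps:
                raise ValueError(
                    f"no matched replicates for {gene!r} in {cond!r}")
            ratios = [
                pfaffl_ratio(tgt_ctrl[r], tgt[r], ref_ctrl[r], ref[r],
                             e_of(gene), e_of(reference_gene))
                for r in reps
            ]
            summary = summarize_replicates(ratios, scheme=scheme)
            rows.append({
                "gene": gene, "condition": cond,
                "fold_change": summary["mean"],
                "dispersion": summary["dispersion"],
                "n_replicates": summary["n"],
            })
    return pd.DataFrame(rows)


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    return frame
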