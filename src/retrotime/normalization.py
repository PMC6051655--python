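"""Between-sample normalization and negative-binomial dispersion.

TMM (trimmed mean of M-values) scaling factors are computed against a
reference sample with the canonical 30% / 5% trims on M and A, weighted by
the inverse asymptotic (binomial) variance of M, and rescaled so their
geometric mean is 1.  Effective library size = raw library size x factor.

RPKM = count / (feature length in kb x effective library size in millions).

Dispersion uses the NB parameterization variance = mu + d * mu**2, so
theta = 1/d is the "size" parameter of the distribution.  A single common d
is estimated by method of moments on library-size-scaled counts, averaging
per-feature max(0, (s^2 - mu)/mu^2); d = 0 is the Poisson limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counting import CountsMatrix

__all__ = [
    "NormalizationResult",
    "tmm_factors",
    "rpkm",
    "estimate_common_dispersion",
    "normalize",
]


@dataclass
class NormalizationResult:
    """TMM factors, effective library sizes, and common dispersion."""

    factors: pd.Series            # per sample, geometric mean 1
    library_sizes: pd.Series      # raw column sums
    dispersion: float             # d >= 0
    samples: list[str]

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors

    @property
    def theta(self) -> float:
        """NB size parameter 1/d (+inf at the Poisson limit d=0)."""
        return np.inf if self.dispersion == 0 else 1.0 / self.dispersion

    def to_json(self, path: str | Path) -> None:
        payload = {
            "factors": self.factors.to_dict(),
            "library_sizes": {k: int(v) for k, v in self.library_sizes.items()},
            "dispersion": self.dispersion,
            "samples": self.samples,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationResult":
        payload = json.loads(Path(path).read_text())
        samples = payload["samples"]
        return cls(
            factors=pd.Series(payload["factors"]).reindex(samples),
            library_sizes=pd.Series(payload["library_sizes"]).reindex(samples),
            dispersion=float(payload["dispersion"]),
            samples=samples,
        )


def _pick_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Sample whose upper-quartile (of depth-scaled counts) is closest to the
    mean upper-quartile."""
    scaled = counts / lib_sizes
    uq = np.array([np.quantile(scaled[:, j][scaled[:, j] > 0], 0.75)
                   if (scaled[:, j] > 0).any() else 0.0
                   for j in range(counts.shape[1])])
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float, weights: str) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if weights == "proportion":
        # delta-method variance of M at a common nominal depth: depends on
        # the count proportions only, so rescaling one sample's counts (a
        # pure depth change) leaves every factor untouched
        w = (1.0 - p_obs) / p_obs + (1.0 - p_ref) / p_ref
    elif weights == "library":
        # per-library binomial variance (the edgeR convention)
        w = (n_obs - obs[keep]) / (n_obs * obs[keep]) \
            + (n_ref - ref[keep]) / (n_ref * ref[keep])
    else:
        raise ValueError(f"weights must be 'proportion' or 'library', got {weights!r}")
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # pure depth difference
        return 1.0
    # double trim: drop the extreme trim_m tail fraction of M and trim_a of A
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f)


def tmm_factors(
    counts: CountsMatrix | pd.DataFrame,
    ref_sample: str | None = None,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    weights: str = "proportion",
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    Features with a zero in either the sample or the reference are excluded
    from each pairwise comparison.  Raises on a sample with all-zero counts.

    ``weights="proportion"`` (default) computes the inverse-variance weights
    from count proportions at a common nominal depth, making the factors
    exactly invariant to rescaling any single sample's counts;
    ``weights="library"`` uses the per-library binomial variances (edgeR's
    convention), which agrees with that tool to machine precision but is
    only approximately depth-invariant.  The two differ by well under 1%
    on typical matrices.
    """
    frame = counts.counts if isinstance(counts, CountsMatrix) else counts
    if frame.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    mat = frame.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    zero = lib <= 0
    if zero.any():
        bad = list(frame.columns[zero])
        raise ValueError(f"samples with all-zero counts: {bad}")
    if ref_sample is None:
        ref_idx = _pick_reference(mat, lib)
    else:
        ref_idx = frame.columns.get_loc(ref_sample)
    factors = np.array([
        1.0 if j == ref_idx else _tmm_pair(mat[:, j], mat[:, ref_idx],
                                           lib[j], lib[ref_idx],
                                           trim_M, trim_A, weights)
        for j in range(mat.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=frame.columns, name="tmm_factor")


def rpkm(counts: CountsMatrix, norm: NormalizationResult) -> pd.DataFrame:
    """Reads per kilobase per million effective library reads."""
    if (counts.lengths <= 0).any():
        raise ValueError("feature lengths must be positive for RPKM")
    eff = norm.effective_library_sizes.reindex(counts.samples)
    kb = counts.lengths.to_numpy()[:, None] / 1e3
    millions = eff.to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        counts.counts.to_numpy() / (kb * millions),
        index=counts.counts.index, columns=counts.counts.columns,
    )


def estimate_common_dispersion(
    counts: CountsMatrix | pd.DataFrame,
    groups: Sequence[str] | None = None,
    factors: pd.Series | None = None,
) -> float:
    """Pooled NB dispersion d by method of moments.

    Counts are scaled to a common depth using effective library sizes; the
    per-feature moment estimate (s^2 - mu)/mu^2 is floored at 0 and averaged
    over features with positive mean.  With *groups*, moments are taken
    within each group of >=2 samples and pooled, so real between-group
    signal does not inflate d.
    """
    frame = counts.counts if isinstance(counts, CountsMatrix) else counts
    if frame.shape[1] < 2:
        raise ValueError("dispersion estimation needs at least 2 samples")
    lib = frame.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(frame.columns)
    scale = lib.mean() / lib
    scaled = frame.to_numpy(dtype=float) * scale.to_numpy()[None, :]

    if groups is None:
        group_cols = [np.arange(frame.shape[1])]
    else:
        groups = np.asarray(groups)
        group_cols = [np.where(groups == g)[0] for g in pd.unique(groups)]
        group_cols = [c for c in group_cols if c.size >= 2]
        if not group_cols:
            raise ValueError("no group has >= 2 samples")

    ests = []
    for cols in group_cols:
        block = scaled[:, cols]
        mu = block.mean(axis=1)
        s2 = block.var(axis=1, ddof=1)
        ok = mu > 0
        if ok.any():
            ests.append(np.maximum(0.0, (s2[ok] - mu[ok]) / mu[ok] ** 2))
    if not ests:
        return 0.0
    return float(np.concatenate(ests).mean())


def normalize(
    counts: CountsMatrix,
    groups: Sequence[str] | None = None,
    ref_sample: str | None = None,
) -> NormalizationResult:
    """One-stop TMM + dispersion estimate for a counts matrix."""
    factors = tmm_factors(counts, ref_sample=ref_sample)
    d = estimate_common_dispersion(counts, groups=groups, factors=factors)
    return NormalizationResult(
        factors=factors,
        library_sizes=counts.library_sizes(),
        dispersion=d,
        samples=counts.samples,
    )
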