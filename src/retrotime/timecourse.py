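"""Two-stage negative-binomial time-course selection and profile clustering.

Each feature's counts are modelled by an NB log-link regression on a
polynomial of time with series (starved vs control) main and interaction
terms, a fixed size parameter theta = 1/d from the normalization stage, and
log effective library sizes as offsets:

    log mu = b0 + sum_k b_k t^k + g0 * starved + sum_k g_k starved * t^k

Stage 1 screens features by the likelihood-ratio test of the full model
against intercept-only, FDR-adjusted (Benjamini-Hochberg) at Q.  Stage 2
runs backward stepwise elimination on the surviving terms (drop the worst
Wald p > alpha, refit, repeat) and requires the final model's deviance
r^2 = 1 - residual/null deviance to reach r2_min.  Selected features are
clustered on z-scored RPKM profiles (control then starved, by time) with
correlation distance and average linkage, and cluster labels are ordered so
that clusters rising late in starvation come first.

With one library per (series, time) point there are no replicates;
inference leans entirely on the externally fixed theta.  This mirrors the
study design and is a real limitation, stated in the package docs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .counting import CountsMatrix, SampleSheet
from .normalization import NormalizationResult, rpkm

__all__ = [
    "TimecourseConfig",
    "TimecourseResult",
    "make_design",
    "fit_global_nb",
    "stepwise_select",
    "select_and_cluster",
    "run_timecourse",
]

logger = logging.getLogger(__name__)


@dataclass
class TimecourseConfig:
    degree: int = 2
    Q: float = 0.01              # global FDR cutoff
    alpha_step: float = 0.05     # per-term stepwise threshold
    r2_min: float = 0.7          # goodness-of-fit cutoff
    k_clusters: int = 4
    log_time: bool = False       # design on log2(hours) instead of raw hours
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.Q < 1:
            raise ValueError("Q must be in (0,1)")
        if not 0 < self.alpha_step <= 1:
            raise ValueError("alpha_step must be in (0,1]")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must be in [0,1]")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


@dataclass
class Design:
    matrix: np.ndarray           # samples x terms, intercept first
    term_names: list[str]
    sample_ids: list[str]

    @property
    def n_terms(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TimecourseResult:
    """Per-feature selection table plus the clustered profile matrix."""

    table: pd.DataFrame          # p_global, p_adj, r2, terms, selected, cluster
    profiles: pd.DataFrame | None = None   # z-scored RPKM of selected features
    config: TimecourseConfig = field(default_factory=TimecourseConfig)

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def cluster_members(self) -> dict[int, list[str]]:
        sel = self.table[self.table["selected"]]
        return {int(c): list(g.index) for c, g in sel.groupby("cluster")}


def make_design(samples: SampleSheet, degree: int = 2, log_time: bool = False) -> Design:
    """Design matrix: intercept, centered time powers, starved dummy,
    starved x time-power interactions."""
    frame = samples.frame
    if set(frame["series"]) != {"control", "starved"}:
        raise ValueError("both control and starved series are required")
    t = frame["time_h"].to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time points")
    if log_time:
        t = np.log2(t)
    tc = t - t.mean()
    starved = (frame["series"] == "starved").astype(float).to_numpy()
    cols = [np.ones_like(tc)]
    names = ["intercept"]
    for k in range(1, degree + 1):
        cols.append(tc ** k)
        names.append(f"time^{k}")
    cols.append(starved)
    names.append("starved")
    for k in range(1, degree + 1):
        cols.append(starved * tc ** k)
        names.append(f"starved:time^{k}")
    return Design(matrix=np.column_stack(cols), term_names=names,
                  sample_ids=list(frame.index))


def _nb_family(theta: float):
    if np.isinf(theta):
        return sm.families.Poisson()
    return sm.families.NegativeBinomial(alpha=1.0 / theta)


def _fit(y: np.ndarray, X: np.ndarray, offset: np.ndarray, theta: float,
         max_iter: int = 100):
    model = sm.GLM(y, X, family=_nb_family(theta), offset=offset)
    return model.fit(maxiter=max_iter, tol=1e-8)


def fit_global_nb(
    y: np.ndarray,
    design: Design,
    offsets: np.ndarray,
    theta: float,
    max_iter: int = 100,
) -> dict:
    """Fit full and intercept-only NB models for one feature.

    Returns a dict with the global LRT p-value, deviance r^2, the fitted
    full-model result (for stepwise), and a convergence flag.
    """
    out = {"p_global": np.nan, "r2": np.nan, "fit": None, "null_deviance": np.nan,
           "converged": False}
    try:
        full = _fit(y, design.matrix, offsets, theta, max_iter)
        null = _fit(y, design.matrix[:, :1], offsets, theta, max_iter)
    except (PerfectSeparationError, ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("feature fit failed: %s", exc)
        return out
    if not np.all(np.isfinite(full.params)):
        return out
    lr = max(0.0, null.deviance - full.deviance)
    df = design.n_terms - 1
    out["p_global"] = float(stats.chi2.sf(lr, df))
    if null.deviance > 0:
        out["r2"] = float(np.clip(1.0 - full.deviance / null.deviance, 0.0, 1.0))
    else:
        out["r2"] = 0.0
    out["fit"] = full
    out["null_deviance"] = float(null.deviance)
    out["converged"] = bool(full.converged and null.converged)
    return out


def stepwise_select(
    y: np.ndarray,
    design: Design,
    offsets: np.ndarray,
    theta: float,
    alpha_step: float = 0.05,
    null_deviance: float | None = None,
    max_iter: int = 100,
) -> tuple[list[str], float]:
    """Backward elimination of non-intercept terms by Wald p.

    Repeatedly drops the term with the largest Wald p above *alpha_step* and
    refits, until every retained term passes.  Returns (retained term names,
    final-model deviance r^2).  An empty retained set yields r^2 = 0.
    """
    active = list(range(design.n_terms))  # column indices; 0 = intercept
    if null_deviance is None:
        null_deviance = float(_fit(y, design.matrix[:, :1], offsets, theta,
                                   max_iter).deviance)
    while True:
        X = design.matrix[:, active]
        fit = _fit(y, X, offsets, theta, max_iter)
        pvals = np.asarray(fit.pvalues)
        # positions of non-intercept terms within the active set
        cand = [i for i, col in enumerate(active) if col != 0]
        if not cand:
            return [], 0.0
        worst = max(cand, key=lambda i: (pvals[i] if np.isfinite(pvals[i]) else np.inf))
        worst_p = pvals[worst]
        if np.isfinite(worst_p) and worst_p <= alpha_step:
            retained = [design.term_names[active[i]] for i in cand]
            r2 = 0.0
            if null_deviance > 0:
                r2 = float(np.clip(1.0 - fit.deviance / null_deviance, 0.0, 1.0))
            return retained, r2
        active.pop(worst)
        if len(active) == 1:  # intercept only left
            return [], 0.0


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def adjust_and_select(table: pd.DataFrame, config: TimecourseConfig) -> pd.DataFrame:
    """BH-adjust the global p-values and flag features passing both the
    FDR cutoff Q and the final-model r^2 floor."""
    table = table.copy()
    tested = table["p_global"].notna()
    adj = np.full(len(table), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = multipletests(
            table.loc[tested, "p_global"], method="fdr_bh")[1]
    table["p_adj"] = adj
    table["selected"] = (
        tested & (table["p_adj"] <= config.Q) & (table["r2"] >= config.r2_min)
    )
    return table


def _sample_order(samples: SampleSheet) -> list[str]:
    """Control samples by time, then starved samples by time."""
    order = []
    for series in ("control", "starved"):
        order += sorted(samples.samples_in(series),
                        key=lambda s: samples.frame.loc[s, "time_h"])
    return order


def cluster_profiles(
    profiles: pd.DataFrame,
    samples: SampleSheet,
    k: int,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster expression profiles into k groups.

    Rows are z-scored, distances are correlation distances, linkage is
    average, and the tree is cut at k clusters.  Labels are renumbered so
    the cluster with the highest mean z at the late starvation time points
    is cluster 1 (up-clusters first).  Returns (labels, z-scored profiles
    in control-then-starved column order).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} features to cluster")
    order = _sample_order(samples)
    prof = profiles[order]
    z = _zscore_rows(prof.to_numpy(dtype=float))
    zframe = pd.DataFrame(z, index=profiles.index, columns=order)

    if len(profiles) == 1 or k == 1:
        labels = np.ones(len(profiles), dtype=int)
    else:
        link = sch.linkage(z, method="average", metric="correlation")
        labels = sch.fcluster(link, t=k, criterion="maxclust")

    starved_sorted = sorted(samples.samples_in("starved"),
                            key=lambda s: samples.frame.loc[s, "time_h"])
    late = starved_sorted[len(starved_sorted) // 2:]
    late_mean = {c: zframe.loc[labels == c, late].mean().mean()
                 for c in np.unique(labels)}
    rank = {c: i + 1 for i, c in enumerate(
        sorted(late_mean, key=late_mean.get, reverse=True))}
    relabelled = pd.Series([rank[c] for c in labels], index=profiles.index,
                           name="cluster")
    return relabelled, zframe


def select_and_cluster(
    table: pd.DataFrame,
    profiles: pd.DataFrame,
    samples: SampleSheet,
    config: TimecourseConfig,
) -> TimecourseResult:
    """BH adjustment, joint (adj-p, r^2) selection, and profile clustering.

    *profiles* holds per-sample RPKM for every tested feature; clustering
    uses z-scored rows, correlation distance, average linkage, and a k-way
    cut.  Cluster ids are relabelled so clusters with the highest mean
    late-starvation z come first (up-clusters before down-clusters).
    """
    table = adjust_and_select(table, config)
    table["cluster"] = pd.array([pd.NA] * len(table), dtype="Int64")

    sel_ids = list(table.index[table["selected"]])
    if not sel_ids:
        raise ValueError("no feature passed selection; nothing to cluster")
    labels, zframe = cluster_profiles(profiles.loc[sel_ids], samples,
                                      config.k_clusters)
    table.loc[sel_ids, "cluster"] = labels

    return TimecourseResult(table=table, profiles=zframe, config=config)


def run_timecourse(
    counts: CountsMatrix,
    samples: SampleSheet,
    norm: NormalizationResult,
    config: TimecourseConfig | None = None,
    cluster: bool = True,
) -> TimecourseResult:
    """Full two-stage selection over a counts matrix, then clustering.

    With ``cluster=False`` only the selection table is produced (useful when
    nothing is expected to pass, e.g. on null data)."""
    config = config or TimecourseConfig()
    design = make_design(samples, degree=config.degree, log_time=config.log_time)
    offsets = np.log(norm.effective_library_sizes.reindex(design.sample_ids)
                     .to_numpy(dtype=float))
    theta = norm.theta
    mat = counts.counts[design.sample_ids].to_numpy()

    rows = []
    for i, feat in enumerate(counts.features):
        y = mat[i]
        res = fit_global_nb(y, design, offsets, theta, config.max_iter)
        terms: list[str] = []
        r2_final = res["r2"]
        if res["fit"] is not None and np.isfinite(res["p_global"]):
            terms, r2_final = stepwise_select(
                y, design, offsets, theta, config.alpha_step,
                null_deviance=res["null_deviance"], max_iter=config.max_iter)
        rows.append({
            "feature": feat,
            "p_global": res["p_global"],
            "r2": r2_final,
            "r2_full": res["r2"],
            "terms": ",".join(terms),
            "unfit": res["fit"] is None,
        })
    table = pd.DataFrame(rows).set_index("feature")

    if not cluster:
        table = adjust_and_select(table, config)
        table["cluster"] = pd.array([pd.NA] * len(table), dtype="Int64")
        return TimecourseResult(table=table, profiles=None, config=config)
    profiles = rpkm(counts, norm)
    return select_and_cluster(table, profiles, samples, config)
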