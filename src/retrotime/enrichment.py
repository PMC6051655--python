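"""Fisher exact enrichment of repeat classes/families and GMT-based ORA.

Class/family enrichment compares the composition of a selected subfamily
set (a cluster, or the up/down lists) against the full taxonomy of genomic
repeat subfamilies via a 2x2 Fisher exact test per category.  The same
machinery drives gene-set overrepresentation against a GMT collection with
a one-sided (greater) test, BH adjustment, and an adjusted-p cutoff.

Two-sided p is the exact hypergeometric sum of all tables (at fixed
margins) whose probability does not exceed the observed table's, with a
1e-12 relative slack for ties.  The odds ratio is the sample estimate
(a*d)/(b*c), with the Haldane 0.5 continuity correction when any cell is 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .repeat_annotation import RepeatTaxonomy

__all__ = [
    "fisher_exact_2x2",
    "class_enrichment",
    "ora_gmt",
    "read_gmt",
]


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     sided: str = "two") -> tuple[float, float]:
    """Exact Fisher test of the table [[a, b], [c, d]].

    Returns ``(p, odds_ratio)``.  ``sided="two"`` sums hypergeometric
    probabilities <= the observed table's; ``sided="greater"`` is the upper
    tail on cell a.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"cell {name} is negative ({v})")
    n = a + b + c + d
    row1 = a + b        # set size
    col1 = a + c        # category size
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    if sided == "two":
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    elif sided == "greater":
        p = float(pmf[support >= a].sum())
    else:
        raise ValueError(f"sided must be 'two' or 'greater', got {sided!r}")
    p = min(1.0, p)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return p, float(odds)


def _enrich_frame(
    sets: Mapping[str, Sequence[str]],
    categories: Mapping[str, set[str]],
    background: set[str],
    sided: str,
) -> pd.DataFrame:
    rows = []
    for set_name, members in sets.items():
        members = set(members)
        stray = members - background
        if stray:
            raise KeyError(
                f"set {set_name!r} members absent from background: "
                f"{sorted(stray)[:5]}"
            )
        for cat_name, cat in categories.items():
            cat = cat & background
            a = len(members & cat)
            b = len(members - cat)
            c = len(cat - members)
            d = len(background) - a - b - c
            p, odds = fisher_exact_2x2(a, b, c, d, sided=sided)
            rows.append({
                "set": set_name, "category": cat_name,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds, "p": p,
                "background_size": len(background),
            })
    frame = pd.DataFrame(rows)
    frame["p_adj"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame


def class_enrichment(
    sets: Mapping[str, Sequence[str]],
    taxonomy: RepeatTaxonomy,
    level: str = "class_",
) -> pd.DataFrame:
    """Per-category Fisher enrichment of subfamily sets vs all genomic
    subfamilies.

    *sets* maps a set name (cluster id, "up", "down") to subfamily members.
    Raw two-sided p drives the significance tiers (p<0.05 -> "*",
    p<0.001 -> "***"); BH-adjusted p is reported alongside.
    """
    for name, members in sets.items():
        if not members:
            raise ValueError(f"set {name!r} is empty")
    background = set(taxonomy.parent)
    if level == "class_":
        names = sorted({c for _, c in taxonomy.parent.values()})
    elif level == "family":
        names = sorted({f for f, _ in taxonomy.parent.values()})
    else:
        raise ValueError("level must be 'class_' or 'family'")
    categories = {n: taxonomy.members(level, n) for n in names}
    frame = _enrich_frame(sets, categories, background, sided="two")
    frame["flag"] = np.select(
        [frame["p"] < 0.001, frame["p"] < 0.05], ["***", "*"], default="")
    return frame


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            name = fields[0]
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return sets


def ora_gmt(
    gene_list: Sequence[str],
    background: Sequence[str],
    gmt: str | Path | Mapping[str, set[str]],
    adj_p_max: float = 0.05,
) -> pd.DataFrame:
    """Overrepresentation of *gene_list* in GMT sets against *background*.

    One-sided (greater) Fisher per set after intersecting each set with the
    background; BH-adjusted p; ``significant`` marks adjusted p < adj_p_max.
    Rows are ranked by adjusted p, ties broken by descending odds ratio.
    """
    background_set = set(background)
    genes = set(gene_list)
    if not genes <= background_set:
        stray = sorted(genes - background_set)[:5]
        raise ValueError(f"gene list members outside background: {stray}")
    sets = read_gmt(gmt) if isinstance(gmt, (str, Path)) else dict(gmt)
    frame = _enrich_frame({"list": genes}, sets, background_set, sided="greater")
    frame = frame.drop(columns="set").rename(columns={"category": "gene_set"})
    frame["significant"] = frame["p_adj"] < adj_p_max
    frame = frame.sort_values(["p_adj", "odds_ratio"],
                              ascending=[True, False], kind="mergesort")
    return frame.reset_index(drop=True)
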