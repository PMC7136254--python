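"""Genome-wide Spearman screen of expression against mutation load.

Per cancer type, each gene's expression z-scores are rank-correlated with the
per-sample mutation load. Because cohort sizes differ between cancer types,
genes are thresholded by their *rank* in the per-cancer correlation ordering
(top-K positive / top-K negative lists) rather than by the correlation value
itself.

Spearman's rho is the Pearson correlation of average-ranked data (ties get
their average rank). The two-sided p-value uses the t approximation
``t = rho * sqrt((n-2)/(1-rho^2))`` with n-2 degrees of freedom for n > 10,
and exact enumeration of the n! rank permutations for n <= 10. A perfectly
monotone pair (|rho| = 1) gets the exact permutation probability 2/n!.

No multiple-testing correction is applied inside the screen — thresholding is
by rank, and within one cancer type n is constant so the rho ordering and the
p ordering coincide in the untied case. A Benjamini-Hochberg column is
emitted for information only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Permutation-count chunk for exact enumeration (bounds memory at ~n*1e5 floats).
_EXACT_CHUNK = 100_000


class SpearmanResult(NamedTuple):
    """Spearman correlation with its two-sided p-value.

    ``rho`` and ``p_value`` are NaN (an explicit NA, never a silent 0) when
    either input is constant and the correlation is undefined; ``note`` then
    carries the reason.
    """

    rho: float
    p_value: float
    n: int
    method: str
    note: str | None = None


def _rank_center(v: np.ndarray) -> np.ndarray:
    """Average ranks, centred. Mean rank is always (n+1)/2."""
    r = stats.rankdata(v)
    return r - (len(v) + 1) / 2.0


def _exact_perm_p(sx: np.ndarray, sy: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p: fraction of the n! orderings of the
    y-ranks whose |rho| >= |rho_obs| (ties enumerated with multiplicity)."""
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    thresh = (abs(rho_obs) - 1e-12) * denom
    n_ge = 0
    total = 0
    it = itertools.permutations(sy)
    while True:
        chunk = np.array(list(itertools.islice(it, _EXACT_CHUNK)))
        if chunk.size == 0:
            break
        dots = chunk @ sx
        n_ge += int(np.count_nonzero(np.abs(dots) >= thresh))
        total += len(chunk)
    return n_ge / total


def spearman(x: Sequence[float], y: Sequence[float],
             p_mode: Literal["auto", "asymptotic", "exact"] = "auto") -> SpearmanResult:
    """Spearman rank correlation of two vectors with a two-sided p-value.

    Pairs with a missing value in either vector are removed; at least 4
    complete pairs are required. ``p_mode="auto"`` enumerates exactly for
    n <= 10 and uses the t approximation above that; the other modes force
    one method (exact enumeration is factorial in n and refuses n > 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")

    sx = _rank_center(x)
    sy = _rank_center(y)
    ssx = float(sx @ sx)
    ssy = float(sy @ sy)
    if ssx == 0.0 or ssy == 0.0:
        which = "x" if ssx == 0.0 else "y"
        return SpearmanResult(math.nan, math.nan, n, "undefined",
                              note=f"constant {which}: correlation undefined")
    rho = float(sx @ sy) / math.sqrt(ssx * ssy)
    rho = max(-1.0, min(1.0, rho))

    if abs(rho) >= 1.0 - 1e-12 and p_mode != "exact":
        # exact probability of a perfectly monotone arrangement
        p = 2.0 * math.exp(-math.lgamma(n + 1))
        return SpearmanResult(rho, p, n, "exact-monotone")

    exact = p_mode == "exact" or (p_mode == "auto" and n <= 10)
    if exact:
        if n > 10:
            raise ValueError(f"exact enumeration limited to n <= 10 (got {n})")
        return SpearmanResult(rho, _exact_perm_p(sx, sy, rho), n, "exact")

    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, min(p, 1.0), n, "t-approx")


def _tie_break_order(df: pd.DataFrame, *, positive: bool) -> pd.Index:
    """Deterministic ordering for ranking and top-K cuts: strongest rho first,
    then smaller p, then lexicographic gene symbol."""
    rho_key = -df["rho"] if positive else df["rho"]
    order = np.lexsort((df["gene"].to_numpy(),
                        df["p_value"].to_numpy(),
                        rho_key.to_numpy()))
    return df.index[order]


def screen_cancer(expr: ExpressionMatrix, loads: pd.DataFrame,
                  load_class: Literal["all", "missense", "sense"] = "all",
                  min_samples: int = 20) -> pd.DataFrame:
    """Correlate every gene's expression with mutation load in one cohort.

    Parameters
    ----------
    expr
        Expression matrix (z-scores expected; a warning is logged otherwise).
    loads
        Load table indexed by sample (from ``mutation_load.compute_loads``).
    load_class
        Which load to rank against: every mutation event, missense only, or
        sense (synonymous) only.
    min_samples
        Minimum shared samples between the two inputs (default 20: below
        that the rank-correlation p is unreliable).

    Returns one row per testable gene: ``gene, cancer_type, rho, p_value, n,
    rank_positive, rank_negative, q_value``. Samples are intersected by ID,
    so column order never matters; constant-expression genes are skipped with
    a logged reason. p-values use the t approximation for n > 10, exact
    enumeration otherwise (see :func:`spearman`).
    """
    if not expr.is_zscore:
        logger.warning("expression matrix is not flagged as z-scores")
    col = f"load_{load_class}"
    if col not in loads.columns:
        raise ValueError(f"unknown load class {load_class!r}")

    shared = expr.samples.intersection(loads.index)
    if len(shared) == 0:
        raise ValueError(
            "no shared samples between expression and loads; expression has "
            f"e.g. {list(expr.samples[:3])}, loads have {list(loads.index[:3])}"
        )
    if len(shared) < min_samples:
        raise ValueError(f"only {len(shared)} shared samples (< min_samples="
                         f"{min_samples})")
    cancer_type = str(loads["cancer_type"].iloc[0]) if "cancer_type" in loads else ""

    X = expr.values[shared].to_numpy(dtype=float)
    load_vec = loads.loc[shared, col].to_numpy(dtype=float)
    n = len(shared)

    if np.all(load_vec == load_vec[0]):
        raise ValueError(f"{col} is constant across the cohort: screen undefined")

    const = np.all(X == X[:, [0]], axis=1)
    if const.any():
        logger.info("%s: skipped %d constant-expression gene(s): %s%s",
                    cancer_type, int(const.sum()),
                    list(expr.genes[const][:10]),
                    "..." if const.sum() > 10 else "")
    genes = expr.genes[~const]
    X = X[~const]

    if n <= 10:
        results = [spearman(row, load_vec) for row in X]
        rho = np.array([r.rho for r in results])
        pvals = np.array([r.p_value for r in results])
    else:
        RX = stats.rankdata(X, axis=1) - (n + 1) / 2.0
        ry = _rank_center(load_vec)
        norm_x = np.sqrt((RX ** 2).sum(axis=1))
        norm_y = math.sqrt(float(ry @ ry))
        rho = np.clip((RX @ ry) / (norm_x * norm_y), -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        pvals = np.minimum(2.0 * stats.t.sf(np.abs(t), df=n - 2), 1.0)
        exact_mono = np.abs(rho) >= 1.0 - 1e-12
        if exact_mono.any():
            pvals[exact_mono] = 2.0 * math.exp(-math.lgamma(n + 1))

    out = pd.DataFrame({"gene": genes.astype(str), "cancer_type": cancer_type,
                        "rho": rho, "p_value": pvals, "n": n})
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]

    out["rank_positive"] = 0
    out["rank_negative"] = 0
    out.loc[_tie_break_order(out, positive=True), "rank_positive"] = \
        np.arange(1, len(out) + 1)
    out.loc[_tie_break_order(out, positive=False), "rank_negative"] = \
        np.arange(1, len(out) + 1)
    return out.sort_values("rank_positive", kind="stable").reset_index(drop=True)


@dataclass
class TopKLists:
    """Per-cancer top-K gene lists by Spearman rank.

    ``positive_genes`` holds (up to) the K genes with the largest rho among
    those with rho > 0, strongest first; ``negative_genes`` the analogue for
    rho < 0. Boundary ties break by smaller p then lexicographic symbol.
    """

    cancer_type: str
    k: int
    positive_genes: list[str] = field(default_factory=list)
    negative_genes: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {"cancer_type": self.cancer_type, "k": self.k,
                "positive_genes": self.positive_genes,
                "negative_genes": self.negative_genes}

    @classmethod
    def from_json_dict(cls, d: dict) -> "TopKLists":
        return cls(d["cancer_type"], d["k"],
                   list(d["positive_genes"]), list(d["negative_genes"]))


def top_k(results: pd.DataFrame, k: int) -> TopKLists:
    """Cut ranked screen results into top-K positive and negative lists."""
    if k <= 0:
        raise ValueError(f"K must be positive, got {k}")
    cancers = results["cancer_type"].unique()
    if len(cancers) > 1:
        raise ValueError(f"results span multiple cancer types: {list(cancers)}")
    ok = results.dropna(subset=["rho"])
    pos = ok[ok["rho"] > 0]
    neg = ok[ok["rho"] < 0]
    pos_genes = pos.loc[_tie_break_order(pos, positive=True), "gene"].head(k)
    neg_genes = neg.loc[_tie_break_order(neg, positive=False), "gene"].head(k)
    return TopKLists(str(cancers[0]) if len(cancers) else "", k,
                     list(pos_genes), list(neg_genes))


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
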