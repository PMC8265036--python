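"""Coexpression statistics: Pearson matrices, ICV condition filtering, and
the random-gene-set null model for fiber significance.

Correlations use the population (1/T) convention throughout: the Pearson
coefficient between genes i and j over T conditions is

    C(i,j) = (1/T) * sum_t ((x_it - mu_i)/sigma_i) * ((x_jt - mu_j)/sigma_j)

with mu and sigma computed over the same condition subset.  A fiber's
synchrony score is the mean off-diagonal correlation of its members.

Condition filtering uses the inverse coefficient of variation of the gene
set at each condition, ICV_t = mu_t / sigma_t; conditions strictly above
the mean ICV are treated as "active" for that set.  Note that this
selection itself induces correlation, which is why significance is always
judged against a null of random gene sets filtered the same way: the null
mean and sd of mean correlations over ``n_samples`` random same-size sets
give, for the m observed fibers of a size, Z = (mu_real - mu) / (sigma/sqrt(m))
and a one-sided upper-tail normal p value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fibration import FiberPartition

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionSelection",
    "SignificanceTable",
    "read_expression",
    "write_expression",
    "pearson_matrix",
    "mean_offdiag",
    "icv_select",
    "random_null",
    "fiber_significance",
    "cross_fiber_corr",
    "functional_network",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-conditions expression TSV (first column: gene ids)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.index.name = "gene"
    _validate_expression(expr)
    return expr

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if expr.columns.duplicated().any():
        raise ValueError("duplicate condition ids in expression matrix")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


# -- correlations --------------------------------------------------------


def pearson_matrix(
    expr: pd.DataFrame,
    genes: Sequence[str],
    conditions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pearson correlation matrix of the given genes over the given conditions.

    Moments use the population convention over exactly the requested
    condition subset (defaulting to all conditions).  Genes with zero
    variance yield missing (NaN) rows/columns with a warning; the diagonal
    of well-defined genes is exactly 1.
    """
    if conditions is None:
        conditions = list(expr.columns)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    sub = expr.loc[list(genes), list(conditions)].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = [g for g, flag in zip(genes, degenerate) if flag]
        logger.warning("zero-variance gene(s) give undefined correlations: %s",
                       ", ".join(map(str, bad)))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    return pd.DataFrame(corr, index=list(genes), columns=list(genes))


def mean_offdiag(C: pd.DataFrame | np.ndarray) -> float:
    """Arithmetic mean of all off-diagonal entries, skipping missing ones."""
    arr = np.asarray(C, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] < 2:
        raise ValueError("need a square matrix of size >= 2")
    mask = ~np.eye(arr.shape[0], dtype=bool)
    vals = arr[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("all off-diagonal correlations are undefined")
    return float(vals.mean())


# -- ICV condition selection ---------------------------------------------


@dataclass(frozen=True)
class ConditionSelection:
    """Active-condition selection for one gene set.

    ``icv`` holds ICV_t per condition (+inf where the per-condition sd is
    zero); ``selected`` are conditions with ICV strictly above the mean of
    the finite ICVs; ``z`` is the ICV z-score over the finite ICVs.
    """

    gene_set: tuple[str, ...]
    icv: pd.Series
    mu_icv: float
    sigma_icv: float
    z: pd.Series
    selected: tuple[str, ...]


def icv_select(expr: pd.DataFrame, genes: Sequence[str]) -> ConditionSelection:
    """Select the conditions in which a gene set is active, by ICV.

    ICV_t = mu_t / sigma_t with mu_t and (population) sigma_t over the
    listed genes at condition t.  Conditions with sigma_t = 0 get ICV
    +inf and are always selected (warned).  The threshold is the mean of
    the finite ICVs, exceeded strictly.
    """
    if len(genes) < 2:
        raise ValueError("ICV needs at least 2 genes")
    sub = expr.loc[list(genes)].to_numpy(dtype=float)
    mu_t = sub.mean(axis=0)
    sd_t = sub.std(axis=0, ddof=0)
    with np.errstate(divide="ignore"):
        icv = np.where(sd_t == 0, np.inf, mu_t / np.where(sd_t == 0, 1.0, sd_t))
    if np.isinf(icv).any():
        logger.warning("%d condition(s) with zero dispersion: ICV=+inf, selected",
                       int(np.isinf(icv).sum()))
    finite = np.isfinite(icv)
    if finite.any():
        mu_icv = float(icv[finite].mean())
        sigma_icv = float(icv[finite].std(ddof=0))
    else:
        mu_icv, sigma_icv = float("nan"), float("nan")
    with np.errstate(invalid="ignore"):
        z = (icv - mu_icv) / sigma_icv if sigma_icv and sigma_icv > 0 else np.full_like(icv, np.nan)
    if math.isnan(mu_icv):
        selected = np.ones(len(icv), dtype=bool)  # all degenerate: keep everything
    else:
        selected = icv > mu_icv
    cols = list(expr.columns)
    return ConditionSelection(
        gene_set=tuple(genes),
        icv=pd.Series(icv, index=cols),
        mu_icv=mu_icv,
        sigma_icv=sigma_icv,
        z=pd.Series(z, index=cols),
        selected=tuple(c for c, flag in zip(cols, selected) if flag),
    )


# -- random-set null model -----------------------------------------------


def _set_mean_corr(
    expr: pd.DataFrame, genes: Sequence[str], filtering: str
) -> float:
    """Mean off-diagonal correlation of one gene set (NaN if undefined)."""
    if filtering == "icv":
        sel = icv_select(expr, genes)
        conditions: Optional[list[str]] = list(sel.selected)
        if len(conditions) < 2:
            return float("nan")
    else:
        conditions = None
    C = pearson_matrix(expr, genes, conditions)
    arr = C.to_numpy()
    mask = ~np.eye(arr.shape[0], dtype=bool)
    vals = arr[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def random_null(
    expr: pd.DataFrame,
    size: int,
    n_samples: int = 100_000,
    filtering: str = "none",
    seed: int = 0,
    return_samples: bool = False,
):
    """Null distribution of mean correlations of random same-size gene sets.

    Draws ``n_samples`` uniform random gene sets (without replacement
    within a set) from all genes in the matrix, scores each by its mean
    off-diagonal Pearson correlation — over all conditions
    (``filtering='none'``) or over its own ICV-selected conditions
    (``filtering='icv'``) — and returns the mean and population sd of the
    sample.  Sets with undefined correlation are redrawn (logged).
    """
    if filtering not in ("none", "icv"):
        raise ValueError(f"unknown filtering mode: {filtering!r}")
    if size < 2:
        raise ValueError("set size must be >= 2")
    if size > expr.shape[0]:
        raise ValueError("set size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    genes = np.asarray(expr.index)
    values = np.empty(n_samples)
    if filtering == "none":
        # vectorised: standardise once, then mean off-diagonal is a dot product
        X = expr.to_numpy(dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (X - mu) / sd
        T = X.shape[1]
        filled = 0
        while filled < n_samples:
            batch = min(2000, n_samples - filled)
            idx = np.stack(
                [rng.choice(len(genes), size=size, replace=False) for _ in range(batch)]
            )
            G = Z[idx]  # batch x size x T
            C = np.einsum("bst,but->bsu", G, G) / T
            mask = ~np.eye(size, dtype=bool)
            vals = C[:, mask].reshape(batch, -1)
            means = np.nanmean(vals, axis=1)
            ok = np.isfinite(means)
            if not ok.all():
                logger.debug("redrawing %d undefined random set(s)", int((~ok).sum()))
            n_ok = int(ok.sum())
            values[filled : filled + n_ok] = means[ok]
            filled += n_ok
    else:
        filled = 0
        redraws = 0
        while filled < n_samples:
            idx = rng.choice(len(genes), size=size, replace=False)
            v = _set_mean_corr(expr, list(genes[idx]), "icv")
            if math.isnan(v):
                redraws += 1
                if redraws > 100 * n_samples:
                    raise RuntimeError("random null: too many undefined draws")
                continue
            values[filled] = v
            filled += 1
        if redraws:
            logger.debug("redrew %d undefined random set(s)", redraws)
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if return_samples:
        return mu, sigma, values
    return mu, sigma


# -- per-size significance -----------------------------------------------


@dataclass
class SignificanceTable:
    """Per-fiber-size synchrony significance versus the random-set null.

    ``table`` rows: size, mu_real (mean over the m fibers of that size of
    their within-fiber mean correlations), mu_m (null mean), sigma_m
    (null sd / sqrt(m)), m, Z, p (one-sided upper tail), significant
    (p < 0.05).  ``per_fiber`` holds each fiber's own mean correlation and
    selected-condition count.  No multiple-testing correction is applied
    across sizes (recorded in ``meta``).
    """

    table: pd.DataFrame
    per_fiber: pd.DataFrame
    meta: dict


def fiber_significance(
    fibers: FiberPartition,
    expr: pd.DataFrame,
    filtering: str = "none",
    n_samples: int = 100_000,
    seed: int = 0,
    size_range: tuple[int, int] = (2, 24),
) -> SignificanceTable:
    """Aggregate within-fiber mean correlations by size and test vs. the null.

    Each fiber of a size within ``size_range`` is scored over its own
    condition set (all conditions, or its own ICV selection); fibers with
    members absent from the matrix, or with an undefined score, are dropped
    with a warning and counted in the output.  The null (mu, sigma) is
    recomputed per size and filtering mode from ``n_samples`` random sets;
    Z = (mu_real - mu) / (sigma / sqrt(m)) and p is the upper normal tail.
    """
    lo, hi = size_range
    if lo > hi:
        raise ValueError("empty size range")
    rows = []
    dropped = 0
    for fid, members in sorted(fibers.fibers.items()):
        size = len(members)
        if not (lo <= size <= hi):
            continue
        present = [g for g in sorted(members) if g in expr.index]
        if len(present) < size:
            logger.warning("fiber %d dropped: member(s) missing from matrix", fid)
            dropped += 1
            continue
        value = _set_mean_corr(expr, present, filtering)
        if math.isnan(value):
            logger.warning("fiber %d dropped: undefined correlation", fid)
            dropped += 1
            continue
        n_cond = (
            len(icv_select(expr, present).selected)
            if filtering == "icv"
            else expr.shape[1]
        )
        rows.append({"fiber_id": fid, "size": size, "mean_corr": value,
                     "n_conditions": n_cond})
    per_fiber = pd.DataFrame(rows, columns=["fiber_id", "size", "mean_corr",
                                            "n_conditions"])
    ss = np.random.SeedSequence(seed)
    out = []
    if not per_fiber.empty:
        sizes = sorted(per_fiber["size"].unique())
        null_seeds = {
            s: int(rng_seed)
            for s, rng_seed in zip(
                sizes, np.random.default_rng(ss).integers(0, 2**31 - 1, len(sizes))
            )
        }
        for s in sizes:
            grp = per_fiber.loc[per_fiber["size"] == s, "mean_corr"]
            m = len(grp)
            mu_real = float(grp.mean())
            mu, sigma = random_null(expr, s, n_samples, filtering, null_seeds[s])
            sigma_m = sigma / math.sqrt(m) if sigma > 0 else float("nan")
            z = (mu_real - mu) / sigma_m if sigma_m and sigma_m > 0 else float("nan")
            p = float(norm.sf(z)) if math.isfinite(z) else float("nan")
            out.append({"size": s, "mu_real": mu_real, "mu_m": mu,
                        "sigma_m": sigma_m, "m": m, "Z": z, "p": p,
                        "significant": bool(p < 0.05) if math.isfinite(p) else False})
    table = pd.DataFrame(out, columns=["size", "mu_real", "mu_m", "sigma_m",
                                       "m", "Z", "p", "significant"])
    meta = {
        "filtering": filtering,
        "n_samples": n_samples,
        "seed": seed,
        "size_range": list(size_range),
        "fibers_dropped": dropped,
        "multiple_testing_correction": "none",
    }
    return SignificanceTable(table=table, per_fiber=per_fiber, meta=meta)


# -- cross-fiber and functional network ----------------------------------


def cross_fiber_corr(
    expr: pd.DataFrame,
    genes_a: Sequence[str],
    selection_a: Optional[ConditionSelection],
    genes_b: Sequence[str],
    selection_b: Optional[ConditionSelection],
) -> pd.DataFrame:
    """Correlations across two fibers over the union of their condition sets.

    Pass ``None`` selections (both) to use all conditions; both selections
    must come from the same filtering mode.
    """
    if (selection_a is None) != (selection_b is None):
        raise ValueError("selections must use the same filtering mode")
    genes = sorted(set(genes_a) | set(genes_b))
    if selection_a is None:
        conditions = None
    else:
        union = set(selection_a.selected) | set(selection_b.selected)
        conditions = [c for c in expr.columns if c in union]
        if len(conditions) < 2:
            raise ValueError("union of selected conditions has fewer than 2 members")
    return pearson_matrix(expr, genes, conditions)


def functional_network(
    C: pd.DataFrame, threshold: float = 0.6
) -> list[tuple[str, str, float]]:
    """Undirected edges (i, j, C(i,j)) for off-diagonal entries strictly above
    the threshold; missing entries never produce edges."""
    arr = C.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("correlation matrix must be square")
    names = list(C.index)
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            v = arr[i, j]
            if np.isfinite(v) and v > threshold:
                edges.append((names[i], names[j], float(v)))
    return edges
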