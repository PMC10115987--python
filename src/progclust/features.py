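"""Gene scoring and node-local feature space selection.

Two complementary scores drive the progressive clustering tree:

* the **Fano factor** (variance over mean) flags genes whose expression
  varies between abundant populations — the top genes span the feature
  space for splitting a node;
* the **Gini index** of a gene's per-cell expression flags genes expressed
  highly in only a handful of cells — computed *locally* on the cells of one
  cluster it exposes rare cells hiding inside that cluster.

Raw Gini correlates with expression level, so it is detrended against
log(max expression + 1) with a locally weighted regression and the residual
("normalized Gini") is what gets thresholded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ExpressionMatrix


@dataclass
class FeatureSpace:
    """An ordered, duplicate-free gene set used to cluster one tree node."""

    gene_ids: list[str]
    origin: str  # "fano_top_k" or "local_high_gini"
    inherited_from_parent: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("feature space contains duplicate gene ids")

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# Fano factor
# ---------------------------------------------------------------------------

def fano_factor(g: np.ndarray) -> float:
    """Variance-to-mean ratio of one gene's expression across cells.

    Population variance (ddof=0), so i.i.d. Poisson counts estimate 1
    without correction.  Returns NaN when the mean is zero (the ratio is
    undefined for an unexpressed gene).
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or g.size < 2:
        raise ValueError("fano_factor needs a 1-D vector of at least 2 values")
    mu = g.mean()
    if mu == 0:
        return float("nan")
    return float(g.var() / mu)


def fano_factors(m: ExpressionMatrix) -> np.ndarray:
    """Per-gene Fano factors over the matrix columns; NaN for silent genes."""
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells to compute Fano factors")
    vals = np.asarray(m.values, dtype=float)
    mu = vals.mean(axis=1)
    var = vals.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mu > 0, var / np.where(mu > 0, mu, 1.0), np.nan)
    return out


def select_top_fano(
    m: ExpressionMatrix,
    k: int = 1000,
    parent_genes: FeatureSpace | None = None,
) -> FeatureSpace:
    """The ``k`` highest-Fano genes of a node, merged with the parent's set.

    Merging the parent's feature genes prevents a child from "forgetting"
    the axes that separated it from its siblings and re-splitting along
    noise.  Ties in Fano are broken by input gene order, so the selection is
    deterministic.
    """
    f = fano_factors(m)
    defined = ~np.isnan(f)
    if not defined.any():
        raise ValueError("no gene has a defined Fano factor (all-zero matrix)")
    order = np.argsort(-np.where(defined, f, -np.inf), kind="stable")
    order = [i for i in order if defined[i]][: min(k, int(defined.sum()))]
    top = [m.gene_ids[i] for i in order]
    if parent_genes is None:
        return FeatureSpace(top, origin="fano_top_k")
    inherited = list(parent_genes.gene_ids)
    merged = inherited + [g for g in top if g not in set(inherited)]
    return FeatureSpace(merged, origin="fano_top_k", inherited_from_parent=inherited)


# ---------------------------------------------------------------------------
# Gini index
# ---------------------------------------------------------------------------

def gini_index(g: np.ndarray) -> float:
    """Gini index of a nonnegative expression vector.

    With the values sorted ascending, ``Gini = sum_j (2j - n - 1) g_(j) /
    (n sum_j g_(j))`` (j one-based).  Zero for a constant positive vector,
    (n-1)/n for a single expressed cell.  NaN when the vector sums to zero.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or g.size < 2:
        raise ValueError("gini_index needs a 1-D vector of at least 2 values")
    if g.min() < 0:
        raise ValueError("gini_index requires nonnegative values")
    total = g.sum()
    if total == 0:
        return float("nan")
    n = g.size
    g_sorted = np.sort(g)
    coef = 2.0 * np.arange(1, n + 1) - n - 1
    return float((coef * g_sorted).sum() / (n * total))


def gini_indices(m: ExpressionMatrix) -> np.ndarray:
    """Vectorized per-gene Gini over the matrix columns; NaN when silent."""
    vals = np.asarray(m.values, dtype=float)
    n = vals.shape[1]
    if n < 2:
        raise ValueError("need at least 2 cells to compute Gini indices")
    totals = vals.sum(axis=1)
    g_sorted = np.sort(vals, axis=1)
    coef = 2.0 * np.arange(1, n + 1) - n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (g_sorted * coef).sum(axis=1) / (n * totals)
    out[totals == 0] = np.nan
    return out


def gene_score_table(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene score table: fano, gini_raw, max_expr (gini_normalized added
    by :func:`normalize_gini`)."""
    return pd.DataFrame(
        {
            "fano": fano_factors(m),
            "gini_raw": gini_indices(m),
            "max_expr": np.asarray(m.values, dtype=float).max(axis=1),
        },
        index=pd.Index(m.gene_ids, name="gene_id"),
    )


def normalize_gini(
    table: pd.DataFrame,
    span: float = 0.9,
    min_points: int = 10,
    refit_quantile: float = 0.9,
) -> pd.DataFrame:
    """Detrend raw Gini against log(max expression + 1).

    Two-pass locally weighted regression: a first LOWESS fit of ``gini_raw``
    on ``log(max_expr + 1)``, then a refit excluding candidate high-Gini
    genes — those whose first-pass residual lies above the
    ``refit_quantile`` quantile *or* whose raw Gini is in the top tail
    (an isolated highly expressed outlier can self-fit the local trend, so
    its residual alone does not identify it).  ``gini_normalized`` is the
    residual from the refined trend.  Genes with undefined Gini (locally
    silent) are left NaN.

    With fewer than ``min_points`` scored genes the smoother is unreliable;
    the residual falls back to ``gini_raw - median(gini_raw)``.
    """
    table = table.copy()
    defined = table["gini_raw"].notna().to_numpy()
    x = np.log(table["max_expr"].to_numpy(dtype=float) + 1.0)[defined]
    y = table["gini_raw"].to_numpy(dtype=float)[defined]
    resid = np.full(len(table), np.nan)

    if defined.sum() < min_points:
        warnings.warn(
            f"only {int(defined.sum())} genes with defined Gini; "
            "falling back to median-centered residuals",
            stacklevel=2,
        )
        if defined.any():
            resid[defined] = y - np.median(y)
        table["gini_normalized"] = resid
        return table

    trend1 = _lowess_predict(x, y, x, span)
    r1 = y - trend1
    keep = (r1 <= np.quantile(r1, refit_quantile)) & (
        y <= np.quantile(y, (1 + refit_quantile) / 2)
    )
    # guard: the quantile cut can never empty the fit set
    if keep.sum() >= min_points:
        trend2 = _lowess_predict(x[keep], y[keep], x, span)
    else:  # pragma: no cover - degenerate residual distribution
        trend2 = trend1
    resid[defined] = y - trend2
    table["gini_normalized"] = resid
    return table


def _lowess_predict(
    x_fit: np.ndarray, y_fit: np.ndarray, x_eval: np.ndarray, span: float
) -> np.ndarray:
    """LOWESS fit on (x_fit, y_fit), evaluated at x_eval by interpolation."""
    fitted = lowess(y_fit, x_fit, frac=span, it=1, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x for np.interp monotonicity
    xs_u, idx = np.unique(xs, return_index=True)
    return np.interp(x_eval, xs_u, ys[idx])


def select_local_high_gini(
    m_node: ExpressionMatrix,
    span: float = 0.9,
    p_cutoff: float = 1e-4,
    min_points: int = 10,
) -> FeatureSpace:
    """Genes with significantly high normalized Gini on a node's cells.

    Raw Gini is computed on the node's cells only, detrended, and a gene is
    selected when its residual exceeds the one-sided normal tail cutoff at
    ``p_cutoff`` (mean/sd estimated from the residual distribution).  An
    empty selection means "no rare-cell signal at this node".
    """
    if m_node.n_cells < 2:
        raise ValueError("need at least 2 cells for local Gini selection")
    table = normalize_gini(gene_score_table(m_node), span=span, min_points=min_points)
    resid = table["gini_normalized"].to_numpy(dtype=float)
    defined = ~np.isnan(resid)
    if not defined.any():
        return FeatureSpace([], origin="local_high_gini")
    r = resid[defined]
    sd = r.std()
    if sd == 0:
        return FeatureSpace([], origin="local_high_gini")
    z = stats.norm.isf(p_cutoff)
    cutoff = r.mean() + z * sd
    selected = defined & (resid > cutoff)
    genes = [g for g, s in zip(m_node.gene_ids, selected) if s]
    return FeatureSpace(genes, origin="local_high_gini")


def write_gene_scores(table: pd.DataFrame, path) -> None:
    """Export the per-gene score table as a TSV."""
    table.to_csv(path, sep="\t")
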