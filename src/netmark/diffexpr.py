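"""Per-gene differential expression with an empirical-Bayes moderated t-test.

Inputs are assumed to be pre-normalized, log2-scale expression values (the
usual output of processed microarray / RNA-seq portals), so the group-mean
difference IS the log2 fold change.  Gene-wise sample variances are shrunk
toward a pooled prior via the standard empirical-Bayes squeeze: the prior
degrees of freedom d0 and prior variance s0² are estimated by the method of
moments on log sample variances, and each gene's posterior variance is

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d),        d = n1 + n2 - 2.

The moderated t statistic lfc / (s̃·sqrt(1/n1 + 1/n2)) is referred to a
t distribution with d + d0 degrees of freedom.  Setting ``prior_df=0``
recovers the ordinary two-sample pooled t-test exactly.

DEG filtering uses strict inequalities: p < p_threshold and |log2FC| >
lfc_threshold, on raw (unadjusted) p-values; a Benjamini-Hochberg column is
emitted for information only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import InsufficientReplicationError, SchemaError, ValidationError

__all__ = [
    "differential_expression",
    "filter_degs",
    "annotate_degs",
    "validate_de_table",
]

_VAR_FLOOR = 1e-12

P_THRESHOLD_DEFAULT = 0.05
LFC_THRESHOLD_DEFAULT = 1.0


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _moment_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior df d0, prior variance s0²) to sample variances."""
    ok = s2 > _VAR_FLOOR
    if ok.sum() < 2:
        return np.inf, float(np.maximum(s2.mean(), _VAR_FLOOR))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def differential_expression(
    expr: pd.DataFrame,
    labels: pd.Series,
    prior_df: float | None = None,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Moderated two-sample test for every gene of a genes x samples matrix.

    Parameters
    ----------
    expr
        Log2-scale expression, genes in rows, samples in columns.
    labels
        Sample → group mapping with groups ``case`` and ``control``.
    prior_df
        Override for the prior degrees of freedom; ``None`` estimates it by
        moments, ``0`` gives the ordinary pooled t-test, ``inf`` fully pools.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``pvalue``,
    ``pvalue_adj`` (Benjamini-Hochberg, informational) and ``is_deg``.
    """
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValidationError("every sample column needs a group label")
    groups = set(labels.unique())
    if groups != {"case", "control"}:
        raise ValidationError(f"labels must be 'case'/'control', got {sorted(groups)}")
    case = expr.loc[:, (labels == "case").to_numpy()]
    ctrl = expr.loc[:, (labels == "control").to_numpy()]
    n1, n0 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n0 < 2:
        raise InsufficientReplicationError(
            f"need >= 2 samples per group, got case={n1}, control={n0}"
        )
    x1, x0 = case.to_numpy(float), ctrl.to_numpy(float)
    if not (np.isfinite(x1).all() and np.isfinite(x0).all()):
        raise ValidationError("expression matrix contains non-finite values")

    lfc = x1.mean(axis=1) - x0.mean(axis=1)
    df_resid = n1 + n0 - 2
    s2 = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n0 - 1) * x0.var(axis=1, ddof=1)) / df_resid
    s2 = np.maximum(s2, _VAR_FLOOR)

    if prior_df is None:
        d0, s0_sq = _moment_prior(s2, df_resid)
    else:
        if prior_df < 0:
            raise ValidationError("prior_df must be non-negative")
        d0 = float(prior_df)
        s0_sq = float(np.median(s2)) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    t = lfc / se
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    pvals = np.minimum(pvals, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pvals,
            "pvalue_adj": stats.false_discovery_control(pvals, method="bh"),
        },
        index=expr.index.rename("gene"),
    )
    return annotate_degs(table, p_threshold, lfc_threshold)


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a (possibly external) DE table for the required schema."""
    missing = {"log2fc", "pvalue"} - set(table.columns)
    if missing:
        raise SchemaError(f"DE table lacks columns: {sorted(missing)}")
    if table.index.has_duplicates:
        raise ValidationError("gene ids must be unique")
    p = table["pvalue"].to_numpy(float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return table


def annotate_degs(
    table: pd.DataFrame,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Add/refresh the ``is_deg`` column under the strict-inequality filter."""
    out = table.copy()
    out["is_deg"] = (out["pvalue"] < p_threshold) & (out["log2fc"].abs() > lfc_threshold)
    return out


def filter_degs(
    table: pd.DataFrame,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
) -> set[str]:
    """Genes with pvalue < p_threshold AND |log2fc| > lfc_threshold (both strict)."""
    if p_threshold <= 0 or lfc_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    validate_de_table(table)
    mask = (table["pvalue"] < p_threshold) & (table["log2fc"].abs() > lfc_threshold)
    return set(table.index[mask])
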