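"""FPKM summarization, fold changes and differential-expression calls.

Expression arrives as a per-feature FPKM matrix over two conditions —
non-vernalized (NV) and vernalized (V) — with replicate columns named like
``NV_1, NV_2, V_1, V_2``. Fold change is ``log2((mean_V + pc) / (mean_NV +
pc))`` with a small pseudocount ``pc``. The differential call is a
two-sample t-test on log2(FPKM + pc) across replicates followed by
Benjamini–Hochberg FDR control; this replaces the count-level
negative-binomial machinery of read-based tools, which cannot operate on an
FPKM matrix, and supplies exactly what the downstream analyses consume:
direction, fold change and an FDR threshold.

With two replicates per condition a per-feature variance estimate has only
two residual degrees of freedom, so the default test moderates the pooled
variances with the standard empirical-Bayes shrinkage toward a common
prior fitted across all features (per-feature sample variances are modeled
as scaled F draws around a prior variance s0^2 with d0 prior df, estimated
by matching the moments of log s^2; the moderated t then has d_g + d0 df).
Set ``DEConfig(moderate_variance=False)`` for the plain pooled t, or
additionally ``equal_var=False`` for Welch's t — note that at n = 2 the
Welch–Satterthwaite df collapse toward one and the test has essentially no
power. Features are only tested when "supported" — mean FPKM of at least
``min_support_fpkm`` in one condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DIRECTIONS = ("up", "down", "ns")


@dataclass(frozen=True)
class DEConfig:
    """Differential-expression thresholds.

    fdr_threshold: BH q-value below which a feature is called up/down.
    high_fc_threshold: |log2 ratio| above which a called feature counts as
        "highly" regulated (used to build enrichment gene lists).
    pseudocount: FPKM added before ratios and log transforms.
    min_support_fpkm: expression-support floor (mean FPKM in >= 1 condition).
    moderate_variance: empirical-Bayes variance moderation (default True).
    equal_var: without moderation, pooled t (True) vs Welch's t (False).
    """

    fdr_threshold: float = 0.05
    high_fc_threshold: float = 2.0
    pseudocount: float = 0.01
    min_support_fpkm: float = 0.5
    moderate_variance: bool = True
    equal_var: bool = True

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "high_fc_threshold", "pseudocount", "min_support_fpkm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class ExpressionMatrix:
    """A nonnegative FPKM matrix (features x samples) with condition labels.

    Condition labels default to the sample-name prefix before the last
    underscore (``NV_1`` -> ``NV``); both ``ref_condition`` and
    ``alt_condition`` must be present with at least one replicate each.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        conditions: Mapping[str, str] | None = None,
        ref_condition: str = "NV",
        alt_condition: str = "V",
    ):
        if not values.index.is_unique:
            raise ValueError("feature ids must be unique")
        arr = values.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(~np.isfinite(arr)):
            raise ValueError("FPKM values must be finite and nonnegative")
        if conditions is None:
            conditions = {c: str(c).rsplit("_", 1)[0] for c in values.columns}
        self.values = values.astype(float)
        self.conditions = dict(conditions)
        self.ref_condition = ref_condition
        self.alt_condition = alt_condition
        for cond in (ref_condition, alt_condition):
            if not self.samples_for(cond):
                raise ValueError(f"no samples for condition {cond!r}")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions.get(s) == condition]

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @classmethod
    def read_tsv(cls, path, **kwargs) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, **kwargs)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


def log2_fold_change(nv_mean, v_mean, pseudocount: float = 0.01):
    """log2((v + pc) / (nv + pc)); antisymmetric under swapping arguments."""
    nv = np.asarray(nv_mean, dtype=float)
    v = np.asarray(v_mean, dtype=float)
    if np.any(nv < 0) or np.any(v < 0):
        raise ValueError("FPKM means must be nonnegative")
    if pseudocount < 0 or (pseudocount == 0 and (np.any(nv == 0) or np.any(v == 0))):
        raise ValueError("pseudocount must be positive when a mean is zero")
    out = np.log2(v + pseudocount) - np.log2(nv + pseudocount)
    return float(out) if out.ndim == 0 else out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration on the inverse scale."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def squeeze_variances(s2: np.ndarray, df_resid: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-feature variances toward a prior.

    Models each sample variance as ``s0^2 * F(df_resid, d0)`` and fits the
    prior variance s0^2 and prior df d0 by matching the mean and variance of
    log s^2 (digamma/trigamma moments). Returns the posterior variances
    ``(d0*s0^2 + df_resid*s^2) / (d0 + df_resid)`` and d0 (inf when the
    observed spread of log s^2 is no larger than pure chi-square scatter).
    """
    if df_resid <= 0:
        raise ValueError("df_resid must be positive")
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    dg2 = df_resid / 2.0
    e = z - float(polygamma(0, dg2)) + np.log(dg2)
    if s2.size < 2:
        return s2.copy(), 0.0
    evar = float(np.var(z, ddof=1)) - float(polygamma(1, dg2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(np.mean(e) + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
        return (d0 * s02 + df_resid * s2) / (d0 + df_resid), d0
    s02 = float(np.exp(np.mean(e)))
    return np.full_like(s2, s02), np.inf


def _moderated_t_pvalues(log_nv: np.ndarray, log_v: np.ndarray) -> np.ndarray:
    n1, n2 = log_nv.shape[1], log_v.shape[1]
    df_resid = n1 + n2 - 2
    s2 = (
        (n1 - 1) * log_nv.var(axis=1, ddof=1) + (n2 - 1) * log_v.var(axis=1, ddof=1)
    ) / df_resid
    s2_post, d0 = squeeze_variances(s2, df_resid)
    diff = log_v.mean(axis=1) - log_nv.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    if np.isinf(d0):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df_resid + d0)


def differential_expression(
    matrix: ExpressionMatrix, config: DEConfig | None = None
) -> pd.DataFrame:
    """Per-feature NV/V means, log2 ratio, two-sample-t p, BH q and direction.

    Returns a DataFrame indexed by feature id with columns ``mean_fpkm_nv``,
    ``mean_fpkm_v``, ``log2_ratio``, ``p_value``, ``fdr``, ``direction`` and
    ``supported``. Unsupported features keep direction ``ns`` with NaN
    p/q-values; BH runs over supported features only. With a single
    replicate per condition no test is possible: p-values are absent, the
    direction falls back to the high-fold-change rule, and the frame is
    flagged via ``attrs["single_replicate"]``.
    """
    config = config or DEConfig()
    nv_cols = matrix.samples_for(matrix.ref_condition)
    v_cols = matrix.samples_for(matrix.alt_condition)
    nv = matrix.values[nv_cols].to_numpy(float)
    v = matrix.values[v_cols].to_numpy(float)
    mean_nv = nv.mean(axis=1)
    mean_v = v.mean(axis=1)
    supported = (
        (mean_nv >= config.min_support_fpkm) | (mean_v >= config.min_support_fpkm)
    )
    lfc = log2_fold_change(mean_nv, mean_v, config.pseudocount)

    single_replicate = len(nv_cols) < 2 or len(v_cols) < 2
    p = np.full(len(mean_nv), np.nan)
    if not single_replicate:
        log_nv = np.log2(nv + config.pseudocount)
        log_v = np.log2(v + config.pseudocount)
        diff = log_v.mean(axis=1) - log_nv.mean(axis=1)
        if config.moderate_variance:
            p_all = _moderated_t_pvalues(log_nv, log_v)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                _t, p_all = stats.ttest_ind(
                    log_v, log_nv, axis=1, equal_var=config.equal_var
                )
        # zero residual variance: degenerate test; equal means -> null,
        # unequal means -> separation is exact at this sample size
        nan_p = ~np.isfinite(p_all)
        p_all[nan_p & (np.abs(diff) < 1e-12)] = 1.0
        p_all[nan_p & (np.abs(diff) >= 1e-12)] = 0.0
        p = p_all

    fdr = np.full(len(mean_nv), np.nan)
    if not single_replicate and supported.any():
        fdr[supported] = bh_fdr(p[supported])

    direction = np.full(len(mean_nv), "ns", dtype=object)
    if single_replicate:
        called = supported & (np.abs(lfc) > config.high_fc_threshold)
    else:
        called = supported & (fdr < config.fdr_threshold) & (lfc != 0)
    direction[called & (lfc > 0)] = "up"
    direction[called & (lfc < 0)] = "down"

    out = pd.DataFrame(
        {
            "mean_fpkm_nv": mean_nv,
            "mean_fpkm_v": mean_v,
            "log2_ratio": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
            "supported": supported,
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )
    out.attrs["single_replicate"] = single_replicate
    return out


def direction_counts(de: pd.DataFrame) -> dict[str, int]:
    sub = de[de["supported"]]
    return {d: int((sub["direction"] == d).sum()) for d in DIRECTIONS}


def compare_category_expression(
    matrix: ExpressionMatrix,
    categories: Mapping[str, str],
    samples: list[str] | None = None,
    pseudocount: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category-wise expression summary and all-pairs Tukey HSD.

    Each feature contributes its mean log2(FPKM + pc) over *samples* (all
    samples by default, or e.g. one condition's replicates). Categories with
    fewer than two features are dropped with a warning. Returns
    ``(summary, pairwise)``: per-category n/mean/quartiles, and the Tukey
    honestly-significant-difference table with family-wise adjusted
    p-values (empty with fewer than two usable categories).
    """
    cols = samples or list(matrix.values.columns)
    expr = np.log2(matrix.values[cols] + pseudocount).mean(axis=1)
    df = pd.DataFrame({"value": expr})
    df["category"] = [categories.get(str(f)) for f in matrix.values.index]
    df = df.dropna(subset=["category"])

    sizes = df.groupby("category").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"categories with < 2 features dropped: {small}")
        df = df[~df["category"].isin(small)]

    summary = (
        df.groupby("category")["value"]
        .agg(
            n="size",
            mean="mean",
            std="std",
            q25=lambda s: s.quantile(0.25),
            median="median",
            q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )

    pairwise_cols = ["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]
    if df["category"].nunique() < 2:
        return summary, pd.DataFrame(columns=pairwise_cols)
    tukey = pairwise_tukeyhsd(df["value"].to_numpy(), df["category"].to_numpy())
    table = pd.DataFrame(
        tukey.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    # the summary table rounds; take exact numbers from the result object
    table["meandiff"] = tukey.meandiffs
    table["p_adj"] = tukey.pvalues
    table["lower"] = tukey.confint[:, 0]
    table["upper"] = tukey.confint[:, 1]
    table["reject"] = tukey.reject
    return summary, table
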