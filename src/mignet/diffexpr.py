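"""Two-group differential expression: fold changes, tests and FDR gating.

Features (miRNAs or mRNAs) are compared between ``cancer`` and
``control`` samples.  The fold change of feature *i* is the ratio of the
group means of raw abundances (with a pseudocount), reported as
``log2fc``.  Significance comes from a two-sided test on
``log2(x + pseudocount)`` values: Welch's unequal-variance t-test by
default, or a moderated t-statistic that shrinks per-feature variances
toward an empirical-Bayes prior before testing.  P-values are adjusted
by the Benjamini-Hochberg step-up procedure and a feature is flagged
significant when ``fdr < alpha`` and ``|log2fc| > log2(fc_threshold)``;
the fold-change gate is two-sided so both over- and under-expressed
features pass.

The miRNA matrix and the mRNA matrix are separate multiple-testing
families: callers adjust each matrix on its own, and cell-fate gene
results are obtained by restricting the mRNA table after adjustment
(``restrict_to_features``), optionally re-adjusting within the subset.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from mignet.errors import ConfigError, DegenerateInputError, InputError

CANCER = "cancer"
CONTROL = "control"


@dataclasses.dataclass
class ExpressionMatrix:
    """Nonnegative feature-by-sample abundance table with a binary group design.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
        Entries are raw abundances (counts or normalised intensities)
        and must be nonnegative and finite.
    groups
        Series mapping every sample id to ``"cancer"`` or ``"control"``
        (case-insensitive).  Both groups must be non-empty.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate feature ids: {list(dupes)[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise InputError("expression values must be finite")
        if (vals < 0).any():
            raise InputError("expression values must be nonnegative")
        groups = self.groups.astype(str).str.lower()
        unlabelled = [s for s in self.values.columns if s not in groups.index]
        if unlabelled:
            raise ConfigError(f"samples without a group label: {unlabelled[:5]}")
        groups = groups.loc[self.values.columns]
        bad = set(groups.unique()) - {CANCER, CONTROL}
        if bad:
            raise ConfigError(f"unknown group labels: {sorted(bad)}")
        for g in (CANCER, CONTROL):
            if (groups == g).sum() == 0:
                raise ConfigError(f"group {g!r} has no samples")
        object.__setattr__(self, "groups", groups)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, group: str) -> pd.DataFrame:
        """Columns of `values` belonging to one group."""
        cols = self.groups.index[self.groups == group]
        return self.values[cols]

    def swapped(self) -> "ExpressionMatrix":
        """Same matrix with cancer/control labels exchanged (for symmetry tests)."""
        flipped = self.groups.map({CANCER: CONTROL, CONTROL: CANCER})
        return ExpressionMatrix(self.values, flipped)


def compute_log2fc(expr: ExpressionMatrix, pseudocount: float = 1.0) -> pd.Series:
    """log2 of (cancer mean + pseudocount) / (control mean + pseudocount) per feature."""
    if pseudocount < 0:
        raise ConfigError("pseudocount must be nonnegative")
    mean_c = expr.group_values(CANCER).mean(axis=1)
    mean_n = expr.group_values(CONTROL).mean(axis=1)
    if pseudocount == 0:
        zero = mean_n[mean_n == 0]
        if len(zero):
            raise DegenerateInputError(
                f"zero control mean with pseudocount 0 for feature(s) {list(zero.index)[:5]}"
            )
        zero_c = mean_c[mean_c == 0]
        if len(zero_c):
            raise DegenerateInputError(
                f"zero cancer mean with pseudocount 0 for feature(s) {list(zero_c.index)[:5]}"
            )
    fc = (mean_c + pseudocount) / (mean_n + pseudocount)
    out = np.log2(fc)
    out.name = "log2fc"
    return out


def _log_groups(
    expr: ExpressionMatrix, pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    a = np.log2(expr.group_values(CANCER).to_numpy(dtype=float) + pseudocount)
    b = np.log2(expr.group_values(CONTROL).to_numpy(dtype=float) + pseudocount)
    return a, b


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance features trigger scipy's precision warning; they are
        # re-assigned explicit p-values downstream
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return np.asarray(res.pvalue, dtype=float)


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on psi'(y) = x (monotone decreasing on (0, inf)).
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def _fit_scaled_invchisq(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of a scaled inverse-chi-square prior on sample variances.

    Returns (d0, s0sq): prior degrees of freedom (may be inf) and prior
    variance, estimated from log sample variances via digamma/trigamma
    moments.
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def _moderated(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    testable = s2 > 0
    if not testable.any():
        return np.full(len(s2), np.nan)
    d0, s0sq = _fit_scaled_invchisq(s2[testable], df)
    d0_eff = min(d0, 1e6)  # effectively-normal tail when the prior df diverge
    s2_post = (d0_eff * s0sq + df * s2) / (d0_eff + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df + d0_eff)
    p[~np.isfinite(t)] = np.nan
    return p


def two_group_test(
    expr: ExpressionMatrix,
    method: str = "welch",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-sided per-feature p-values on log2(x + pseudocount) values.

    Returns a DataFrame with columns ``p_value`` and ``untestable``.
    Features whose log values are constant and equal across all samples
    carry no signal: they get p = 1.0 and ``untestable = True`` so that
    downstream gates remain total functions.  Features with zero
    within-group variance but different group means are perfectly
    separated and get p = 0.0.
    """
    if method not in ("welch", "moderated"):
        raise ConfigError(f"unknown test method {method!r}")
    a, b = _log_groups(expr, pseudocount)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ConfigError(
            "two_group_test requires at least 2 samples per group "
            f"(got {a.shape[1]} cancer, {b.shape[1]} control)"
        )
    p = _welch(a, b) if method == "welch" else _moderated(a, b)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    untestable = zero_var & (mean_diff == 0)
    p = np.where(untestable, 1.0, p)
    p = np.where(zero_var & (mean_diff != 0), 0.0, p)
    # any remaining NaN (degenerate variance fit) is treated as no evidence
    untestable = untestable | ~np.isfinite(p)
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(
        {"p_value": np.clip(p, 0.0, 1.0), "untestable": untestable},
        index=expr.values.index,
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    method: str = "welch",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature DE table with the fold-change and FDR gate applied.

    Returns a DataFrame indexed by feature id with columns ``log2fc``,
    ``p_value``, ``fdr``, ``significant`` and ``untestable``.  A feature
    is significant iff ``fdr < alpha`` and ``|log2fc| > log2(fc_threshold)``.
    """
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    if fc_threshold <= 1:
        raise ConfigError("fc_threshold must exceed 1")
    log2fc = compute_log2fc(expr, pseudocount)
    test = two_group_test(expr, method=method, pseudocount=pseudocount)
    fdr = bh_adjust(test["p_value"].to_numpy())
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": test["p_value"],
            "fdr": fdr,
            "untestable": test["untestable"],
        },
        index=expr.values.index,
    )
    out["significant"] = (out["fdr"] < alpha) & (
        out["log2fc"].abs() > np.log2(fc_threshold)
    )
    out.index.name = "feature_id"
    return out[["log2fc", "p_value", "fdr", "significant", "untestable"]]


def restrict_to_features(
    results: pd.DataFrame,
    feature_ids: Iterable[str],
    readjust: bool = False,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Subset a DE table to a feature list (e.g. the cell-fate genes).

    By default the rows keep the FDR computed over the full family; with
    ``readjust=True`` the BH adjustment and the significance gate are
    recomputed within the subset only.
    """
    ids = [f for f in feature_ids if f in results.index]
    sub = results.loc[ids].copy()
    if readjust and len(sub):
        sub["fdr"] = bh_adjust(sub["p_value"].to_numpy())
        sub["significant"] = (sub["fdr"] < alpha) & (
            sub["log2fc"].abs() > np.log2(fc_threshold)
        )
    return sub
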