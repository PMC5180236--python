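"""Between-sample normalization and moderated two-group differential analysis.

Count libraries (16S genus tables or gene-level expression counts) are scaled
with trimmed-mean-of-M-values (TMM) factors, converted to log2
counts-per-million (log2-cpm), and tested feature-wise with a two-group
linear model whose residual variances are shrunk toward an empirical-Bayes
prior.  The moderated variance for feature *g* is the posterior mean

    s2_post = (d0 * s0^2 + d * s2_g) / (d0 + d)

where ``d`` is the residual degrees of freedom, and the prior ``(d0, s0^2)``
is estimated by moment-matching the observed sample variances to a scaled-F
distribution.  The moderated t-statistic is referred to a t distribution on
``d0 + d`` degrees of freedom.  Features are called *differential* with the
combined rule |fold change| > ``fc_thresh`` and p < ``p_thresh``.

An optional mean-variance precision-weighting scheme (lowess trend of the
square-root residual standard deviation against average log-count, inverted
to observation-level weights) is provided for count data where the variance
depends strongly on abundance.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError

METADATA_COLUMNS = ("arm", "timepoint", "subject")
#: B = before therapy, E = early (1 h), A = after (34 d)
TIMEPOINTS = ("B", "E", "A")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AbundanceTable:
    """Feature x sample count matrix with per-sample metadata.

    ``counts`` has feature ids as the row index and sample ids as columns;
    entries are non-negative integers.  ``metadata`` is indexed by sample id
    and carries at least ``arm``, ``timepoint`` and ``subject`` columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise DataError("empty abundance table (no features or no samples)")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise DataError(f"duplicate feature ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dup}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise DataError("negative counts in abundance table")
        if not np.allclose(vals, np.round(vals)):
            raise DataError("non-integer counts in abundance table")
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing_cols:
            raise DataError(f"metadata lacks required columns: {missing_cols}")
        absent = [s for s in self.counts.columns if s not in self.metadata.index]
        if absent:
            raise DataError(f"samples without metadata: {absent}")
        bad_tp = set(self.metadata.loc[list(self.counts.columns), "timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise DataError(f"unknown timepoint codes: {sorted(bad_tp)}")
        # keep metadata aligned and restricted to the samples present
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def filter(self, arms: Sequence[str] | None = None,
               timepoints: Sequence[str] | None = None) -> "AbundanceTable":
        """Subset samples by arm and/or timepoint."""
        keep = pd.Series(True, index=self.samples)
        if arms is not None:
            known = set(self.metadata["arm"])
            unknown = set(arms) - known
            if unknown:
                raise DataError(f"unknown arm labels: {sorted(unknown)}")
            keep &= self.metadata["arm"].isin(arms)
        if timepoints is not None:
            keep &= self.metadata["timepoint"].isin(timepoints)
        cols = self.samples[keep.to_numpy()]
        if len(cols) == 0:
            raise DataError("sample filter removed every sample")
        return AbundanceTable(self.counts[cols], self.metadata.loc[cols].copy())


@dataclasses.dataclass
class NormalizedTable:
    """TMM-normalized abundances alongside the log2-cpm transform.

    ``normalized`` is count / (library size x TMM factor) x 1e6 — normalized
    abundance on the cpm scale, before any log transform.
    """

    factors: pd.Series
    lib_size: pd.Series
    normalized: pd.DataFrame
    log_cpm: pd.DataFrame
    metadata: pd.DataFrame


@dataclasses.dataclass
class DiffResult:
    """Per-feature moderated differential-analysis results.

    ``table`` columns: logFC (log2, group1 minus group2), AveExpr, t, p,
    p_adj (Benjamini-Hochberg), flag.
    """

    table: pd.DataFrame
    groups: tuple[str, str]
    prior_df: float
    prior_var: float
    residual_df: float

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "feature", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @staticmethod
    def read_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", index_col="feature")


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, sum_trim: float, do_weighting: bool) -> float:
    """Scaling factor of one library against the reference library.

    Weighted trimmed mean of M-values: features with a zero in either
    library are excluded, the log-ratios M are trimmed by `logratio_trim`
    on each tail and the average log-abundances A by `sum_trim`, and the
    surviving M values are averaged with inverse asymptotic-variance
    (delta-method binomial) weights.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(log_r)
    rank_s = rankdata(abs_e)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    if do_weighting:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def compute_tmm_factors(counts: pd.DataFrame | AbundanceTable,
                        reference: str | None = None,
                        logratio_trim: float = 0.3,
                        sum_trim: float = 0.05,
                        do_weighting: bool = True) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference library, unless given, is the sample whose 75th-percentile
    count-to-library-size ratio is closest to the across-sample mean of that
    ratio.
    """
    if isinstance(counts, AbundanceTable):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    dead = np.flatnonzero(lib == 0)
    if dead.size:
        names = [str(counts.columns[j]) for j in dead]
        raise DataError(f"all-zero sample(s): {names}")
    if reference is None:
        f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        try:
            ref_idx = counts.columns.get_loc(reference)
        except KeyError as exc:
            raise ConfigError(f"reference sample {reference!r} not in table") from exc
    factors = np.array([
        _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx],
                  logratio_trim, sum_trim, do_weighting)
        for j in range(mat.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def to_log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
               prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a library-size-scaled prior count.

    Convention: the prior count is scaled per sample in proportion to the
    effective library size (library size x TMM factor), and the denominator
    is augmented by twice the scaled prior:

        log2( (count + prior_j) / (L_j + 2 * prior_j) * 1e6 )

    so that, e.g., a zero count at prior 0.5, factor 1 and library 1e6
    maps to log2(0.5) up to a term of order prior/L.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if factors is None:
        f = np.ones(mat.shape[1])
    else:
        f = np.asarray(factors.loc[counts.columns] if isinstance(factors, pd.Series) else factors,
                       dtype=float)
    if (f <= 0).any():
        raise ConfigError("TMM factors must be positive")
    eff = lib * f
    prior = prior_count * eff / eff.mean()
    out = np.log2((mat + prior) / (eff + 2.0 * prior) * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def normalize(table: AbundanceTable, prior_count: float = 0.5,
              reference: str | None = None) -> NormalizedTable:
    """TMM-normalize an abundance table and attach its log2-cpm transform."""
    factors = compute_tmm_factors(table.counts, reference=reference)
    lib = table.counts.sum(axis=0).astype(float)
    lib.name = "lib_size"
    normalized = table.counts / (lib * factors) * 1e6
    log_cpm = to_log_cpm(table.counts, factors, prior_count)
    return NormalizedTable(factors=factors, lib_size=lib, normalized=normalized,
                           log_cpm=log_cpm, metadata=table.metadata.copy())


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton iteration on the trigamma function; monotone decreasing on (0, inf)
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def fit_scaled_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match sample variances to a scaled-F distribution.

    Returns the prior degrees of freedom ``d0`` (possibly ``inf``) and the
    prior variance ``s0^2``.  Works on the log scale: for s2 ~ s0^2 * F(df, d0)
    the log has a known mean and variance in terms of digamma/trigamma, which
    are inverted here.
    """
    x = np.asarray(s2, dtype=float)
    x = x[x > 0]
    if x.size < 2:
        return math.inf, float(np.exp(np.mean(np.log(x)))) if x.size else 1.0
    z = np.log(x)
    e = z - float(digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # no excess spread beyond sampling noise: the pooled mean variance is
        # the maximum-likelihood scale in the infinite-prior-df limit
        d0 = math.inf
        s20 = float(np.mean(x))
    return d0, s20


def fit_moderated(log_cpm: pd.DataFrame,
                  labels: Mapping[str, str] | pd.Series | Sequence[str],
                  groups: tuple[str, str] | None = None,
                  prior_df: float | str = "auto",
                  weights: pd.DataFrame | None = None) -> DiffResult:
    """Two-group moderated linear model on a log-intensity matrix.

    ``labels`` assigns each sample (column) to a group; ``groups`` fixes the
    contrast order (logFC = mean(groups[0]) - mean(groups[1])), defaulting to
    order of first appearance.  ``prior_df`` is ``"auto"`` (moment-matched),
    ``0`` (ordinary t) or a fixed numeric prior df.  Optional observation
    weights (same shape as the matrix) give a weighted fit.
    """
    if isinstance(labels, Mapping):
        lab = pd.Series({s: labels[s] for s in log_cpm.columns})
    else:
        lab = pd.Series(np.asarray(labels), index=log_cpm.columns) \
            if not isinstance(labels, pd.Series) else labels.loc[log_cpm.columns]
    if groups is None:
        uniq = list(dict.fromkeys(lab))
        if len(uniq) != 2:
            raise ConfigError(f"need exactly 2 groups, found {uniq}")
        groups = (uniq[0], uniq[1])
    g1, g2 = groups
    m1 = (lab == g1).to_numpy()
    m2 = (lab == g2).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise DataError(f"each group needs >= 2 samples (got {int(m1.sum())} {g1!r}, "
                        f"{int(m2.sum())} {g2!r})")
    cols = log_cpm.columns[m1 | m2]
    Y = log_cpm.loc[:, cols].to_numpy(dtype=float)
    sel1 = m1[m1 | m2]
    sel2 = m2[m1 | m2]
    if weights is not None:
        W = weights.loc[log_cpm.index, cols].to_numpy(dtype=float)
        if (W <= 0).any():
            raise DataError("observation weights must be positive")
    else:
        W = np.ones_like(Y)

    def _wmean(sel):
        sw = W[:, sel].sum(axis=1)
        return (W[:, sel] * Y[:, sel]).sum(axis=1) / sw, sw

    mu1, sw1 = _wmean(sel1)
    mu2, sw2 = _wmean(sel2)
    rss = ((W[:, sel1] * (Y[:, sel1] - mu1[:, None]) ** 2).sum(axis=1)
           + (W[:, sel2] * (Y[:, sel2] - mu2[:, None]) ** 2).sum(axis=1))
    df_resid = float(sel1.sum() + sel2.sum() - 2)
    s2 = rss / df_resid
    stdev_unscaled = np.sqrt(1.0 / sw1 + 1.0 / sw2)
    logfc = mu1 - mu2

    if prior_df == "auto":
        d0, s20 = fit_scaled_f_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ConfigError("prior_df must be >= 0")
        _, s20 = (0.0, float("nan")) if d0 == 0 else fit_scaled_f_prior(s2, df_resid)

    if d0 == 0:
        s2_post = s2
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s20)
    else:
        s2_post = (d0 * s20 + df_resid * s2) / (d0 + df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(s2_post) * stdev_unscaled)
    # the prior information cannot exceed the pooled residual information
    df_total = min(df_resid + d0, len(s2) * df_resid)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "logFC": logfc,
        "AveExpr": Y.mean(axis=1),
        "t": t,
        "p": p,
        "p_adj": p_adj,
        "flag": False,
    }, index=log_cpm.index)
    return DiffResult(table=table, groups=(g1, g2), prior_df=d0,
                      prior_var=s20, residual_df=df_resid)


def call_differential(result: DiffResult, fc_thresh: float = 2.0,
                      p_thresh: float = 0.05, use_adjusted: bool = False) -> pd.Index:
    """Flag features with |fold change| > fc_thresh and p < p_thresh.

    ``fc_thresh`` is on the linear scale (2 means two-fold).  Returns the
    flagged feature ids and records the flag in ``result.table``.
    """
    if fc_thresh <= 0 or p_thresh <= 0:
        raise ConfigError("thresholds must be positive")
    pcol = "p_adj" if use_adjusted else "p"
    flag = (result.table["logFC"].abs() > np.log2(fc_thresh)) & (result.table[pcol] < p_thresh)
    result.table["flag"] = flag
    return result.table.index[flag]


# ---------------------------------------------------------------------------
# mean-variance precision weights
# ---------------------------------------------------------------------------

def voom_weights(counts: pd.DataFrame, factors: pd.Series,
                 labels: Mapping[str, str] | pd.Series | Sequence[str],
                 span: float = 0.5) -> pd.DataFrame:
    """Observation-level precision weights from the mean-variance trend.

    Fits the group-means model on log2-cpm, lowess-smooths the square-root
    residual standard deviation against average log2 count, predicts the
    trend at each observation's fitted log-count, and returns
    1 / trend^4 as weights.
    """
    if isinstance(labels, Mapping):
        lab = pd.Series({s: labels[s] for s in counts.columns})
    elif isinstance(labels, pd.Series):
        lab = labels.loc[counts.columns]
    else:
        lab = pd.Series(np.asarray(labels), index=counts.columns)
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    eff = lib * np.asarray(factors.loc[counts.columns], dtype=float)
    y = np.log2((mat + 0.5) / (eff + 1.0) * 1e6)
    fitted = np.empty_like(y)
    rss = np.zeros(mat.shape[0])
    df = 0
    for g in dict.fromkeys(lab):
        sel = (lab == g).to_numpy()
        mu = y[:, sel].mean(axis=1)
        fitted[:, sel] = mu[:, None]
        rss += ((y[:, sel] - mu[:, None]) ** 2).sum(axis=1)
        df += int(sel.sum()) - 1
    sigma = np.sqrt(rss / max(df, 1))
    sx = y.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    fitted_logcount = fitted + np.log2(eff + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_logcount, tx, ty)
    w = 1.0 / pred ** 4
    return pd.DataFrame(w, index=counts.index, columns=counts.columns)
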