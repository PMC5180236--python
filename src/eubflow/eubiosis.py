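"""Eubiotic/dysbiotic frequency statistic and therapy contingency tests.

Each genus carries a literature label — *harmful*, *unharmful* or *unknown*.
For a therapy arm, the signed per-genus abundance delta (after minus before
therapy, on the TMM-normalized scale) is split by label and sign:

* eubiotic frequency  = sum |delta| over unharmful genera that increased
  plus harmful genera that decreased,
* dysbiotic frequency = sum |delta| over unharmful genera that decreased
  plus harmful genera that increased,

with unknown-labeled genera and exactly-zero deltas contributing to neither.
Two therapies are compared on the 2x2 table of their rounded
(eubiotic, dysbiotic) pairs with a chi-square test and Fisher's exact test;
the one-sided Fisher alternative is that the row therapy is *more eubiotic*
than the column therapy.

Because Fisher's test needs integer counts while the frequencies are sums of
continuous deltas, the default rounding scale normalizes each arm's summed
|delta| to its *effective* number of contributing genera,
n_eff = (sum |delta|)^2 / sum delta^2 (the Kish effective sample size of the
|delta| weights), before rounding half-up.  Under a random-sign null the
scaled difference (eubiotic - dysbiotic) then has standard deviation
sqrt(n_eff), exactly the binomial/hypergeometric standard deviation that
Fisher's test assumes at that total count, so the test behaves as a
correctly calibrated |delta|-weighted sign test.  Scaling to the raw genus
count ("per-genus") or by a fixed numeric factor is also accepted but is
anticonservative when the |delta| weights are uneven.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .normdiff import NormalizedTable

LABELS = ("harmful", "unharmful", "unknown")


# ---------------------------------------------------------------------------
# genus annotation registry
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenusAnnotation:
    """genus -> harmful/unharmful/unknown, with a provenance note per genus."""

    labels: pd.Series
    provenance: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise DataError(f"unknown annotation labels: {sorted(bad)}")


def load_registry(path) -> GenusAnnotation:
    """Read a genus annotation registry TSV (columns: genus, label[, citation]).

    Duplicate rows with conflicting labels are a validation error; duplicate
    consistent rows collapse.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genus", "label"}
    if not required.issubset(df.columns):
        raise DataError(f"registry must have columns {sorted(required)}, got {list(df.columns)}")
    conflicts = (df.groupby("genus")["label"].nunique() > 1)
    if conflicts.any():
        raise DataError("conflicting registry labels for genera: "
                        f"{sorted(conflicts.index[conflicts])}")
    df = df.drop_duplicates("genus")
    labels = df.set_index("genus")["label"]
    prov = df.set_index("genus").get("citation", pd.Series("", index=labels.index))
    prov = prov.fillna("")
    return GenusAnnotation(labels=labels, provenance=prov)


def annotate_genera(genera: Sequence[str], registry: GenusAnnotation) -> pd.Series:
    """Label each genus from the registry; absent genera become 'unknown'."""
    genera = pd.Index(genera)
    labels = registry.labels.reindex(genera)
    absent = genera[labels.isna()]
    if len(absent):
        warnings.warn(f"{len(absent)} genera absent from registry labeled 'unknown': "
                      f"{sorted(absent)[:10]}", stacklevel=2)
    return labels.fillna("unknown").rename("label")


# ---------------------------------------------------------------------------
# abundance deltas
# ---------------------------------------------------------------------------

def abundance_delta(norm: NormalizedTable, arm: str, mode: str = "arm-mean",
                    genera: Sequence[str] | None = None,
                    before: str = "B", after: str = "A") -> pd.Series:
    """Per-genus signed after-minus-before delta of TMM-normalized abundance.

    mode "arm-mean": difference of arm-level mean abundance;
    mode "per-subject": mean of paired per-subject differences.
    """
    if mode not in ("arm-mean", "per-subject"):
        raise ConfigError(f"unknown delta mode {mode!r}")
    meta = norm.metadata
    sub = meta[meta["arm"] == arm]
    if len(sub) == 0:
        raise DataError(f"no samples for arm {arm!r}")
    cols_b = sub.index[sub["timepoint"] == before]
    cols_a = sub.index[sub["timepoint"] == after]
    if len(cols_b) == 0 or len(cols_a) == 0:
        raise DataError(f"arm {arm!r} lacks timepoint "
                        f"{before if len(cols_b) == 0 else after!r} samples")
    table = norm.normalized if genera is None else norm.normalized.loc[list(genera)]
    if mode == "arm-mean":
        delta = table[cols_a].mean(axis=1) - table[cols_b].mean(axis=1)
    else:
        subj_a = sub.loc[cols_a, "subject"]
        subj_b = sub.loc[cols_b, "subject"]
        shared = sorted(set(subj_a) & set(subj_b))
        if not shared:
            raise DataError(f"arm {arm!r}: no subjects observed at both timepoints")
        diffs = []
        for s in shared:
            ca = subj_a.index[subj_a == s][0]
            cb = subj_b.index[subj_b == s][0]
            diffs.append(table[ca] - table[cb])
        delta = pd.concat(diffs, axis=1).mean(axis=1)
    return delta.rename("delta")


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EubiosisSummary:
    arm: str
    eubiotic: float
    dysbiotic: float
    eubiotic_rounded: int
    dysbiotic_rounded: int
    ledger: pd.DataFrame     # genus, delta, label, side
    scale: float | str

    @property
    def n_contributing(self) -> int:
        return int(self.ledger["side"].isin(["eubiotic", "dysbiotic"]).sum())


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def eubiosis_frequencies(deltas: pd.Series, labels: Mapping[str, str] | pd.Series,
                         arm: str = "", scale: float | str = "effective") -> EubiosisSummary:
    """Split summed |delta| into eubiotic and dysbiotic frequencies.

    ``scale`` controls the integerization used by the contingency tests:
    "effective" (default) rescales each arm so the total weight equals the
    Kish effective number of contributing genera, (sum|d|)^2 / sum d^2,
    which variance-matches Fisher's null; "per-genus" rescales to the raw
    count of contributing genera; a positive float multiplies the raw
    frequencies.  The unrounded values and the per-genus ledger are always
    retained.
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    lab = labels.reindex(deltas.index)
    if lab.isna().any():
        missing = sorted(deltas.index[lab.isna()])
        warnings.warn(f"genera without labels treated as unknown: {missing[:10]}",
                      stacklevel=2)
        lab = lab.fillna("unknown")
    d = deltas.to_numpy(dtype=float)
    lv = lab.to_numpy()
    eub_mask = ((lv == "unharmful") & (d > 0)) | ((lv == "harmful") & (d < 0))
    dys_mask = ((lv == "unharmful") & (d < 0)) | ((lv == "harmful") & (d > 0))
    side = np.where(eub_mask, "eubiotic", np.where(dys_mask, "dysbiotic", "excluded"))
    eub = float(np.abs(d[eub_mask]).sum())
    dys = float(np.abs(d[dys_mask]).sum())
    ledger = pd.DataFrame({"genus": deltas.index, "delta": d, "label": lv, "side": side})
    n_contrib = int(eub_mask.sum() + dys_mask.sum())
    total = eub + dys
    if scale == "effective":
        ss = float(np.sum(d[eub_mask | dys_mask] ** 2))
        c = total / ss if ss > 0 else 0.0   # total * c = total^2 / ss = n_eff
    elif scale == "per-genus":
        c = n_contrib / total if total > 0 else 0.0
    else:
        c = float(scale)
        if c <= 0:
            raise ConfigError("rounding scale must be positive")
    return EubiosisSummary(arm=arm, eubiotic=eub, dysbiotic=dys,
                           eubiotic_rounded=_round_half_up(eub * c),
                           dysbiotic_rounded=_round_half_up(dys * c),
                           ledger=ledger, scale=scale)


# ---------------------------------------------------------------------------
# exact and chi-square contingency tests
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ContingencyResult:
    table: np.ndarray
    arms: tuple[str, str]
    chi2: float
    chi2_p: float
    fisher_two_sided: float
    fisher_one_sided: float   # alternative: row-1 therapy more eubiotic
    odds_ratio: float


def fisher_exact_2x2(table: np.ndarray) -> tuple[float, float, float, float]:
    """Fisher's exact test on a 2x2 table by hypergeometric summation.

    Returns (p_greater, p_less, p_two_sided, odds_ratio), where "greater"
    is the alternative that cell (0,0) is larger than expected under the
    fixed margins.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError("Fisher test needs a non-negative 2x2 integer table")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if min(r1, n - r1, c1, n - c1) == 0:
        warnings.warn("degenerate margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return 1.0, 1.0, 1.0, float("nan")
    rv = stats.hypergeom(n, c1, r1)
    kmin = max(0, r1 - (n - c1))
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = rv.pmf(ks)
    p_obs = pmf[a - kmin]
    p_greater = float(min(1.0, pmf[ks >= a].sum()))
    p_less = float(min(1.0, pmf[ks <= a].sum()))
    p_two = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    b, c, d = int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return p_greater, p_less, p_two, odds


def contingency_test(summary_a: EubiosisSummary, summary_b: EubiosisSummary,
                     yates: bool = True) -> ContingencyResult:
    """Compare two arms' rounded (eubiotic, dysbiotic) pairs.

    One-sided Fisher alternative: the first (row) therapy leads to a more
    eubiotic composition than the second.  A zero margin yields Fisher p = 1
    by convention (with a warning) and chi-square reported as NaN.
    """
    table = np.array([[summary_a.eubiotic_rounded, summary_a.dysbiotic_rounded],
                      [summary_b.eubiotic_rounded, summary_b.dysbiotic_rounded]], dtype=int)
    arms = (summary_a.arm, summary_b.arm)
    n = table.sum()
    degenerate = (min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0) or n == 0
    if degenerate:
        warnings.warn(f"zero margin comparing {arms}; p-values set to 1", stacklevel=2)
        return ContingencyResult(table=table, arms=arms, chi2=float("nan"),
                                 chi2_p=float("nan"), fisher_two_sided=1.0,
                                 fisher_one_sided=1.0, odds_ratio=float("nan"))
    chi2, chi2_p = stats.chi2_contingency(table, correction=yates)[:2]
    p_greater, _, p_two, odds = fisher_exact_2x2(table)
    return ContingencyResult(table=table, arms=arms, chi2=float(chi2),
                             chi2_p=float(chi2_p), fisher_two_sided=p_two,
                             fisher_one_sided=p_greater, odds_ratio=odds)


@dataclasses.dataclass
class PairwiseResult:
    pvalues: pd.DataFrame    # rows: therapy A, cols: therapy B; one-sided Fisher p
    flags: pd.DataFrame      # p < alpha
    results: dict


def pairwise_therapy_matrix(summaries: Sequence[EubiosisSummary], alpha: float = 0.05,
                            yates: bool = True) -> PairwiseResult:
    """Asymmetric matrix of one-sided Fisher p-values across therapy arms.

    Cell (A, B) tests whether therapy A is more eubiotic than therapy B.
    """
    if len(summaries) < 2:
        raise ConfigError("need at least 2 arms for a pairwise matrix")
    arms = [s.arm for s in summaries]
    if len(set(arms)) != len(arms):
        raise ConfigError(f"duplicate arm names in summaries: {arms}")
    p = pd.DataFrame(np.nan, index=arms, columns=arms)
    results: dict = {}
    for sa in summaries:
        for sb in summaries:
            res = contingency_test(sa, sb, yates=yates)
            p.loc[sa.arm, sb.arm] = res.fisher_one_sided
            results[(sa.arm, sb.arm)] = res
    flags = p < alpha
    return PairwiseResult(pvalues=p, flags=flags, results=results)
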