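"""Multi-method gene-set enrichment and the spatiotemporal robustness grid.

Three methodological variants are provided for testing whether a
differential gene list is enriched for a curated set: an exact
hypergeometric over-representation test (raw p), the same with
Benjamini-Hochberg adjustment across sets, and a permutation running-sum
enrichment score over a ranked gene list (GSEA-style, gene-label
permutation null).  Per-(context x set x method) outcomes aggregate into a
grid whose cells count how many tested analysis variants confirm the
enrichment of a spatiotemporal context (tissue x timepoint x arm) for a
functional phase.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError(f"gene set {self.name!r} is empty")


class GeneSetCollection(dict):
    """Ordered mapping of set name -> GeneSet."""

    def add(self, gs: GeneSet) -> None:
        if gs.name in self:
            raise DataError(f"duplicate gene set name {gs.name!r}")
        self[gs.name] = gs


def _norm_id(g: str) -> str:
    return g.strip().upper()


def load_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file (name, description, then one gene per column).

    Gene ids are case-normalized to upper case; duplicates within a line
    collapse with a warning; a line without genes is an error.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: line {lineno}: gene set with no genes")
            name, desc = parts[0], parts[1]
            genes = [_norm_id(g) for g in parts[2:] if g.strip()]
            if not genes:
                raise DataError(f"{path}: line {lineno}: gene set with no genes")
            if len(genes) != len(set(genes)):
                warnings.warn(f"{path}: line {lineno}: duplicated genes in set "
                              f"{name!r} collapsed", stacklevel=2)
            coll.add(GeneSet(name=name, description=desc, genes=frozenset(genes)))
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in coll.values():
            fh.write("\t".join([gs.name, gs.description] + sorted(gs.genes)) + "\n")


# ---------------------------------------------------------------------------
# hypergeometric over-representation
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(query: Iterable[str], gene_set: Iterable[str],
                              universe: Iterable[str]) -> float:
    """P(X >= k) for the overlap k of query and set drawn from the universe.

    X ~ Hypergeometric(N=|universe|, K=|set|, n=|query|).  Both query and
    set must be contained in the universe; offenders are reported.
    """
    uni = {_norm_id(g) for g in universe}
    q = {_norm_id(g) for g in query}
    s = {_norm_id(g) for g in gene_set}
    stray_q = q - uni
    if stray_q:
        raise DataError(f"query genes outside universe: {sorted(stray_q)[:10]}")
    stray_s = s - uni
    if stray_s:
        raise DataError(f"gene-set genes outside universe: {sorted(stray_s)[:10]}")
    n_uni, n_set, n_query = len(uni), len(s), len(q)
    k = len(q & s)
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, n_uni, n_set, n_query)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation running-sum enrichment
# ---------------------------------------------------------------------------

def _running_sum_es(hits: np.ndarray, weights: np.ndarray | None) -> float:
    n = hits.size
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        raise DataError("gene set must hit some but not all of the ranked list")
    if weights is None:
        inc = np.where(hits, 1.0 / nh, 0.0)
    else:
        w = np.abs(weights)
        denom = w[hits].sum()
        if denom == 0:
            inc = np.where(hits, 1.0 / nh, 0.0)
        else:
            inc = np.where(hits, w / denom, 0.0)
    dec = np.where(~hits, 1.0 / (n - nh), 0.0)
    run = np.cumsum(inc - dec)
    # cumulative rounding can overshoot the theoretical bounds by ~1 ulp
    return float(np.clip(run[np.argmax(np.abs(run))], -1.0, 1.0))


def permutation_es(ranked: Sequence[str], gene_set: Iterable[str],
                   stats_values: Sequence[float] | None = None,
                   weight: float = 0.0, n_perm: int = 1000,
                   seed: int | None = None) -> tuple[float, float, float]:
    """Running-sum enrichment score with a gene-label permutation null.

    ``ranked`` is the gene universe ordered by a ranking statistic (best
    first); hits increment the running sum by |stat|^weight normalized over
    the set's hits (uniformly when weight = 0), misses decrement by
    1/(N - set size).  ES is the maximum-magnitude deviation; the
    permutation p-value is (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1), and
    NES is ES divided by the mean permuted |ES|.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    genes = [_norm_id(g) for g in ranked]
    if len(genes) != len(set(genes)):
        raise DataError("ranked list contains duplicate gene ids")
    sset = {_norm_id(g) for g in gene_set}
    stray = sset - set(genes)
    if stray:
        raise DataError(f"gene-set genes outside ranked universe: {sorted(stray)[:10]}")
    hits = np.array([g in sset for g in genes])
    if weight != 0.0:
        if stats_values is None:
            raise ConfigError("weight > 0 requires ranking statistics")
        w = np.power(np.abs(np.asarray(stats_values, dtype=float)), weight)
    else:
        w = None
    es = _running_sum_es(hits, w)
    rng = np.random.default_rng(seed)
    n = len(genes)
    nh = int(hits.sum())
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=nh, replace=False)
        ph = np.zeros(n, dtype=bool)
        ph[idx] = True
        perm_es[i] = _running_sum_es(ph, w)
    p = (1.0 + np.sum(np.abs(perm_es) >= abs(es))) / (n_perm + 1.0)
    mean_abs = float(np.mean(np.abs(perm_es)))
    nes = es / mean_abs if mean_abs > 0 else float("nan")
    return es, nes, float(p)


# ---------------------------------------------------------------------------
# robustness grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnrichmentRecord:
    """One enrichment outcome with its analysis-variant coordinates."""

    context: str          # e.g. "subcutaneous_1h_MS"
    gene_set: str
    method: str           # hypergeometric-raw | hypergeometric-bh | permutation-es
    layer: str = "mrna"
    batch: str = "batch1"
    statistic: float = float("nan")   # p for hypergeometric methods, ES for permutation
    p_adjusted: float = float("nan")
    significant: bool = False


@dataclasses.dataclass
class RobustnessGrid:
    """Contexts x phases matrix of confirming-variant counts (NA = untested)."""

    counts: pd.DataFrame   # Int64 with pd.NA for untested cells
    tested: pd.DataFrame   # number of variants tested per cell

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "context", out.index)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    @staticmethod
    def read_tsv(path) -> pd.DataFrame:
        df = pd.read_csv(path, sep="\t", index_col="context", na_values=["NA"])
        return df.astype("Int64")


def robustness_grid(records: Sequence[EnrichmentRecord],
                    phase_of: Mapping[str, str],
                    contexts: Sequence[str] | None = None,
                    phases: Sequence[str] | None = None) -> RobustnessGrid:
    """Aggregate enrichment records into the phase-confirmation grid.

    ``phase_of`` maps each gene-set variant to its functional phase column.
    Cell (context, phase) counts significant records among the variants
    tested there; untested cells are NA, distinct from a tested zero.
    Passing ``contexts``/``phases`` explicitly keeps rows or columns with no
    records (e.g. a context that yielded zero differential genes) in the
    grid as all-NA.  A duplicated (context, set, method, layer, batch)
    record is an error.
    """
    seen = set()
    for r in records:
        key = (r.context, r.gene_set, r.method, r.layer, r.batch)
        if key in seen:
            raise DataError(f"duplicate enrichment record: {key}")
        seen.add(key)
    unmapped = {r.gene_set for r in records} - set(phase_of)
    if unmapped:
        raise ConfigError(f"gene sets without a phase mapping: {sorted(unmapped)}")
    if contexts is None:
        contexts = list(dict.fromkeys(r.context for r in records))
    if phases is None:
        phases = list(dict.fromkeys(phase_of[r.gene_set] for r in records))
    counts = pd.DataFrame(pd.NA, index=list(contexts), columns=list(phases), dtype="Int64")
    tested = pd.DataFrame(0, index=list(contexts), columns=list(phases), dtype=int)
    for r in records:
        ph = phase_of[r.gene_set]
        tested.loc[r.context, ph] += 1
        cur = counts.loc[r.context, ph]
        base = 0 if pd.isna(cur) else int(cur)
        counts.loc[r.context, ph] = base + int(bool(r.significant))
    counts.index.name = "context"
    tested.index.name = "context"
    return RobustnessGrid(counts=counts, tested=tested)


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
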