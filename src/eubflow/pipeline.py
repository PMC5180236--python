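"""Orchestration of the two headline analyses.

``run_microbiome`` chains normalization -> per-arm differential analysis ->
Shannon diversity -> eubiotic/dysbiotic frequencies -> pairwise one-sided
Fisher matrix, and writes the report bundle (differential tables, diversity
report, p-value matrix with significance flags, per-genus highlight table,
provenance record).  ``run_enrichment`` runs every (context x gene set x
method) combination and aggregates the outcomes into the robustness grid.

All randomness flows through the single seed in the run configuration;
repeated runs with the same configuration produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import arm_diversity
from .enrichment import (EnrichmentRecord, GeneSetCollection, bh_adjust,
                         hypergeometric_enrichment, load_gene_sets,
                         permutation_es, records_to_frame, robustness_grid)
from .errors import ConfigError, DataError, EubflowError
from .eubiosis import (abundance_delta, annotate_genera, eubiosis_frequencies,
                       load_registry, pairwise_therapy_matrix)
from .io import read_abundance, read_expression
from .normdiff import call_differential, fit_moderated, normalize, voom_weights
from .synthdata import SimConfig, simulate_expression, simulate_microbiome

logger = logging.getLogger("eubflow")

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MicrobiomeRunConfig:
    seed: int
    out_dir: str
    synthetic: SimConfig | None = None
    counts: str | None = None
    metadata: str | None = None
    registry: str | None = None
    fc_thresh: float = 2.0
    p_thresh: float = 0.05
    use_adjusted: bool = False
    alpha: float = 0.05
    delta_mode: str = "arm-mean"
    rounding_scale: float | str = "effective"
    genera_scope: str = "differential"    # or "all"
    use_precision_weights: bool = False
    yates: bool = True
    plot: bool = True

    def __post_init__(self) -> None:
        if self.synthetic is None:
            missing = [k for k in ("counts", "metadata", "registry")
                       if getattr(self, k) is None]
            if missing:
                raise ConfigError(f"microbiome run needs {missing} when not synthetic")
            for k in ("counts", "metadata", "registry"):
                p = getattr(self, k)
                if not os.path.exists(p):
                    raise ConfigError(f"{k} file not found: {p}")
        if not (0 < self.p_thresh <= 1 and 0 < self.alpha <= 1):
            raise ConfigError("p_thresh and alpha must lie in (0, 1]")
        if self.fc_thresh <= 0:
            raise ConfigError("fc_thresh must be positive")
        if self.delta_mode not in ("arm-mean", "per-subject"):
            raise ConfigError(f"unknown delta_mode {self.delta_mode!r}")
        if self.genera_scope not in ("differential", "all"):
            raise ConfigError(f"unknown genera_scope {self.genera_scope!r}")


@dataclasses.dataclass
class EnrichmentContext:
    name: str                      # e.g. "subcutaneous_1h_MS"
    planted: tuple = ()            # set names planted in the synthetic matrix
    diff_genes: tuple | None = None   # pre-computed differential genes (non-synthetic)


@dataclasses.dataclass
class EnrichmentRunConfig:
    seed: int
    out_dir: str
    contexts: Sequence[EnrichmentContext]
    gene_sets: str | None = None          # GMT path; None -> synthetic default sets
    phase_of: Mapping[str, str] | None = None
    n_genes: int = 400
    group_sizes: tuple = (8, 8)
    effect: float = 2.0
    methods: tuple = ("hypergeometric-raw", "hypergeometric-bh", "permutation-es")
    n_perm: int = 500
    weight: float = 0.0
    alpha: float = 0.05
    fc_thresh: float = 2.0
    p_thresh: float = 0.05
    plot: bool = True

    def __post_init__(self) -> None:
        known = {"hypergeometric-raw", "hypergeometric-bh", "permutation-es"}
        bad = set(self.methods) - known
        if bad:
            raise ConfigError(f"unknown enrichment methods: {sorted(bad)}")
        if not self.contexts:
            raise ConfigError("enrichment run needs at least one context")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")


def load_run_config(path) -> dict:
    """Parse a YAML run configuration into typed config objects."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    if "seed" not in raw or "out_dir" not in raw:
        raise ConfigError(f"{path}: 'seed' and 'out_dir' are required")
    out: dict = {}
    common = {"seed": int(raw["seed"]), "out_dir": str(raw["out_dir"])}
    if "microbiome" in raw:
        sec = dict(raw["microbiome"])
        if "synthetic" in sec:
            syn = dict(sec.pop("synthetic") or {})
            syn.setdefault("seed", common["seed"])
            if "eubiotic_effect" in syn:
                syn["eubiotic_effect"] = {str(k): float(v)
                                          for k, v in syn["eubiotic_effect"].items()}
            if "arms" in syn:
                syn["arms"] = tuple(syn["arms"])
            sec["synthetic"] = SimConfig(**syn)
        try:
            out["microbiome"] = MicrobiomeRunConfig(**common, **sec)
        except TypeError as exc:
            raise ConfigError(f"{path}: invalid microbiome section: {exc}") from exc
    if "enrichment" in raw:
        sec = dict(raw["enrichment"])
        ctxs = [EnrichmentContext(name=str(c["name"]),
                                  planted=tuple(c.get("planted", ())))
                for c in sec.pop("contexts", [])]
        sec["contexts"] = ctxs
        if "group_sizes" in sec:
            sec["group_sizes"] = tuple(sec["group_sizes"])
        if "methods" in sec:
            sec["methods"] = tuple(sec["methods"])
        try:
            out["enrichment"] = EnrichmentRunConfig(**common, **sec)
        except TypeError as exc:
            raise ConfigError(f"{path}: invalid enrichment section: {exc}") from exc
    if not out:
        raise ConfigError(f"{path}: no 'microbiome' or 'enrichment' section")
    return out


def _config_hash(cfg) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (tuple, set)):
            return list(o)
        return str(o)
    payload = dataclasses.asdict(cfg)
    payload.pop("out_dir", None)   # hash the analysis, not the output location
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Bundle:
    """Tracks files written by a run so a failed stage can clean up."""

    def __init__(self, out_dir: str):
        self.out_dir = out_dir
        self.paths: list[str] = []
        os.makedirs(out_dir, exist_ok=True)

    def path(self, name: str) -> str:
        p = os.path.join(self.out_dir, name)
        self.paths.append(p)
        return p

    def discard(self) -> None:
        for p in self.paths:
            if os.path.exists(p):
                os.remove(p)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except EubflowError as exc:
                raise type(exc)(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def _save_heatmap(df: pd.DataFrame, path: str, title: str, annotate=None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = df.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(1.2 * df.shape[1] + 2, 0.8 * df.shape[0] + 2))
    im = ax.imshow(np.ma.masked_invalid(vals), cmap="viridis")
    ax.set_xticks(range(df.shape[1]), labels=[str(c) for c in df.columns],
                  rotation=45, ha="right")
    ax.set_yticks(range(df.shape[0]), labels=[str(i) for i in df.index])
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            if np.isfinite(vals[i, j]):
                txt = f"{vals[i, j]:.3g}"
                if annotate is not None and annotate.iloc[i, j]:
                    txt = f"*{txt}*"
                ax.text(j, i, txt, ha="center", va="center", color="white", fontsize=8)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# microbiome report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MicrobiomeReport:
    diff_results: dict
    diversity: object
    summaries: list
    pairwise: object
    highlights: pd.DataFrame
    paths: dict


def run_microbiome(config: MicrobiomeRunConfig) -> MicrobiomeReport:
    """Execute the full microbiome analysis and write the report bundle."""
    bundle = _Bundle(config.out_dir)
    try:
        return _run_microbiome_inner(config, bundle)
    except Exception:
        bundle.discard()
        raise


def _run_microbiome_inner(config: MicrobiomeRunConfig, bundle: _Bundle) -> MicrobiomeReport:
    if config.synthetic is not None:
        table, truth = _stage("simulate")(simulate_microbiome)(config.synthetic)
        labels_all = truth.records["label"]
    else:
        table = _stage("load")(read_abundance)(config.counts, config.metadata)
        registry = _stage("load")(load_registry)(config.registry)
        labels_all = annotate_genera(table.features, registry)

    norm = _stage("normalize")(normalize)(table)
    arms = list(dict.fromkeys(table.metadata["arm"]))

    # per-arm differential analysis: after (A) vs before (B)
    diff_results: dict = {}
    scope: set = set()
    for arm in arms:
        sub_meta = table.metadata[table.metadata["arm"] == arm]
        cols = sub_meta.index
        if config.use_precision_weights:
            w = voom_weights(table.counts[cols], norm.factors.loc[cols],
                             sub_meta["timepoint"])
        else:
            w = None
        res = _stage("differential")(fit_moderated)(
            norm.log_cpm[cols], sub_meta["timepoint"], groups=("A", "B"), weights=w)
        flagged = call_differential(res, config.fc_thresh, config.p_thresh,
                                    config.use_adjusted)
        diff_results[arm] = res
        scope |= set(flagged)
        res.to_tsv(bundle.path(f"diff_{arm}.tsv"))

    if config.genera_scope == "all":
        scope = set(table.features)
    if not scope:
        logger.warning("no differential genera in any arm; eubiosis tables will be empty")
    scope_list = [g for g in table.features if g in scope]

    report = _stage("diversity")(arm_diversity)(table)
    report.to_tsv(bundle.path("diversity_per_sample.tsv"),
                  bundle.path("diversity_per_arm.tsv"))

    summaries = []
    for arm in arms:
        deltas = _stage("eubiosis")(abundance_delta)(
            norm, arm, mode=config.delta_mode,
            genera=scope_list if scope_list else None)
        if not scope_list:
            deltas = deltas.iloc[0:0]
        summary = eubiosis_frequencies(deltas, labels_all.reindex(deltas.index),
                                       arm=arm, scale=config.rounding_scale)
        summaries.append(summary)
        summary.ledger.to_csv(bundle.path(f"eubiosis_ledger_{arm}.tsv"), sep="\t",
                              index=False, float_format=_FLOAT_FMT)
    summary_frame = pd.DataFrame([{
        "arm": s.arm, "eubiotic": s.eubiotic, "dysbiotic": s.dysbiotic,
        "eubiotic_rounded": s.eubiotic_rounded, "dysbiotic_rounded": s.dysbiotic_rounded,
        "n_contributing": s.n_contributing} for s in summaries])
    summary_frame.to_csv(bundle.path("eubiosis_summary.tsv"), sep="\t", index=False,
                         float_format=_FLOAT_FMT)

    pairwise = _stage("contingency")(pairwise_therapy_matrix)(
        summaries, alpha=config.alpha, yates=config.yates)
    pw = pairwise.pvalues.copy()
    pw.index.name = "arm"
    pw.to_csv(bundle.path("pairwise_fisher_p.tsv"), sep="\t", float_format=_FLOAT_FMT)
    fl = pairwise.flags.copy()
    fl.index.name = "arm"
    fl.to_csv(bundle.path("pairwise_flags.tsv"), sep="\t")

    # per-genus highlight table: arm-wise deltas with significance annotation
    rows = []
    for arm in arms:
        res = diff_results[arm]
        deltas = abundance_delta(norm, arm, mode=config.delta_mode)
        for genus in table.features:
            rows.append({
                "genus": genus, "arm": arm,
                "delta": float(deltas.loc[genus]),
                "label": str(labels_all.reindex([genus]).fillna("unknown").iloc[0]),
                "p": float(res.table.loc[genus, "p"]),
                "significant": bool(res.table.loc[genus, "p"] < config.p_thresh),
                "differential": bool(res.table.loc[genus, "flag"]),
            })
    highlights = pd.DataFrame(rows)
    highlights.to_csv(bundle.path("genus_highlights.tsv"), sep="\t", index=False,
                      float_format=_FLOAT_FMT)

    if config.plot:
        _save_heatmap(pairwise.pvalues, bundle.path("pairwise_fisher_p.png"),
                      "one-sided Fisher p (row more eubiotic than column)",
                      annotate=pairwise.flags)

    provenance = {
        "tool": "eubflow", "version": __version__, "seed": config.seed,
        "config_hash": _config_hash(config),
        "outputs": sorted(os.path.basename(p) for p in bundle.paths),
    }
    with open(bundle.path("provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return MicrobiomeReport(diff_results=diff_results, diversity=report,
                            summaries=summaries, pairwise=pairwise,
                            highlights=highlights,
                            paths={os.path.basename(p): p for p in bundle.paths})


# ---------------------------------------------------------------------------
# enrichment grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnrichmentReport:
    records: list
    grid: object
    paths: dict


def run_enrichment(config: EnrichmentRunConfig) -> EnrichmentReport:
    bundle = _Bundle(config.out_dir)
    try:
        return _run_enrichment_inner(config, bundle)
    except Exception:
        bundle.discard()
        raise


def _default_sets(n_genes: int) -> GeneSetCollection:
    from .enrichment import GeneSet
    universe = [f"GENE{i:04d}" for i in range(n_genes)]
    coll = GeneSetCollection()
    spans = {"Heal.E": (0, 30), "Mec.E": (30, 60), "EMT.T2": (60, 100),
             "InflGO": (100, 140)}
    for name, (a, b) in spans.items():
        coll.add(GeneSet(name, name, frozenset(universe[a:b])))
    return coll


def _run_enrichment_inner(config: EnrichmentRunConfig, bundle: _Bundle) -> EnrichmentReport:
    if config.gene_sets is not None:
        sets = _stage("load")(load_gene_sets)(config.gene_sets)
    else:
        sets = _default_sets(config.n_genes)
    phase_of = dict(config.phase_of) if config.phase_of else {n: n for n in sets}

    universe = [f"GENE{i:04d}" for i in range(config.n_genes)]
    records: list[EnrichmentRecord] = []
    rng_seed = np.random.SeedSequence(config.seed)
    for ci, ctx in enumerate(config.contexts):
        if ctx.diff_genes is not None:
            query = list(ctx.diff_genes)
            ranked = None
        else:
            planted = {n: sorted(sets[n].genes) for n in ctx.planted if n in sets}
            missing = set(ctx.planted) - set(sets)
            if missing:
                raise ConfigError(f"context {ctx.name!r} plants unknown sets: "
                                  f"{sorted(missing)}")
            expr, labels, _ = simulate_expression(
                config.n_genes, config.group_sizes, planted,
                effect=config.effect, seed=config.seed + 1000 * (ci + 1))
            res = fit_moderated(np.log2(expr), labels)
            query = list(call_differential(res, config.fc_thresh, config.p_thresh))
            ranked = res.table["t"].sort_values(ascending=False)
        if not query:
            logger.warning("context %s: zero differential genes; recording untested row",
                           ctx.name)
            continue
        hyper_p = {name: hypergeometric_enrichment(query, sets[name].genes, universe)
                   for name in sets}
        adj = dict(zip(hyper_p, bh_adjust(list(hyper_p.values()))))
        for name in sets:
            if "hypergeometric-raw" in config.methods:
                records.append(EnrichmentRecord(
                    context=ctx.name, gene_set=name, method="hypergeometric-raw",
                    statistic=hyper_p[name], p_adjusted=hyper_p[name],
                    significant=hyper_p[name] < config.alpha))
            if "hypergeometric-bh" in config.methods:
                records.append(EnrichmentRecord(
                    context=ctx.name, gene_set=name, method="hypergeometric-bh",
                    statistic=hyper_p[name], p_adjusted=adj[name],
                    significant=adj[name] < config.alpha))
            if "permutation-es" in config.methods and ranked is not None:
                child = int(np.random.default_rng(
                    rng_seed.spawn(1)[0]).integers(0, 2 ** 31 - 1))
                es, nes, p = permutation_es(list(ranked.index), sets[name].genes,
                                            stats_values=ranked.to_numpy(),
                                            weight=config.weight,
                                            n_perm=config.n_perm, seed=child)
                # one-sided call: enrichment toward the top of the ranking
                records.append(EnrichmentRecord(
                    context=ctx.name, gene_set=name, method="permutation-es",
                    statistic=es, p_adjusted=p,
                    significant=(p < config.alpha and es > 0)))

    frame = records_to_frame(records)
    frame.to_csv(bundle.path("enrichment_records.tsv"), sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    all_contexts = [c.name for c in config.contexts]
    grid = _stage("grid")(robustness_grid)(records, phase_of, contexts=all_contexts,
                                           phases=list(dict.fromkeys(phase_of.values())))
    grid.to_tsv(bundle.path("robustness_grid.tsv"))
    if config.plot:
        _save_heatmap(grid.counts.astype(float), bundle.path("robustness_grid.png"),
                      "confirming analysis variants per context and phase")
    provenance = {
        "tool": "eubflow", "version": __version__, "seed": config.seed,
        "config_hash": _config_hash(config),
        "outputs": sorted(os.path.basename(p) for p in bundle.paths),
    }
    with open(bundle.path("provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return EnrichmentReport(records=records, grid=grid,
                            paths={os.path.basename(p): p for p in bundle.paths})
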