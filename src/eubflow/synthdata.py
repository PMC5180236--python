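"""Synthetic paired microbiome, expression, qPCR and ELISA data with known truth.

The microbiome generator emulates a paired before/after 16S genus survey
across therapy arms: a cohort-level genus composition is drawn from a
Dirichlet, each subject perturbs it (a second Dirichlet around the cohort
mean), and counts are negative-binomial around the subject composition
scaled to the sequencing depth.  In "after" samples the genera annotated
harmful/unharmful are shifted on the log2 scale by the arm's eubiotic
effect — unharmful genera up and harmful genera down for a positive effect
(the eubiotic direction), reversed for a negative one — and the composition
is renormalized, so planted shifts also ripple compositionally through the
remaining genera, as they would in real relative-abundance data.

Every generated feature carries exactly one truth record (label, planted
direction, planted log2 effect per arm), enabling parameter-recovery,
calibration and power tests downstream without any external download.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet, GeneSetCollection, write_gene_sets
from .errors import ConfigError, DataError
from .normdiff import AbundanceTable
from .validation import four_pl

#: batch1 therapy arms; the paired before-therapy (B) samples are the
#: untreated CIA baseline state.
DEFAULT_ARMS = ("MS", "MTX", "PLA", "ANE", "NOCIA")
#: second-experiment arms, available by extending ``SimConfig.arms``
BATCH2_ARMS = ("CIA", "MTXMS", "NOCIAMS")

#: per-arm planted log2 eubiotic effects mirroring the qualitative pattern
#: the pipeline is meant to resolve: one strongly eubiotic arm (MS), a mildly
#: eubiotic placebo, a mildly dysbiotic drug arm, and two null arms.
DEFAULT_EFFECTS = {"MS": 1.5, "PLA": 0.75, "MTX": -0.75, "ANE": 0.0, "NOCIA": 0.0}


@dataclasses.dataclass
class SimConfig:
    """Generator settings for the paired microbiome simulation.

    ``depth`` is the expected reads per sample (10 000 by default, the
    batch1 sequencing depth).  ``eubiotic_effect`` maps arm -> signed log2
    shift applied to annotated genera in after-therapy samples.
    ``dispersion`` is the negative-binomial overdispersion phi in
    var = mu + phi * mu^2.
    """

    n_genera: int = 60
    # 55 animals over 5 therapy arms in the emulated first experiment
    n_subjects_per_arm: int = 11
    arms: tuple = DEFAULT_ARMS
    depth: int = 10_000
    frac_harmful: float = 0.3
    frac_unharmful: float = 0.3
    frac_unknown: float = 0.4
    eubiotic_effect: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    dispersion: float = 0.2
    subject_concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_harmful + self.frac_unharmful + self.frac_unknown
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"annotation fractions must sum to 1, got {total}")
        if min(self.frac_harmful, self.frac_unharmful, self.frac_unknown) < 0:
            raise ConfigError("annotation fractions must be non-negative")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.n_genera < 2:
            raise ConfigError("need at least 2 genera")
        if self.n_subjects_per_arm < 1:
            raise ConfigError("need at least 1 subject per arm")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if not self.arms:
            raise ConfigError("arms must be nonempty")
        stray = set(self.eubiotic_effect) - set(self.arms)
        if stray:
            raise ConfigError(f"eubiotic_effect refers to unknown arms: {sorted(stray)}")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")


@dataclasses.dataclass
class MicrobiomeTruth:
    """Per-genus annotation label and per-arm planted log2 effects."""

    records: pd.DataFrame   # index genus; columns: label, effect_<arm>...

    def label(self, genus: str) -> str:
        return str(self.records.loc[genus, "label"])

    def effect(self, genus: str, arm: str) -> float:
        return float(self.records.loc[genus, f"effect_{arm}"])

    def direction(self, genus: str, arm: str) -> str:
        e = self.effect(genus, arm)
        return "up" if e > 0 else ("down" if e < 0 else "none")

    def to_json(self, path) -> None:
        payload = {g: {"label": row["label"],
                       "effects": {c[len("effect_"):]: float(row[c])
                                   for c in self.records.columns if c.startswith("effect_")}}
                   for g, row in self.records.iterrows()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and var mu + phi*mu^2."""
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    size = 1.0 / phi
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_microbiome(config: SimConfig) -> tuple[AbundanceTable, MicrobiomeTruth]:
    """Paired before/after genus count tables with planted eubiotic shifts.

    Returns one AbundanceTable holding both timepoints (metadata column
    ``timepoint`` in {B, A}, samples paired by ``subject``) and the truth.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genera
    genera = [f"g{i:03d}__Genus{i:03d}" for i in range(g)]

    n_h = int(round(config.frac_harmful * g))
    n_u = int(round(config.frac_unharmful * g))
    n_h = min(n_h, g)
    n_u = min(n_u, g - n_h)
    labels = np.array(["harmful"] * n_h + ["unharmful"] * n_u + ["unknown"] * (g - n_h - n_u))
    rng.shuffle(labels)

    base = rng.dirichlet(np.ones(g))
    # planted per-arm log2 shifts: +e for unharmful, -e for harmful (eubiotic
    # when e > 0); unknown genera are never planted
    effects = {}
    for arm in config.arms:
        e = float(config.eubiotic_effect.get(arm, 0.0))
        arm_eff = np.zeros(g)
        arm_eff[labels == "unharmful"] = e
        arm_eff[labels == "harmful"] = -e
        effects[arm] = arm_eff

    counts = {}
    meta_rows = []
    for arm in config.arms:
        for s in range(config.n_subjects_per_arm):
            subject = f"{arm}{s + 1:02d}"
            comp = rng.dirichlet(base * config.subject_concentration + 1e-6)
            for tp in ("B", "A"):
                q = comp * (2.0 ** effects[arm]) if tp == "A" else comp
                q = q / q.sum()
                sample = f"{arm}_{tp}_{s + 1:02d}"
                counts[sample] = _nb_counts(rng, config.depth * q, config.dispersion)
                meta_rows.append({"sample": sample, "arm": arm, "timepoint": tp,
                                  "subject": subject})
    counts_df = pd.DataFrame(counts, index=genera)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    table = AbundanceTable(counts=counts_df, metadata=metadata)

    rec = pd.DataFrame({"label": labels}, index=pd.Index(genera, name="genus"))
    for arm in config.arms:
        rec[f"effect_{arm}"] = effects[arm]
    truth = MicrobiomeTruth(records=rec)
    return table, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionTruth:
    records: pd.DataFrame   # index gene; columns: planted (bool), effect

    def to_json(self, path) -> None:
        payload = {g: {"planted": bool(row["planted"]), "effect": float(row["effect"])}
                   for g, row in self.records.iterrows()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def gene_universe(n_genes: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n_genes)]


def simulate_expression(n_genes: int, group_sizes: tuple[int, int],
                        planted_sets: GeneSetCollection | Mapping[str, Sequence[str]],
                        effect: float, seed: int, sigma: float = 0.35,
                        group_labels: tuple[str, str] = ("treated", "control")
                        ) -> tuple[pd.DataFrame, pd.Series, ExpressionTruth]:
    """Log-normal expression with planted-set genes shifted in the first group.

    Returns (matrix of raw intensities, sample -> group labels, truth).
    Baseline log2 means are uniform on [3, 10]; ``sigma`` is the log2
    residual standard deviation; genes in any planted set gain ``effect``
    log2 units in the first group.
    """
    if n_genes < 2:
        raise ConfigError("need at least 2 genes")
    universe = gene_universe(n_genes)
    uni_set = set(universe)
    if isinstance(planted_sets, GeneSetCollection):
        members = {g for gs in planted_sets.values() for g in gs.genes}
    else:
        members = {g.strip().upper() for genes in planted_sets.values() for g in genes}
    stray = members - uni_set
    if stray:
        raise ConfigError(f"planted sets contain unknown gene ids: {sorted(stray)[:10]}")
    rng = np.random.default_rng(seed)
    n1, n2 = group_sizes
    if n1 < 2 or n2 < 2:
        raise ConfigError("each group needs >= 2 samples")
    base = rng.uniform(3.0, 10.0, size=n_genes)
    planted = np.array([g in members for g in universe])
    shift = np.where(planted, effect, 0.0)
    cols = ([f"{group_labels[0]}_{i + 1:02d}" for i in range(n1)]
            + [f"{group_labels[1]}_{i + 1:02d}" for i in range(n2)])
    labels = pd.Series([group_labels[0]] * n1 + [group_labels[1]] * n2, index=cols)
    mu = np.concatenate([np.tile((base + shift)[:, None], (1, n1)),
                         np.tile(base[:, None], (1, n2))], axis=1)
    log2x = mu + rng.normal(0.0, sigma, size=mu.shape)
    mat = pd.DataFrame(2.0 ** log2x, index=universe, columns=cols)
    rec = pd.DataFrame({"planted": planted, "effect": shift},
                       index=pd.Index(universe, name="gene"))
    return mat, labels, ExpressionTruth(records=rec)


# ---------------------------------------------------------------------------
# qPCR and ELISA
# ---------------------------------------------------------------------------

def simulate_qpcr(means_by_group: Mapping[str, Mapping[str, float]], cv: float,
                  n_replicates: int, seed: int) -> pd.DataFrame:
    """Positive replicate table (gene, group, replicate, value).

    Replicates are log-normal around each gene/group mean with coefficient
    of variation ``cv`` (mean-preserving); cv = 0 reproduces the means
    exactly.
    """
    if cv < 0:
        raise ConfigError("cv must be >= 0")
    if n_replicates < 1:
        raise ConfigError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv ** 2)
    sigma = np.sqrt(sigma2)
    rows = []
    for gene, groups in means_by_group.items():
        for grp, mean in groups.items():
            if mean <= 0:
                raise ConfigError(f"non-positive mean for {gene}/{grp}")
            if cv == 0:
                vals = np.full(n_replicates, float(mean))
            else:
                vals = np.exp(rng.normal(np.log(mean) - sigma2 / 2.0, sigma,
                                         size=n_replicates))
            for i, v in enumerate(vals, start=1):
                rows.append({"gene": gene, "group": grp, "replicate": i,
                             "value": float(v)})
    return pd.DataFrame(rows)


def simulate_elisa_standards(params: tuple[float, float, float, float],
                             concentrations: Sequence[float], noise_sd: float = 0.0,
                             n_duplicates: int = 2, seed: int = 0) -> pd.DataFrame:
    """OD/concentration standard table from known 4-PL parameters."""
    lower, upper, slope, ec50 = params
    if not upper > lower or ec50 <= 0:
        raise ConfigError("invalid 4-PL parameters")
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        od0 = float(four_pl(c, lower, upper, slope, ec50))
        for _ in range(n_duplicates):
            od = od0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"concentration": float(c), "od": od})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixtures(output_dir, config: SimConfig,
                   gene_sets: GeneSetCollection | None = None) -> dict:
    """Emit a self-consistent fixture directory (TSV/GMT/JSON) and return paths.

    Contents: paired genus counts + metadata sidecar, an annotation registry
    derived from the truth, an expression matrix with one planted set, the
    gene-set collection, and both truth files.  Everything round-trips
    through the package readers.
    """
    from .io import write_abundance, write_registry  # local import avoids a cycle

    os.makedirs(output_dir, exist_ok=True)
    table, truth = simulate_microbiome(config)

    paths = {
        "counts": os.path.join(output_dir, "genus_counts.tsv"),
        "metadata": os.path.join(output_dir, "sample_metadata.tsv"),
        "registry": os.path.join(output_dir, "genus_registry.tsv"),
        "microbiome_truth": os.path.join(output_dir, "microbiome_truth.json"),
        "gene_sets": os.path.join(output_dir, "gene_sets.gmt"),
        "expression": os.path.join(output_dir, "expression.tsv"),
        "expression_groups": os.path.join(output_dir, "expression_groups.tsv"),
        "expression_truth": os.path.join(output_dir, "expression_truth.json"),
    }
    write_abundance(table, paths["counts"], paths["metadata"])
    registry = pd.DataFrame({
        "genus": truth.records.index,
        "label": truth.records["label"].to_numpy(),
        "citation": "synthetic truth",
    })
    write_registry(registry, paths["registry"])
    truth.to_json(paths["microbiome_truth"])

    if gene_sets is None:
        universe = gene_universe(400)
        gene_sets = GeneSetCollection()
        gene_sets.add(GeneSet("Heal.E", "early healing (planted)",
                              frozenset(universe[:30])))
        gene_sets.add(GeneSet("Mec.E", "early mechanotransduction",
                              frozenset(universe[30:60])))
        gene_sets.add(GeneSet("EMT.T2", "wound-healing EMT",
                              frozenset(universe[60:100])))
        gene_sets.add(GeneSet("InflGO", "inflammation",
                              frozenset(universe[100:140])))
    write_gene_sets(gene_sets, paths["gene_sets"])

    first = next(iter(gene_sets.values()))
    expr, labels, etruth = simulate_expression(
        n_genes=400, group_sizes=(8, 8),
        planted_sets={first.name: sorted(first.genes)},
        effect=2.0, seed=config.seed + 1)
    out = expr.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(paths["expression"], sep="\t", index=False, float_format="%.10g")
    labels.rename("group").rename_axis("sample").reset_index().to_csv(
        paths["expression_groups"], sep="\t", index=False)
    etruth.to_json(paths["expression_truth"])
    return paths
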