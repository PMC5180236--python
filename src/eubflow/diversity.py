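"""Shannon alpha diversity with arm-wise averaging.

H = -sum p_i ln p_i in natural-log units (nats).  Per-arm means carry a
standard error and a signed delta against the untreated baseline state
(by default the pooled before-therapy samples).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .normdiff import AbundanceTable


def shannon_index(counts) -> float:
    """Shannon entropy of one sample's feature counts, in nats."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise DataError("negative counts in diversity computation")
    if arr.sum() <= 0:
        raise DataError("all-zero sample has undefined diversity")
    # scipy normalizes to proportions and drops zero entries
    return float(stats.entropy(arr))


@dataclasses.dataclass
class DiversityReport:
    per_sample: pd.Series           # sample -> H
    per_arm: pd.DataFrame           # arm, n, mean, sem, delta_vs_reference
    reference_mean: float
    mode: str

    def to_tsv(self, sample_path, arm_path) -> None:
        s = self.per_sample.rename("shannon_h").rename_axis("sample").reset_index()
        s.to_csv(sample_path, sep="\t", index=False, float_format="%.10g")
        self.per_arm.to_csv(arm_path, sep="\t", index=False, float_format="%.10g")


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def arm_diversity(table: AbundanceTable, timepoint: str = "A",
                  reference_timepoint: str = "B", mode: str = "after",
                  arms=None) -> DiversityReport:
    """Per-arm Shannon diversity report.

    mode "after": mean H of each arm's samples at `timepoint`, delta against
    the mean H of the pooled samples at `reference_timepoint` (the untreated
    baseline state).  mode "delta": mean of per-subject paired differences
    H(timepoint) - H(reference_timepoint); the reference mean is then 0.
    """
    if mode not in ("after", "delta"):
        raise ConfigError(f"unknown diversity mode {mode!r}")
    meta = table.metadata
    if arms is not None:
        unknown = set(arms) - set(meta["arm"])
        if unknown:
            raise DataError(f"unknown arm labels: {sorted(unknown)}")
    h = pd.Series({s: shannon_index(table.counts[s].to_numpy()) for s in table.samples},
                  name="shannon_h")

    arm_list = arms if arms is not None else list(dict.fromkeys(meta["arm"]))
    rows = []
    if mode == "after":
        ref_samples = meta.index[meta["timepoint"] == reference_timepoint]
        if len(ref_samples) == 0:
            raise DataError(f"no samples at reference timepoint {reference_timepoint!r}")
        ref_mean = float(h.loc[ref_samples].mean())
        for arm in arm_list:
            sel = meta.index[(meta["arm"] == arm) & (meta["timepoint"] == timepoint)]
            if len(sel) == 0:
                raise DataError(f"arm {arm!r} has no samples at timepoint {timepoint!r}")
            vals = h.loc[sel].to_numpy()
            rows.append({"arm": arm, "n": len(vals), "mean": float(vals.mean()),
                         "sem": _sem(vals), "delta_vs_reference": float(vals.mean()) - ref_mean})
    else:
        ref_mean = 0.0
        for arm in arm_list:
            sub = meta[meta["arm"] == arm]
            after = sub[sub["timepoint"] == timepoint].set_index("subject")
            before = sub[sub["timepoint"] == reference_timepoint].set_index("subject")
            shared = after.index.intersection(before.index)
            if len(shared) == 0:
                raise DataError(f"arm {arm!r}: no subjects with both timepoints")
            deltas = np.array(
                [h[sub[(sub["subject"] == s) & (sub["timepoint"] == timepoint)].index[0]]
                 - h[sub[(sub["subject"] == s) & (sub["timepoint"] == reference_timepoint)].index[0]]
                 for s in shared])
            rows.append({"arm": arm, "n": len(deltas), "mean": float(deltas.mean()),
                         "sem": _sem(deltas), "delta_vs_reference": float(deltas.mean())})
    per_arm = pd.DataFrame(rows, columns=["arm", "n", "mean", "sem", "delta_vs_reference"])
    return DiversityReport(per_sample=h, per_arm=per_arm, reference_mean=ref_mean, mode=mode)
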