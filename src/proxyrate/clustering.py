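"""Immediate-early-gene classification from a differential-expression table.

IEG clusters are defined by serum-induction log2 fold-change thresholds:
a gene is a 2-/4-/8-/16-fold IEG if it is expressed and its log2FC is at
least 1.0/2.0/3.0/4.0 (inclusive boundaries). Membership is cumulative —
every 16-fold IEG is also a 2-, 4- and 8-fold IEG — so cluster sizes nest,
n(16) <= n(8) <= n(4) <= n(2). Non-DE genes are expressed genes less than
1.4-fold up- or down-regulated; remaining expressed genes (including
down-regulated ones) are "other".

The DE model producing log2FC is upstream and out of scope; this module
consumes its thresholded output. A count-based fallback (plain log2 ratio
of mean normalized counts with pseudocount 0.5) is provided as a
documented stand-in only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default inclusive log2FC cutoffs per IEG cluster
IEG_THRESHOLDS: dict[str, float] = {
    "2fold": 1.0,
    "4fold": 2.0,
    "8fold": 3.0,
    "16fold": 4.0,
}

#: fold-change band (either direction) defining non-differential genes
NONDE_FOLD: float = 1.4

#: half-open log2FC bands in which each label is the *top* label
CLUSTER_BANDS: dict[str, tuple[float, float]] = {
    "2fold": (1.0, 2.0),
    "4fold": (2.0, 3.0),
    "8fold": (3.0, 4.0),
    "16fold": (4.0, np.inf),
}

TOP_LABELS = ("16fold", "8fold", "4fold", "2fold", "nonDE", "other", "not_expressed")


@dataclass
class ClusterAssignment:
    """Gene-to-class mapping with cumulative IEG membership flags.

    ``table`` has one row per gene: top_label plus boolean columns
    is_2fold..is_16fold and is_nonde. ``counts`` reports the cumulative
    cluster sizes the way the field quotes them (overlapping n's).
    """

    table: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        out = {k: int(self.table[f"is_{k}"].sum()) for k in IEG_THRESHOLDS}
        out["nonDE"] = int(self.table["is_nonde"].sum())
        return out

    def genes_in(self, label: str) -> list[str]:
        if label in IEG_THRESHOLDS:
            mask = self.table[f"is_{label}"]
        elif label == "nonDE":
            mask = self.table["is_nonde"]
        else:
            mask = self.table["top_label"] == label
        return self.table.loc[mask, "gene_id"].tolist()

    def random_nonde(self, n: int, seed: int) -> list[str]:
        """A seeded random draw of n non-DE genes (comparison set)."""
        pool = self.genes_in("nonDE")
        if n > len(pool):
            raise ValueError(f"requested {n} non-DE genes, only {len(pool)} available")
        rng = np.random.default_rng(seed)
        return list(rng.choice(pool, size=n, replace=False))


def expression_filter(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 6
) -> pd.Series:
    """Expressed iff >= min_samples samples have >= min_count reads.

    Both comparisons are inclusive; defaults match bulk RNA-Seq filtering
    (10 counts in 6 samples; use 50/4 for TT-Seq).
    """
    if min_samples > counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {counts.shape[1]}"
        )
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return pd.Series(
        (arr >= min_count).sum(axis=1) >= min_samples,
        index=counts.index,
        name="expressed",
    )


def log2fc_from_counts(
    counts: pd.DataFrame,
    treatment_samples: list[str],
    reference_samples: list[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Stand-in log2FC: log2 ratio of mean normalized counts + pseudocount.

    This is not a differential-expression model; use a proper one when
    replicate variance matters.
    """
    t = counts[treatment_samples].mean(axis=1)
    r = counts[reference_samples].mean(axis=1)
    return np.log2((t + pseudocount) / (r + pseudocount)).rename("log2fc")


def assign_clusters(
    table: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    nonde_fold: float = NONDE_FOLD,
) -> ClusterAssignment:
    """Classify genes by log2FC thresholds.

    ``table`` needs columns gene_id, log2fc, expressed. IEG cluster k
    requires expressed and log2fc >= cutoff_k (inclusive); non-DE requires
    expressed and |log2fc| < log2(nonde_fold). Up-regulation only defines
    IEG clusters; down-regulated expressed genes fall to "other".
    """
    thresholds = thresholds or IEG_THRESHOLDS
    required = {"gene_id", "log2fc", "expressed"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    expressed = table["expressed"].astype(bool).to_numpy()
    lfc = table["log2fc"].to_numpy(dtype=float)
    if np.any(expressed & ~np.isfinite(lfc)):
        bad = table.loc[expressed & ~np.isfinite(lfc), "gene_id"].tolist()
        raise ValueError(f"expressed genes with missing log2fc: {bad[:5]}")

    out = pd.DataFrame({"gene_id": table["gene_id"].to_numpy()})
    for label, cutoff in thresholds.items():
        out[f"is_{label}"] = expressed & (lfc >= cutoff)
    band = np.log2(nonde_fold)
    out["is_nonde"] = expressed & (np.abs(lfc) < band)

    top = np.full(len(table), "other", dtype=object)
    top[~expressed] = "not_expressed"
    top[out["is_nonde"].to_numpy()] = "nonDE"
    for label, _ in sorted(thresholds.items(), key=lambda kv: kv[1]):
        top[out[f"is_{label}"].to_numpy()] = label
    out["top_label"] = top
    out["log2fc"] = lfc
    return ClusterAssignment(out)
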