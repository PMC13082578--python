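"""Promoter classification: major / minor (alternative) / inactive.

Per gene, the promoter with the highest mean activity across the selected
samples is the *major* promoter; other promoters at or above the activity
threshold are *minor/alternative*; promoters below it are *inactive*.  The
default threshold of 0.25 on log2 activity is the field's conventional
cutoff for detectable promoter expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import PromoterMap

GENE_CLASSES = (
    "single_promoter_single_active",
    "multi_promoter_single_active",
    "multi_promoter_multi_active",
    "no_active",
)


@dataclass
class PromoterClassification:
    """Per-promoter categories plus the gene-level summaries behind them.

    ``promoters`` columns: gene_id, rank_5to3, mean_activity, category
    (major/minor/inactive/not_quantifiable).  ``genes`` columns: n_promoters,
    n_active, gene_class, major_activity, total_activity.
    ``major_rank_histogram``: counts of the major promoter's 5'→3' rank over
    multipromoter genes with at least one active promoter.
    """

    promoters: pd.DataFrame
    genes: pd.DataFrame
    major_rank_histogram: pd.Series
    min_activity: float

    def category_of(self, promoter_id: int) -> str:
        return self.promoters.at[promoter_id, "category"]

    def ids_in_category(self, category: str) -> set[int]:
        sub = self.promoters[self.promoters["category"] == category]
        return set(sub.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.promoters.copy()
        out.insert(0, "promoter_id", out.index)
        out.to_csv(path, sep="\t", index=False)


def classify_promoters(
    activity: pd.DataFrame,
    pmap: PromoterMap,
    sample_ids: list[str] | None = None,
    min_activity: float = 0.25,
) -> PromoterClassification:
    """Label each quantifiable promoter major, minor or inactive.

    Parameters
    ----------
    activity
        log2 activity matrix (promoters x samples); NaN rows are promoters
        the quantification method cannot measure and are reported separately
        as ``not_quantifiable``.
    sample_ids
        Subset of samples to average over (default: all columns).
    min_activity
        Promoters with mean activity below this are inactive.  The gene's
        highest-mean active promoter is major; ties break toward the 5'-most
        (lowest rank).
    """
    if min_activity <= 0:
        raise ValueError("min_activity must be > 0")
    samples = list(activity.columns) if sample_ids is None else list(sample_ids)
    if not samples:
        raise ValueError("empty sample subset")
    mean_act = activity[samples].mean(axis=1)

    rows = []
    for p in pmap.promoters:
        if p.excluded or p.promoter_id not in mean_act.index:
            continue
        m = mean_act.get(p.promoter_id, np.nan)
        rows.append((p.promoter_id, p.gene_id, p.rank_5to3, m))
    df = pd.DataFrame(
        rows, columns=["promoter_id", "gene_id", "rank_5to3", "mean_activity"]
    ).set_index("promoter_id")

    df["category"] = "inactive"
    df.loc[df["mean_activity"].isna(), "category"] = "not_quantifiable"
    active = df["mean_activity"] >= min_activity
    df.loc[active, "category"] = "minor"
    for gene_id, sub in df[active].groupby("gene_id"):
        # tie on max activity resolved toward the 5'-most promoter
        best = sub.sort_values(
            ["mean_activity", "rank_5to3"], ascending=[False, True]
        ).index[0]
        df.at[best, "category"] = "major"

    genes = summarize_genes_table(df, min_activity)
    hist = _major_rank_histogram(df)
    return PromoterClassification(df, genes, hist, min_activity)


def summarize_genes_table(promoters: pd.DataFrame, min_activity: float) -> pd.DataFrame:
    """Gene-level summary over quantifiable promoters."""
    rows = []
    for gene_id, sub in promoters.groupby("gene_id"):
        q = sub[sub["category"] != "not_quantifiable"]
        n_prom = len(q)
        n_active = int((q["category"].isin(["major", "minor"])).sum())
        if n_active == 0:
            gclass = "no_active"
        elif n_prom == 1:
            gclass = "single_promoter_single_active"
        elif n_active == 1:
            gclass = "multi_promoter_single_active"
        else:
            gclass = "multi_promoter_multi_active"
        major = q[q["category"] == "major"]
        major_act = float(major["mean_activity"].iloc[0]) if len(major) else np.nan
        total_act = float(q["mean_activity"].sum()) if n_prom else np.nan
        rows.append((gene_id, n_prom, n_active, gclass, major_act, total_act))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_promoters", "n_active", "gene_class",
                 "major_activity", "total_activity"],
    ).set_index("gene_id")


def _major_rank_histogram(promoters: pd.DataFrame) -> pd.Series:
    counts: dict[int, int] = {}
    for gene_id, sub in promoters.groupby("gene_id"):
        q = sub[sub["category"] != "not_quantifiable"]
        if len(q) < 2:  # multipromoter genes only
            continue
        major = q[q["category"] == "major"]
        if len(major) == 0:  # needs >= 1 active promoter
            continue
        rank = int(major["rank_5to3"].iloc[0])
        counts[rank] = counts.get(rank, 0) + 1
    if not counts:
        return pd.Series(dtype=int)
    max_rank = max(counts)
    return pd.Series({r: counts.get(r, 0) for r in range(1, max_rank + 1)}, dtype=int)


def summarize_genes(
    classification: PromoterClassification, pmap: PromoterMap
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Gene-class counts, major-rank histogram and (major, total) activity pairs."""
    gene_class_counts = (
        classification.genes["gene_class"]
        .value_counts()
        .reindex(GENE_CLASSES, fill_value=0)
    )
    pairs = classification.genes[["major_activity", "total_activity"]]
    return gene_class_counts, classification.major_rank_histogram, pairs
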