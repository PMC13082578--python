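"""Concordance benchmarking of a quantification method against a reference.

The metric suite compares paired promoter-level values (typically an RNA-seq
method against CAGE): Pearson and Spearman correlations for linear and rank
concordance, Lin's concordance correlation coefficient (CCC) for agreement on
the absolute scale, the mean bias, and the Bland–Altman bias and trend
(mean of paired differences, and the slope of differences on pair means).
Classification agreement is summarised as precision and recall of the
major/minor promoter sets.  Bootstrap resampling at the promoter level gives
percentile confidence intervals, and equal-frequency expression strata show
how concordance varies with signal level.

Bias orientation is fixed as method minus reference throughout: a negative
bias means the method underestimates the reference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classify import PromoterClassification

logger = logging.getLogger(__name__)

METRICS = ("pearson", "spearman", "ccc", "mean_bias", "ba_bias", "ba_trend")


@dataclass
class ClassificationAgreement:
    category: str
    n_method: int
    n_reference: int
    n_overlap: int

    @property
    def precision(self) -> float:
        return self.n_overlap / self.n_method if self.n_method else np.nan

    @property
    def recall(self) -> float:
        return self.n_overlap / self.n_reference if self.n_reference else np.nan


@dataclass
class ConcordanceReport:
    n: int
    pearson: float
    spearman: float
    ccc: float
    mean_bias: float
    ba_bias: float
    ba_trend: float
    bootstrap: dict[str, tuple[float, float]] | None = None
    bootstrap_B: int | None = None
    bootstrap_seed: int | None = None
    n_degenerate_resamples: int = 0
    strata: list["ConcordanceReport"] | None = None
    stratum_bounds: tuple[float, float] | None = None

    def metric(self, name: str) -> float:
        return getattr(self, name)

    def to_dict(self) -> dict:
        d = {
            "bias_orientation": "method_minus_reference",
            "n": self.n,
            **{m: _jsonable(self.metric(m)) for m in METRICS},
        }
        if self.bootstrap is not None:
            d["bootstrap"] = {
                k: [_jsonable(v[0]), _jsonable(v[1])] for k, v in self.bootstrap.items()
            }
            d["bootstrap_B"] = self.bootstrap_B
            d["bootstrap_seed"] = self.bootstrap_seed
            d["n_degenerate_resamples"] = self.n_degenerate_resamples
        if self.strata is not None:
            d["strata"] = [s.to_dict() for s in self.strata]
        if self.stratum_bounds is not None:
            d["stratum_bounds"] = [_jsonable(b) for b in self.stratum_bounds]
        return d


def _jsonable(x) -> float | None:
    x = float(x)
    return None if not np.isfinite(x) else x


def classification_agreement(
    method_class: PromoterClassification,
    ref_class: PromoterClassification,
    category: str,
) -> ClassificationAgreement:
    """Precision/recall of the method's promoter set for one category.

    Precision is the fraction of the method's promoters in the category that
    the reference also assigns to it; recall is the fraction of the
    reference's promoters the method recovers.
    """
    u_method = set(method_class.promoters.index)
    u_ref = set(ref_class.promoters.index)
    if u_method != u_ref:
        diff = len(u_method.symmetric_difference(u_ref))
        raise ValueError(
            f"promoter universes differ by {diff} ids; classifications must "
            "cover the same promoters"
        )
    a = method_class.ids_in_category(category)
    b = ref_class.ids_in_category(category)
    return ClassificationAgreement(
        category=category,
        n_method=len(a),
        n_reference=len(b),
        n_overlap=len(a & b),
    )


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _concordance_core(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    n = len(x)
    out = {m: np.nan for m in METRICS}
    if n < 3 or np.var(x) == 0 or np.var(y) == 0:
        logger.warning("concordance: n < 3 or zero variance; metrics missing")
        diffs = x - y
        out["mean_bias"] = out["ba_bias"] = float(np.mean(diffs)) if n else np.nan
        return out
    if np.array_equal(x, y):
        # exact identity: return exact values rather than float round-off
        out.update(pearson=1.0, spearman=1.0, ccc=1.0,
                   mean_bias=0.0, ba_bias=0.0, ba_trend=0.0)
        return out
    out["pearson"] = float(stats.pearsonr(x, y).statistic)
    out["spearman"] = float(stats.spearmanr(x, y).statistic)
    # Lin's CCC with population (1/n) moments
    mx, my = np.mean(x), np.mean(y)
    vx, vy = np.var(x), np.var(y)
    cov = np.mean((x - mx) * (y - my))
    out["ccc"] = float(2 * cov / (vx + vy + (mx - my) ** 2))
    diffs = x - y
    means = (x + y) / 2.0
    out["mean_bias"] = out["ba_bias"] = float(np.mean(diffs))
    if np.var(means) > 0:
        slope = np.cov(means, diffs, ddof=0)[0, 1] / np.var(means)
        out["ba_trend"] = float(slope)
    return out


def concordance(
    x,
    y,
    log10_transform: bool = False,
    pseudocount: float = 1.0,
) -> ConcordanceReport:
    """Full concordance metric suite for paired vectors (x = method, y = reference).

    Pairs with a missing value on either side are dropped.  With
    ``log10_transform`` both vectors become ``log10(value + pseudocount)``
    first.  Degenerate inputs (n < 3 or zero variance) yield missing metric
    values with a warning, never an exception.
    """
    xv, yv = _paired(x, y)
    if log10_transform:
        xv = np.log10(xv + pseudocount)
        yv = np.log10(yv + pseudocount)
    core = _concordance_core(xv, yv)
    return ConcordanceReport(n=len(xv), **core)


def bootstrap_concordance(
    x,
    y,
    B: int = 1000,
    seed: int = 0,
    log10_transform: bool = False,
    pseudocount: float = 1.0,
) -> ConcordanceReport:
    """Promoter-level bootstrap percentile CIs (2.5/97.5) for every metric.

    Pairs are resampled with replacement ``B`` times with a seeded generator;
    resamples with zero variance are skipped and counted.  More than 50%
    degenerate resamples is an error.
    """
    xv, yv = _paired(x, y)
    if log10_transform:
        xv = np.log10(xv + pseudocount)
        yv = np.log10(yv + pseudocount)
    report = ConcordanceReport(n=len(xv), **_concordance_core(xv, yv))
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {m: [] for m in METRICS}
    n_degenerate = 0
    for _ in range(B):
        idx = rng.integers(0, len(xv), size=len(xv))
        bx, by = xv[idx], yv[idx]
        if np.var(bx) == 0 or np.var(by) == 0:
            n_degenerate += 1
            continue
        core = _concordance_core(bx, by)
        for m in METRICS:
            samples[m].append(core[m])
    if n_degenerate > B / 2:
        raise ValueError(
            f"{n_degenerate}/{B} bootstrap resamples degenerate; data too sparse"
        )
    cis = {}
    for m in METRICS:
        vals = np.asarray(samples[m], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals):
            cis[m] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
        else:
            cis[m] = (np.nan, np.nan)
    report.bootstrap = cis
    report.bootstrap_B = B
    report.bootstrap_seed = seed
    report.n_degenerate_resamples = n_degenerate
    return report


def stratified_concordance(
    x,
    y,
    reference_for_strata,
    n_strata: int = 6,
    log10_transform: bool = False,
    pseudocount: float = 1.0,
) -> ConcordanceReport:
    """Concordance inside equal-frequency strata of reference expression.

    Only promoters with a positive stratification value participate; they are
    split into ``n_strata`` quantile bins (ties go to the lower bin) and the
    metric suite is recomputed per bin.  Bins with fewer than 3 pairs report
    missing metrics with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ref = np.asarray(reference_for_strata, dtype=float)
    if not (len(x) == len(y) == len(ref)):
        raise ValueError("x, y and strata vectors must be paired")
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(ref) & (ref > 0)
    xv, yv, rv = x[ok], y[ok], ref[ok]
    overall = concordance(xv, yv, log10_transform, pseudocount)
    if len(rv) == 0:
        overall.strata = []
        return overall
    inner = np.quantile(rv, [i / n_strata for i in range(1, n_strata)])
    bin_idx = np.searchsorted(inner, rv, side="left")  # tie at an edge -> lower bin
    edges = np.concatenate(([rv.min()], inner, [rv.max()]))
    strata = []
    for b in range(n_strata):
        sel = bin_idx == b
        rep = concordance(xv[sel], yv[sel], log10_transform, pseudocount)
        rep.stratum_bounds = (float(edges[b]), float(edges[b + 1]))
        strata.append(rep)
    overall.strata = strata
    return overall


def report_to_json(report: ConcordanceReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def report_to_tsv(
    report: ConcordanceReport,
    path: str | Path,
    agreements: list[ClassificationAgreement] | None = None,
) -> None:
    rows = [("overall", report.n, *(report.metric(m) for m in METRICS))]
    if report.strata:
        for i, s in enumerate(report.strata, start=1):
            rows.append((f"Q{i}", s.n, *(s.metric(m) for m in METRICS)))
    df = pd.DataFrame(rows, columns=["stratum", "n", *METRICS])
    with open(path, "w") as fh:
        fh.write("# bias orientation: method - reference\n")
        df.to_csv(fh, sep="\t", index=False)
        if agreements:
            fh.write("\n")
            pd.DataFrame(
                [
                    (a.category, a.n_method, a.n_reference, a.n_overlap,
                     a.precision, a.recall)
                    for a in agreements
                ],
                columns=["category", "n_method", "n_reference", "n_overlap",
                         "precision", "recall"],
            ).to_csv(fh, sep="\t", index=False)
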