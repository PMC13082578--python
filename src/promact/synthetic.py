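"""Synthetic annotation and signal generator with known ground truth.

Emits format-faithful toy datasets — a GTF, per-sample splice-junction
tables, transcript quantification tables, aligned-read BEDs and CAGE tag
tables, plus a sample sheet and a truth table — so the whole pipeline is
testable without external downloads.

The generative model mirrors the assumptions of the analysis:

* Genes are laid out with non-overlapping bodies on 1–3 toy chromosomes;
  each gene has 1–3 promoters with disjoint first exons, every multi-exon
  transcript of a gene splices into one shared downstream exon, and a
  configurable fraction of promoters is intronless (single-exon), matching
  the sizeable intronless share of real annotations.
* Expected promoter counts are ``depth x gene weight x promoter usage``;
  observed counts are negative-binomially distributed around them, shared
  consistently across the junction, transcript and read channels.
* Differential promoters scale their expectation by ``2^de_log2fc`` in the
  test condition; switch genes move ``delta_usage`` of usage from the major
  to a minor promoter with the gene total unchanged (a pure compositional
  shift).
* CAGE means equal the RNA means times promoter-level multiplicative
  lognormal noise, giving the benchmark a tunable true concordance; tags are
  scattered a few bases around the TSS inside the promoter window.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .differential import SampleDesign
from .quantify import JunctionRecord, ReadInterval, TranscriptQuant

TRUTH_COLUMNS = [
    "gene_id", "promoter_label", "chrom", "strand", "tss", "rank_5to3",
    "intronless", "injected_internal", "injected_overlapping",
    "usage_ref", "usage_test", "lambda_ref", "lambda_test",
    "is_de", "is_switch", "category_ref", "category_test",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    ``mean_depth`` is the expected number of assigned reads per sample; the
    default of 2e6 is a desk-scale stand-in for a typical ~20M-read bulk
    library, preserving per-promoter counts in the hundreds for moderately
    expressed genes.  ``dispersion`` is the NB alpha typical of biological
    replicates.  ``de_log2fc = 2`` and ``delta_usage = 0.4`` are
    well-separated effects for recovery checks.
    """

    n_genes: int = 500
    promoters_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    intronless_promoter_fraction: float = 0.2
    exon_length: tuple[int, int] = (200, 500)
    intron_length: tuple[int, int] = (500, 2000)
    samples_per_condition: int = 3
    mean_depth: float = 2e6
    dispersion: float = 0.05
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    switch_fraction: float = 0.2
    delta_usage: float = 0.4
    cage_noise: float = 0.3
    internal_fraction: float = 0.0
    overlapping_fraction: float = 0.0
    n_chroms: int = 2
    read_length: int = 80
    cage_jitter: int = 20
    min_activity: float = 0.25
    conditions: tuple[str, str] = ("ref", "test")
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.promoters_per_gene.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("promoters_per_gene probabilities must sum to 1")
        for name in ("intronless_promoter_fraction", "de_fraction",
                     "switch_fraction", "internal_fraction", "overlapping_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.delta_usage < 1.0:
            raise ValueError("delta_usage must be in (0, 1)")


@dataclass
class GroundTruth:
    """Per-promoter truth (usages, expected counts, categories, event sets)."""

    table: pd.DataFrame  # TRUTH_COLUMNS
    config: SimulationConfig

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def attach_promoter_ids(self, pmap) -> pd.DataFrame:
        """Join truth rows to map promoter ids by (gene, tss)."""
        key = {(p.gene_id, p.tss): p.promoter_id for p in pmap.promoters}
        t = self.table.copy()
        t["promoter_id"] = [
            key.get((g, tss)) for g, tss in zip(t["gene_id"], t["tss"])
        ]
        return t


# usage patterns per promoter count: well separated, major first (rank order
# is permuted per gene below)
_USAGE_PATTERNS = {1: [1.0], 2: [0.7, 0.3], 3: [0.6, 0.3, 0.1]}


def _reflect(span: tuple[int, int], iv: tuple[int, int]) -> tuple[int, int]:
    s0, e0 = span
    a, b = iv
    return (s0 + e0 - b, s0 + e0 - a)


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Lay out genes and promoters; return transcript models and the truth skeleton.

    Expected counts, event memberships and categories are filled in here as
    well, so the returned truth is complete; signal synthesis only adds noise.
    """
    rng = np.random.default_rng(config.seed)
    ks = sorted(config.promoters_per_gene)
    kprobs = [config.promoters_per_gene[k] for k in ks]

    transcripts: list[TranscriptModel] = []
    rows: list[dict] = []
    gap_between_genes = 5000
    cursor = {f"chrS{i + 1}": 1000 for i in range(config.n_chroms)}
    chrom_names = list(cursor)

    gene_weights = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    gene_weights = gene_weights / gene_weights.sum()

    host_candidates: list[dict] = []  # geometry kept for internal/overlap injection

    for gi in range(config.n_genes):
        gene_id = f"G{gi + 1:04d}"
        chrom = chrom_names[gi % len(chrom_names)]
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.choice(ks, p=kprobs))
        intronless = rng.random(k) < config.intronless_promoter_fraction

        # forward-frame construction, mirrored afterwards for "-" genes
        start = cursor[chrom]
        pos = start
        fe: list[tuple[int, int]] = []
        for _ in range(k):
            L = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            fe.append((pos, pos + L - 1))
            pos = pos + L + int(rng.integers(100, 300))
        max_fe_end = fe[-1][1]
        common_start = max_fe_end + int(
            rng.integers(config.intron_length[0], config.intron_length[1] + 1)
        )
        Lc = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
        common = (common_start, common_start + Lc - 1)
        span = (start, common[1])
        cursor[chrom] = common[1] + gap_between_genes

        # usage pattern: the major is the 5'-most promoter in ~60% of genes,
        # otherwise a random permutation across ranks
        pattern = np.array(_USAGE_PATTERNS[k])
        if k > 1 and rng.random() >= 0.6:
            pattern = pattern[rng.permutation(k)]

        host_geometry = []
        for j in range(k):
            n_tx = 1 if intronless[j] else (1 + int(rng.random() < 0.5))
            fe_s, fe_e = fe[j]
            exon_sets: list[list[tuple[int, int]]] = []
            if intronless[j]:
                exon_sets.append([(fe_s, fe_e)])
            else:
                exon_sets.append([(fe_s, fe_e), common])
                if n_tx == 2:
                    # overlapping alternative first exon: same start, shorter end
                    alt_e = fe_s + max(50, (fe_e - fe_s) // 2)
                    exon_sets.append([(fe_s, alt_e), common])
            for ti, exons in enumerate(exon_sets, start=1):
                if strand == "-":
                    exons = [_reflect(span, iv) for iv in exons]
                    exons = sorted(exons, key=lambda iv: iv[0], reverse=True)
                transcripts.append(
                    TranscriptModel(
                        transcript_id=f"{gene_id}.P{j + 1}.T{ti}",
                        gene_id=gene_id,
                        gene_biotype="protein_coding",
                        chrom=chrom,
                        strand=strand,
                        exons=list(exons),
                    )
                )
            if strand == "+":
                tss = fe_s
            else:
                tss = _reflect(span, (fe_s, fe_e))[1]
            rows.append(
                {
                    "gene_id": gene_id,
                    "promoter_label": f"P{j + 1}",
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "rank_5to3": j + 1,
                    "intronless": bool(intronless[j]),
                    "injected_internal": False,
                    "injected_overlapping": False,
                    "usage_ref": float(pattern[j]),
                    "usage_test": float(pattern[j]),
                    "lambda_ref": 0.0,
                    "lambda_test": 0.0,
                    "is_de": False,
                    "is_switch": False,
                    "category_ref": "",
                    "category_test": "",
                    "_gene_weight": float(gene_weights[gi]),
                }
            )
            host_geometry.append((fe[j], intronless[j]))
        host_candidates.append(
            {"gene_id": gene_id, "chrom": chrom, "strand": strand, "span": span,
             "common": common, "first_exons": fe, "k": k,
             "has_multi_exon": bool((~intronless).any())}
        )

    truth = pd.DataFrame(rows)

    _inject_flag_exercisers(truth, transcripts, host_candidates, config, rng)
    _assign_events(truth, config, rng)
    _fill_expectations(truth, config)
    return transcripts, GroundTruth(table=truth[TRUTH_COLUMNS].copy(), config=config)


def _inject_flag_exercisers(truth, transcripts, hosts, config, rng) -> None:
    """Add extra genes that trigger the internal / overlapping flags."""
    extra_rows = []
    n_internal = int(round(config.internal_fraction * len(hosts)))
    n_overlap = int(round(config.overlapping_fraction * len(hosts)))
    # the internal-flag construction needs a downstream exon to land in
    multi_exon_hosts = [h for h in hosts if h["has_multi_exon"]]
    idx = rng.permutation(len(multi_exon_hosts))
    taken = 0
    gid_counter = len(hosts)
    for i in idx:
        if taken >= n_internal:
            break
        h = multi_exon_hosts[i]
        # TSS inside the host's shared downstream exon (a non-first exon of
        # the host's multi-exon transcripts)
        cs, ce = h["common"] if h["strand"] == "+" else _reflect(h["span"], h["common"])
        if ce - cs < 60:
            continue
        gid_counter += 1
        gene_id = f"G{gid_counter:04d}I"
        tss = cs + 30
        exon = (tss, ce + 200)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.P1.T1", gene_id=gene_id,
                gene_biotype="protein_coding", chrom=h["chrom"], strand="+",
                exons=[exon],
            )
        )
        extra_rows.append(_injected_row(gene_id, h["chrom"], "+", tss, internal=True))
        taken += 1
    taken = 0
    for i in idx[::-1]:
        if taken >= n_overlap:
            break
        h = multi_exon_hosts[i]
        fe_s, fe_e = h["first_exons"][0]
        if h["strand"] == "-":
            fe_s, fe_e = _reflect(h["span"], (fe_s, fe_e))
        shift = (fe_e - fe_s) // 2
        exon = (fe_s + shift, fe_e + shift)
        gid_counter += 1
        gene_id = f"G{gid_counter:04d}O"
        tss = exon[0] if h["strand"] == "+" else exon[1]
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.P1.T1", gene_id=gene_id,
                gene_biotype="protein_coding", chrom=h["chrom"],
                strand=h["strand"], exons=[exon],
            )
        )
        extra_rows.append(
            _injected_row(gene_id, h["chrom"], h["strand"], tss, internal=False)
        )
        taken += 1
    for r in extra_rows:
        truth.loc[len(truth)] = r


def _injected_row(gene_id, chrom, strand, tss, internal: bool) -> dict:
    return {
        "gene_id": gene_id, "promoter_label": "P1", "chrom": chrom,
        "strand": strand, "tss": tss, "rank_5to3": 1, "intronless": True,
        "injected_internal": internal, "injected_overlapping": not internal,
        "usage_ref": 1.0, "usage_test": 1.0, "lambda_ref": 0.0,
        "lambda_test": 0.0, "is_de": False, "is_switch": False,
        "category_ref": "", "category_test": "", "_gene_weight": 0.0,
    }


def _assign_events(truth: pd.DataFrame, config: SimulationConfig, rng) -> None:
    regular = truth[~truth["injected_internal"] & ~truth["injected_overlapping"]]

    # reciprocal usage switches first, on multipromoter genes
    multi_genes = [g for g, sub in regular.groupby("gene_id") if len(sub) >= 2]
    n_switch = int(round(config.switch_fraction * len(multi_genes)))
    switch_genes = list(
        rng.choice(np.array(multi_genes, dtype=object), size=n_switch, replace=False)
    )
    for g in switch_genes:
        sub = truth[truth["gene_id"] == g]
        major = sub["usage_ref"].idxmax()
        minors = sub.index[sub.index != major]
        target = minors[int(rng.integers(len(minors)))]
        delta = min(config.delta_usage, float(truth.at[major, "usage_ref"]) - 0.05)
        if delta <= 0:
            continue
        truth.loc[[major, target], "is_switch"] = True
        truth.at[major, "usage_test"] = truth.at[major, "usage_ref"] - delta
        truth.at[target, "usage_test"] = truth.at[target, "usage_ref"] + delta

    # activity-level DE kept off switch genes so the two event types stay
    # separable in recovery checks
    eligible = regular.index[~regular["gene_id"].isin(switch_genes)]
    n_de = min(int(round(config.de_fraction * len(regular))), len(eligible))
    de_idx = rng.choice(eligible.to_numpy(), size=n_de, replace=False)
    truth.loc[de_idx, "is_de"] = True


def _fill_expectations(truth: pd.DataFrame, config: SimulationConfig) -> None:
    depth = config.mean_depth
    lam_ref = depth * truth["_gene_weight"] * truth["usage_ref"]
    lam_test = depth * truth["_gene_weight"] * truth["usage_test"]
    lam_test = lam_test * np.where(truth["is_de"], 2.0 ** config.de_log2fc, 1.0)
    truth["lambda_ref"] = lam_ref
    truth["lambda_test"] = lam_test
    # usage columns hold realised within-gene proportions (DE scaling changes
    # the test-condition composition of its gene)
    for col, lam_col in (("usage_ref", "lambda_ref"), ("usage_test", "lambda_test")):
        totals = truth.groupby("gene_id")[lam_col].transform("sum")
        with np.errstate(invalid="ignore", divide="ignore"):
            truth[col] = np.where(totals > 0, truth[lam_col] / totals, truth[col])
    for cond, lam_col in (("ref", "lambda_ref"), ("test", "lambda_test")):
        act = np.log2(truth[lam_col] + 1.0)
        cat = np.where(act >= config.min_activity, "minor", "inactive")
        truth[f"category_{cond}"] = cat
        for g, sub in truth.groupby("gene_id"):
            active = sub[np.log2(sub[lam_col] + 1.0) >= config.min_activity]
            if len(active):
                best = active.sort_values(
                    [lam_col, "rank_5to3"], ascending=[False, True]
                ).index[0]
                truth.at[best, f"category_{cond}"] = "major"


# ------------------------------------------------------------------ signals


@dataclass
class SimulatedSignals:
    """Per-sample simulated inputs, keyed by sample id."""

    sj_tables: dict[str, list[JunctionRecord]]
    quant_tables: dict[str, list[TranscriptQuant]]
    read_tables: dict[str, list[ReadInterval]]
    cage_tables: dict[str, pd.DataFrame]  # chrom, pos, strand, count
    design: SampleDesign


def _nb_draw(rng, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, alpha) via the gamma–Poisson mixture; Poisson when alpha ~ 0."""
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    if alpha <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def simulate_signals(
    transcripts: list[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    channels: set[str] = frozenset({"sj", "quant", "reads", "cage"}),
) -> SimulatedSignals:
    """Draw per-sample counts and materialise every input modality.

    Noise is hierarchical: the gene-level count is negative-binomial around
    the gene's expected total (biological replicate variability acts on the
    gene), and promoter counts split that total multinomially by the true
    within-gene usage, so usage estimates converge with depth while
    promoter-level counts stay overdispersed marginally.  One count per
    (promoter, sample) feeds the junction, transcript and read channels
    consistently; CAGE gets an independent per-promoter NB draw around a
    lognormal-perturbed mean.  Deterministic under ``config.seed``.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)  # independent of the layout stream
    t = truth.table
    ref_name, test_name = config.conditions
    samples = {
        f"{ref_name}{i + 1}": ref_name for i in range(config.samples_per_condition)
    } | {
        f"{test_name}{i + 1}": test_name for i in range(config.samples_per_condition)
    }
    design = SampleDesign(
        samples={s: (c, None) for s, c in samples.items()},
        contrast=(ref_name, test_name),
    )

    by_tid = {tr.transcript_id: tr for tr in transcripts}
    members: list[list[TranscriptModel]] = []
    for _, row in t.iterrows():
        prefix = f"{row.gene_id}.{row.promoter_label}."
        members.append(
            [tr for tid, tr in by_tid.items() if tid.startswith(prefix)]
        )

    # promoter-level CAGE platform factor, fixed across samples
    cage_factor = np.exp(rng.normal(0.0, config.cage_noise, size=len(t)))

    sj_tables: dict[str, list[JunctionRecord]] = {}
    quant_tables: dict[str, list[TranscriptQuant]] = {}
    read_tables: dict[str, list[ReadInterval]] = {}
    cage_tables: dict[str, pd.DataFrame] = {}

    jitter_offsets = np.arange(-config.cage_jitter, config.cage_jitter + 1)
    jitter_probs = np.full(len(jitter_offsets), 1.0 / len(jitter_offsets))

    gene_indices = [idx.to_numpy() for _, idx in
                    t.groupby("gene_id", sort=False).groups.items()]

    for sample, cond in samples.items():
        lam = (t["lambda_ref"] if cond == ref_name else t["lambda_test"]).to_numpy()
        counts = np.zeros(len(t), dtype=np.int64)
        for idx in gene_indices:
            lam_gene = float(lam[idx].sum())
            if lam_gene <= 0:
                continue
            n_gene = int(_nb_draw(rng, np.array([lam_gene]), config.dispersion)[0])
            counts[idx] = rng.multinomial(n_gene, lam[idx] / lam_gene)

        if "sj" in channels:
            sj_tables[sample] = _make_sj(t, members, counts, rng)
        if "quant" in channels:
            quant_tables[sample] = _make_quant(by_tid, t, members, counts, rng)
        if "reads" in channels:
            read_tables[sample] = _make_reads(t, members, counts, config, rng, sample)
        if "cage" in channels:
            cage_counts = _nb_draw(rng, lam * cage_factor, config.dispersion)
            cage_tables[sample] = _make_cage(
                t, cage_counts, jitter_offsets, jitter_probs, rng
            )

    return SimulatedSignals(sj_tables, quant_tables, read_tables, cage_tables, design)


def _make_sj(t, members, counts, rng) -> list[JunctionRecord]:
    agg: dict[tuple[str, int, int, int], int] = {}
    for (_, row), mem, n in zip(t.iterrows(), members, counts):
        if n == 0:
            continue
        introns = sorted({m.first_intron for m in mem if m.first_intron is not None})
        if not introns:
            continue
        split = rng.multinomial(n, np.full(len(introns), 1.0 / len(introns)))
        code = 1 if row.strand == "+" else 2
        for (s, e), c in zip(introns, split):
            if c:
                key = (row.chrom, s, e, code)
                agg[key] = agg.get(key, 0) + int(c)
    return [
        JunctionRecord(chrom=k[0], intron_first=k[1], intron_last=k[2],
                       strand_code=k[3], unique_reads=v, multi_reads=0)
        for k, v in sorted(agg.items())
    ]


def _make_quant(by_tid, t, members, counts, rng) -> list[TranscriptQuant]:
    reads = {tid: 0.0 for tid in by_tid}
    for mem, n in zip(members, counts):
        if n == 0 or not mem:
            continue
        split = rng.multinomial(n, np.full(len(mem), 1.0 / len(mem)))
        for m, c in zip(mem, split):
            reads[m.transcript_id] += float(c)
    dens_total = sum(
        reads[tid] / by_tid[tid].length for tid in by_tid if reads[tid] > 0
    )
    out = []
    for tid in sorted(by_tid):
        tr = by_tid[tid]
        eff = max(tr.length - 100.0, 1.0)
        dens = reads[tid] / tr.length
        tpm = dens / dens_total * 1e6 if dens_total > 0 else 0.0
        out.append(TranscriptQuant(tid, tr.length, eff, tpm, reads[tid]))
    return out


def _make_reads(t, members, counts, config, rng, sample) -> list[ReadInterval]:
    reads: list[ReadInterval] = []
    rl = config.read_length
    i = 0
    for (_, row), mem, n in zip(t.iterrows(), members, counts):
        if n == 0 or not mem:
            continue
        # sample read starts uniformly within the union of member first exons
        ivs = sorted({m.first_exon for m in mem})
        widths = np.array([e - s + 1 for s, e in ivs], dtype=float)
        pick = rng.choice(len(ivs), size=n, p=widths / widths.sum())
        for j in pick:
            s, e = ivs[j]
            if e - s + 1 <= rl:
                rs, re = s, e
            else:
                rs = int(rng.integers(s, e - rl + 2))
                re = rs + rl - 1
            reads.append(
                ReadInterval(chrom=row.chrom, start=rs, end=re,
                             strand=row.strand, read_id=f"{sample}_r{i}")
            )
            i += 1
    return reads


def _make_cage(t, counts, offsets, probs, rng) -> pd.DataFrame:
    rows = []
    for (_, row), n in zip(t.iterrows(), counts):
        if n == 0:
            continue
        spread = rng.multinomial(n, probs)
        for off, c in zip(offsets, spread):
            if c:
                rows.append((row.chrom, max(1, int(row.tss + off)), row.strand, int(c)))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    return (
        df.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "pos", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )


# --------------------------------------------------------------------- I/O


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tr in sorted(transcripts, key=lambda x: (x.chrom, x.exons[-1][0], x.transcript_id)):
            for s, e in sorted(tr.exons):
                fh.write(
                    f"{tr.chrom}\tsynthetic\texon\t{s}\t{e}\t.\t{tr.strand}\t.\t"
                    f'gene_id "{tr.gene_id}"; transcript_id "{tr.transcript_id}"; '
                    f'gene_biotype "{tr.gene_biotype}";\n'
                )


def write_dataset(
    transcripts: list[TranscriptModel],
    truth: GroundTruth,
    signals: SimulatedSignals,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write every modality under ``outdir``; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gtf"] = outdir / "annotation.gtf"
    write_gtf(transcripts, paths["gtf"])

    paths["truth"] = outdir / "truth.tsv"
    truth.to_tsv(paths["truth"])

    paths["samples"] = outdir / "samples.tsv"
    with open(paths["samples"], "w") as fh:
        fh.write("sample\tcondition\n")
        for s, (c, _) in signals.design.samples.items():
            fh.write(f"{s}\t{c}\n")

    for sample, records in signals.sj_tables.items():
        p = outdir / f"{sample}.SJ.out.tab"
        with open(p, "w") as fh:
            for r in records:
                fh.write(
                    f"{r.chrom}\t{r.intron_first}\t{r.intron_last}\t{r.strand_code}"
                    f"\t0\t1\t{r.unique_reads}\t{r.multi_reads}\t20\n"
                )
        paths[f"sj:{sample}"] = p
    for sample, table in signals.quant_tables.items():
        p = outdir / f"{sample}.quant.sf"
        with open(p, "w") as fh:
            fh.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
            for q in table:
                fh.write(
                    f"{q.transcript_id}\t{q.length}\t{q.effective_length:.3f}"
                    f"\t{q.tpm:.6f}\t{q.num_reads:.3f}\n"
                )
        paths[f"quant:{sample}"] = p
    for sample, reads in signals.read_tables.items():
        p = outdir / f"{sample}.reads.bed"
        with open(p, "w") as fh:
            for r in reads:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")
        paths[f"reads:{sample}"] = p
    for sample, df in signals.cage_tables.items():
        p = outdir / f"{sample}.cage.tsv"
        df.to_csv(p, sep="\t", index=False, header=False)
        paths[f"cage:{sample}"] = p
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["promoters_per_gene"] = {str(k): v for k, v in d["promoters_per_gene"].items()}
    d["conditions"] = list(d["conditions"])
    return d
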