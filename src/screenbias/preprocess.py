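"""QC filtering, LFC computation, gene collapse and profile scaling.

The preprocessing chain reproduces the standard dependency-map treatment of
pooled CRISPR-Cas9 read counts:

1. drop guides with disqualifying library-alignment QC flags;
2. drop low-quality replicates (mean reads/guide < 185, best sibling
   correlation < 0.41 on high-variance genes, or NNMD > -1.25);
3. per replicate, LFC = log2 of pseudocounted, total-normalized abundance
   relative to the plasmid library; replicate LFCs averaged per model;
4. gene-level LFC = median over the gene's surviving guides;
5. optional per-model affine scaling so the median of common-essential
   controls is -1 and of non-essential controls is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    DISQUALIFYING_GUIDE_FLAGS,
    CountMatrix,
    GeneSets,
    GuideMap,
    ScreenMatrix,
)
from .quality import nnmd

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_guides",
    "filter_replicates",
    "compute_replicate_lfc",
    "compute_lfc",
    "collapse_to_genes",
    "scale_profiles",
]


@dataclass(frozen=True)
class QCThresholds:
    """Replicate-level QC thresholds (defaults are the standard cut-offs)."""

    min_mean_reads: float = 185.0
    min_replicate_correlation: float = 0.41
    max_nnmd: float = -1.25
    n_high_variance_genes: int = 100


@dataclass
class QCReport:
    """Record of removed guides/replicates and the thresholds applied."""

    removed_guides: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["guide_id", "reasons"])
    )
    removed_replicates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["replicate", "model", "mean_reads", "correlation", "nnmd"]
        )
    )
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    notes: list[str] = field(default_factory=list)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "removed_guides": self.removed_guides,
            "removed_replicates": self.removed_replicates,
        }

    def summary(self) -> dict:
        return {
            "n_removed_guides": int(len(self.removed_guides)),
            "n_removed_replicates": int(len(self.removed_replicates)),
            "thresholds": vars(self.thresholds) | {},
            "notes": list(self.notes),
        }


def filter_guides(guidemap: GuideMap) -> tuple[GuideMap, QCReport]:
    """Remove guides carrying any disqualifying QC flag."""
    flags = guidemap.table["qc_flags"]
    bad = flags.map(lambda f: bool(f & DISQUALIFYING_GUIDE_FLAGS))
    report = QCReport()
    report.removed_guides = pd.DataFrame(
        {
            "guide_id": guidemap.table.index[bad],
            "reasons": [
                ";".join(sorted(f & DISQUALIFYING_GUIDE_FLAGS))
                for f in flags[bad]
            ],
        }
    )
    surviving = guidemap.table[~bad]
    if surviving.empty:
        raise ValueError("no guides survive QC filtering")
    return GuideMap(surviving), report


def compute_replicate_lfc(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-replicate guide LFC against the plasmid reference.

    LFC_g = log2((c_g,s + pc) / T_s) - log2((c_g,p + pc) / T_p) with T the
    raw sample total. With several plasmid samples, the log2-normalized
    plasmid abundances are averaged into one reference profile.
    """
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    logabund = np.log2(counts.values.add(pseudocount)).sub(np.log2(totals), axis=1)
    plasmid_ref = logabund[counts.plasmid_samples].mean(axis=1)
    return logabund[counts.replicate_samples].sub(plasmid_ref, axis=0)


def compute_lfc(counts: CountMatrix, pseudocount: float = 1.0) -> ScreenMatrix:
    """Guide-level LFC per model: replicate LFCs averaged across replicates."""
    rep_lfc = compute_replicate_lfc(counts, pseudocount)
    by_model = rep_lfc.T.groupby(
        [counts.replicate_to_model[s] for s in rep_lfc.columns]
    ).mean().T
    return ScreenMatrix(by_model, level="guide", scale_tag="raw")


def filter_replicates(
    counts: CountMatrix,
    lfc_preview: ScreenMatrix,
    gene_sets: GeneSets,
    high_variance_genes=None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[CountMatrix, QCReport]:
    """Drop low-quality replicates and models left with no replicate.

    ``lfc_preview`` must be a gene-level matrix with one column per
    *replicate sample* (not per model); replicate correlations are computed
    on gene-level profiles restricted to the high-variance genes (top
    ``thresholds.n_high_variance_genes`` by variance when not supplied).
    A replicate fails if any of: mean reads/guide below the minimum, best
    Pearson correlation with a sibling replicate below the minimum
    (criterion skipped and flagged for single-replicate models), or NNMD
    above the maximum.
    """
    if lfc_preview.level != "gene":
        raise ValueError("lfc_preview must be gene-level (see QCReport notes)")
    report = QCReport(thresholds=thresholds)
    preview = lfc_preview.values
    if high_variance_genes is None:
        variances = preview.var(axis=1)
        high_variance_genes = (
            variances.sort_values(ascending=False)
            .head(thresholds.n_high_variance_genes)
            .index
        )
        report.notes.append(
            f"high-variance genes computed from preview (top {len(high_variance_genes)})"
        )
    hv = pd.Index(high_variance_genes).intersection(preview.index)

    ess = list(gene_sets.essential & set(preview.index))
    ness = list(gene_sets.nonessential & set(preview.index))

    mean_reads = counts.values[counts.replicate_samples].mean(axis=0)
    removed = []
    for model in counts.models:
        reps = counts.replicates_of(model)
        for rep in reps:
            fail_reads = mean_reads[rep] < thresholds.min_mean_reads
            siblings = [r for r in reps if r != rep]
            if siblings:
                corr = max(
                    preview.loc[hv, rep].corr(preview.loc[hv, sib])
                    for sib in siblings
                )
                fail_corr = corr < thresholds.min_replicate_correlation
            else:
                corr = np.nan
                fail_corr = False
                report.notes.append(
                    f"model {model!r}: single replicate, correlation QC skipped"
                )
            rep_nnmd = nnmd(preview.loc[ess, rep], preview.loc[ness, rep])
            fail_nnmd = rep_nnmd > thresholds.max_nnmd
            if fail_reads or fail_corr or fail_nnmd:
                removed.append(
                    {
                        "replicate": rep,
                        "model": model,
                        "mean_reads": bool(fail_reads),
                        "correlation": bool(fail_corr),
                        "nnmd": bool(fail_nnmd),
                    }
                )
    report.removed_replicates = pd.DataFrame(
        removed, columns=["replicate", "model", "mean_reads", "correlation", "nnmd"]
    )
    dropped = set(report.removed_replicates["replicate"])
    keep = [
        s
        for s in counts.values.columns
        if counts.sample_roles[s] == "plasmid" or s not in dropped
    ]
    filtered = CountMatrix(
        counts.values[keep],
        {s: counts.sample_roles[s] for s in keep},
        {s: m for s, m in counts.replicate_to_model.items() if s in keep},
    )
    lost_models = set(counts.models) - set(filtered.models)
    if lost_models:
        warnings.warn(
            f"model(s) lost all replicates and were dropped: {sorted(lost_models)}",
            stacklevel=2,
        )
    return filtered, report


def collapse_to_genes(guide_lfc: ScreenMatrix, guidemap: GuideMap) -> ScreenMatrix:
    """Gene-level LFC = median over the gene's guides, per model.

    Guides absent from the guide map and genes left with zero surviving
    guides are dropped. The median of an even number of guides is the
    midpoint of the two central values.
    """
    if guide_lfc.level != "guide":
        raise ValueError("collapse_to_genes expects a guide-level matrix")
    common = guide_lfc.values.index.intersection(guidemap.guides)
    mapped = guide_lfc.values.loc[common]
    gene_of = guidemap.table.loc[common, "gene"]
    collapsed = mapped.groupby(gene_of.to_numpy()).median()
    collapsed.index.name = "gene"
    return ScreenMatrix(collapsed, level="gene", scale_tag=guide_lfc.scale_tag)


def scale_profiles(m: ScreenMatrix, gene_sets: GeneSets) -> ScreenMatrix:
    """Affine-scale each model so median(essential) = -1, median(non-ess) = 0.

    The transform is x -> (x - med_N) / (med_N - med_E) per model; it is
    idempotent and preserves ranks within each model.
    """
    ess = list(gene_sets.essential & set(m.values.index))
    ness = list(gene_sets.nonessential & set(m.values.index))
    if not ess or not ness:
        raise ValueError("both control sets must be represented in the matrix")
    med_e = m.values.loc[ess].median(axis=0)
    med_n = m.values.loc[ness].median(axis=0)
    denom = med_n - med_e
    degenerate = denom[denom == 0]
    if not degenerate.empty:
        raise ValueError(
            f"degenerate screen(s) with med_E == med_N: {list(degenerate.index)}"
        )
    scaled = m.values.sub(med_n, axis=1).div(denom, axis=1)
    return m.with_values(scaled, scale_tag="scaled")
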