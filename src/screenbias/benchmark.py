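"""End-to-end benchmark of correction methods on one screen bundle.

For every labelled corrected matrix (plus the mandatory ``uncorrected``
baseline) the full evaluation suite is run: proximity bias (mean per-arm
BMP, TP53 ratio when available), CN bias (mean per-screen AURC, dataset
ARD), data quality (median AUROC/AUPRC/NNMD, recall at fixed FDR per gene
set), oncogene-addiction AUROC, and the biomarker hit count. Corrected
methods are contrasted against the baseline with a two-sided paired t-test
over per-arm BMPs (arms are the compared unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cn_bias, quality
from .datamodel import ScreenBundle, ScreenMatrix
from .preprocess import scale_profiles
from .proximity import proximity_report

__all__ = ["BenchmarkTable", "run_benchmark", "summarize_vs_uncorrected"]


@dataclass
class BenchmarkTable:
    """Per-method metric table plus the per-screen/per-arm detail it summarizes."""

    table: pd.DataFrame
    per_arm_bmp: dict[str, pd.DataFrame] = field(default_factory=dict)
    per_screen: dict[str, pd.DataFrame] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="method")


def _evaluate_method(
    bundle: ScreenBundle,
    matrix: ScreenMatrix,
    seed: int,
    max_inter_pairs: int | None,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    row: dict = {}
    prox = proximity_report(
        matrix, bundle.annotation, cfe=bundle.cfe,
        max_inter_pairs=max_inter_pairs, seed=seed,
    )
    row["mean_bmp"] = prox.mean_bmp
    if prox.arm_ratio is not None:
        row["bmp_tp53_ratio"] = prox.arm_ratio

    aurcs = cn_bias.per_screen_aurc(matrix, bundle.omics)
    row["mean_aurc"] = float(aurcs.mean())
    row["ard"], _ = cn_bias.dataset_ard(matrix, bundle.omics)

    per_screen_rows = []
    for model in matrix.values.columns:
        lfc = matrix.values[model]
        auroc, auprc = quality.screen_roc(lfc, bundle.gene_sets)
        ess = sorted(bundle.gene_sets.essential & set(lfc.index))
        ness = sorted(bundle.gene_sets.nonessential & set(lfc.index))
        rec = quality.recall_at_fdr(
            lfc, bundle.gene_sets, bundle.gene_sets.msigdb_sets
        )
        per_screen_rows.append(
            {
                "model": model,
                "auroc": auroc,
                "auprc": auprc,
                "nnmd": quality.nnmd(lfc.loc[ess], lfc.loc[ness]),
                "aurc": aurcs.get(model, np.nan),
                **{f"recall_{k}": v for k, v in rec.recalls.items()},
            }
        )
    per_screen = pd.DataFrame(per_screen_rows).set_index("model")
    row["median_auroc"] = float(per_screen["auroc"].median())
    row["median_auprc"] = float(per_screen["auprc"].median())
    row["median_nnmd"] = float(per_screen["nnmd"].median())
    for col in per_screen.columns:
        if col.startswith("recall_"):
            row[f"median_{col}"] = float(per_screen[col].median())

    if bundle.mutation_calls is not None and bundle.gene_sets.oncogenes:
        scaled = scale_profiles(matrix, bundle.gene_sets)
        row["oncogene_auroc"] = quality.oncogene_addiction_auroc(
            scaled, bundle.omics, bundle.gene_sets.oncogenes, bundle.mutation_calls
        )
    if bundle.cfe is not None and bundle.gene_sets.ssd_genes:
        scan = quality.biomarker_scan(matrix, bundle.cfe, bundle.gene_sets.ssd_genes)
        row["n_biomarker_hits"] = int(len(scan.hits))
        row["n_biomarker_tests"] = scan.n_tests
    return row, prox.per_arm, per_screen


def run_benchmark(
    bundle: ScreenBundle,
    methods: list[ScreenMatrix] | None = None,
    seed: int = 0,
    max_inter_pairs: int | None = 1_000_000,
) -> BenchmarkTable:
    """Evaluate the uncorrected baseline and every labelled corrected matrix.

    ``methods`` are ScreenMatrix objects with ``name`` set (see
    :func:`screenbias.corrections.register_external_correction`). A failing
    stage marks the method's row and the benchmark continues.
    """
    entries: list[ScreenMatrix] = [
        bundle.screen if bundle.screen.name else
        bundle.screen.with_values(bundle.screen.values, name="uncorrected")
    ]
    entries[0].name = "uncorrected"
    for m in methods or []:
        if not m.name:
            raise ValueError("every method matrix must carry a name")
        entries.append(m)

    rows: dict[str, dict] = {}
    result = BenchmarkTable(table=pd.DataFrame())
    for entry in entries:
        try:
            row, per_arm, per_screen = _evaluate_method(
                bundle, entry, seed, max_inter_pairs
            )
        except Exception as exc:  # partial table with failure markers
            result.failures[entry.name] = f"{type(exc).__name__}: {exc}"
            rows[entry.name] = {}
            continue
        rows[entry.name] = row
        result.per_arm_bmp[entry.name] = per_arm
        result.per_screen[entry.name] = per_screen

    base = result.per_arm_bmp.get("uncorrected")
    for name in list(rows):
        if name == "uncorrected" or base is None or name not in result.per_arm_bmp:
            continue
        merged = base.merge(
            result.per_arm_bmp[name], on=["chromosome", "arm"], suffixes=("_0", "_1")
        )
        if len(merged) >= 2:
            t, p = stats.ttest_rel(merged["bmp_1"], merged["bmp_0"])
            rows[name]["bmp_vs_uncorrected_p"] = float(p)
    result.table = pd.DataFrame.from_dict(rows, orient="index")
    result.table.index.name = "method"
    return result


def summarize_vs_uncorrected(table: BenchmarkTable) -> pd.DataFrame:
    """Percentage change of every metric relative to the uncorrected baseline.

    100 * (method - uncorrected) / |uncorrected|; cells with a zero baseline
    are NaN (flagged, not silently dropped). Sign convention: for metrics
    where lower/more negative is better (e.g. NNMD), a negative change is an
    improvement.
    """
    if "uncorrected" not in table.table.index:
        raise ValueError("baseline row 'uncorrected' missing")
    metrics = table.table.select_dtypes(include=[np.number])
    base = metrics.loc["uncorrected"]
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (metrics.subtract(base, axis=1)).divide(base.abs(), axis=1)
    change[metrics.columns[base == 0]] = np.nan
    return change.drop(index="uncorrected")
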