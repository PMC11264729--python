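"""Arm-level bias corrections for gene-effect / LFC matrices.

Two in-house corrections are implemented:

* **Arm-median alignment** (applied after a Chronos-style gene-effect fit):
  for every chromosome arm with more than five genes, each screen's arm
  median gene effect m_s is aligned to the median of m_s across screens,
  i.e. every gene on the arm is shifted by -(m_s - med(m_s)). With a single
  screen the formula collapses and the matrix is returned unchanged.

* **Unexpressed-gene centering** (the "geometric" estimator of proximity
  bias): per model and chromosome arm, the mean LFC of the model's
  unexpressed genes (TPM < 1) on that arm is subtracted from every gene on
  the arm. Arms with no unexpressed gene in a model are left unchanged for
  that model and counted in the returned summary.

Both corrections are pure per-(screen, arm) shifts: they are idempotent and
preserve the rank order of genes within each (screen, arm).

Externally corrected matrices (e.g. from CRISPRcleanR, MAGeCK MLE, Crispy,
GAM or LDO) enter the benchmark through :func:`register_external_correction`
rather than being recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import GenomeAnnotation, OmicsProfiles, ScreenMatrix

__all__ = [
    "ArmCorrectionState",
    "ac_chronos_correct",
    "GeometricCorrectionSummary",
    "geometric_correct",
    "register_external_correction",
    "MIN_ARM_GENES",
]

#: An arm is corrected only when it carries more than this many genes
#: (counted on the shared gene axis), so that the arm median is stable.
MIN_ARM_GENES = 5


@dataclass
class ArmCorrectionState:
    """Audit trail of the arm-median alignment.

    ``table`` has one row per (screen, chromosome, arm) that qualified, with
    the pre-correction arm median ``m_s``, the cross-screen median ``med_m``
    and the applied ``shift`` = m_s - med_m.
    """

    table: pd.DataFrame
    skipped_arms: list[tuple[str, str]]
    unmapped_genes: list[str]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def ac_chronos_correct(
    effects: ScreenMatrix,
    annotation: GenomeAnnotation,
    min_arm_genes: int = MIN_ARM_GENES,
) -> tuple[ScreenMatrix, ArmCorrectionState]:
    """Align each chromosome arm's median gene effect across screens.

    For every arm with more than ``min_arm_genes`` genes, each screen s is
    shifted by -(m_s - med(m_s)), where m_s is the arm's median gene effect
    in screen s and med(m_s) the median of m_s over screens. Arms at or
    below the gene threshold and genes without arm assignment are untouched.
    """
    arms, unmapped = annotation.assign_arms(effects.values.index)
    out = effects.values.copy()
    records: list[dict] = []
    skipped: list[tuple[str, str]] = []
    for (chrom, arm), sub in arms.groupby(["chromosome", "arm"], sort=True):
        genes = sub.index
        if len(genes) <= min_arm_genes:
            skipped.append((str(chrom), str(arm)))
            continue
        block = out.loc[genes]
        m_s = block.median(axis=0)
        med_m = m_s.median()
        shift = m_s - med_m
        out.loc[genes] = block.sub(shift, axis=1)
        for screen in out.columns:
            records.append(
                {
                    "screen": screen,
                    "chromosome": chrom,
                    "arm": arm,
                    "m_s": float(m_s[screen]),
                    "med_m": float(med_m),
                    "shift": float(shift[screen]),
                }
            )
    state = ArmCorrectionState(
        pd.DataFrame(records, columns=["screen", "chromosome", "arm", "m_s", "med_m", "shift"]),
        skipped,
        unmapped,
    )
    corrected = effects.with_values(out, scale_tag="corrected", name="ac_chronos")
    return corrected, state


@dataclass
class GeometricCorrectionSummary:
    """Per-(model, arm) record of the unexpressed-gene centering."""

    table: pd.DataFrame  # model, chromosome, arm, n_unexpressed, shift
    n_skipped: int  # (model, arm) pairs with no unexpressed gene

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def geometric_correct(
    lfc: ScreenMatrix,
    omics: OmicsProfiles,
    annotation: GenomeAnnotation,
    tpm_threshold: float = 1.0,
) -> tuple[ScreenMatrix, GeometricCorrectionSummary]:
    """Center each (model, arm) on its unexpressed genes.

    Per model and arm, every gene's LFC is reduced by the mean LFC of the
    model's unexpressed genes (TPM strictly below ``tpm_threshold``) on that
    arm, so the corrected unexpressed mean is exactly 0. A (model, arm) with
    no unexpressed gene is left unchanged and counted in the summary.
    """
    arms, _ = annotation.assign_arms(lfc.values.index)
    out = lfc.values.copy()
    records: list[dict] = []
    n_skipped = 0
    tpm = omics.tpm
    models = [m for m in out.columns if m in tpm.columns]
    for (chrom, arm), sub in arms.groupby(["chromosome", "arm"], sort=True):
        genes = sub.index
        genes_with_tpm = genes.intersection(tpm.index)
        block = out.loc[genes, models]
        if len(genes_with_tpm) == 0:
            n_skipped += len(models)
            continue
        unexpr = tpm.loc[genes_with_tpm, models] < tpm_threshold
        n_unexpr = unexpr.sum(axis=0)
        shift = (
            out.loc[genes_with_tpm, models].where(unexpr).mean(axis=0)
        ).where(n_unexpr > 0, 0.0)
        out.loc[genes, models] = block.sub(shift, axis=1)
        n_skipped += int((n_unexpr == 0).sum())
        for model in models:
            records.append(
                {
                    "model": model,
                    "chromosome": chrom,
                    "arm": arm,
                    "n_unexpressed": int(n_unexpr[model]),
                    "shift": float(shift[model]),
                }
            )
    summary = GeometricCorrectionSummary(
        pd.DataFrame(records, columns=["model", "chromosome", "arm", "n_unexpressed", "shift"]),
        n_skipped,
    )
    corrected = lfc.with_values(out, scale_tag="corrected", name="geometric")
    return corrected, summary


def register_external_correction(
    name: str, corrected: ScreenMatrix, reference: ScreenMatrix
) -> ScreenMatrix:
    """Label an externally corrected matrix and align it to the reference axes.

    The corrected matrix must cover every gene and model of ``reference``
    (the uncorrected matrix after cohort intersection); missing entries are
    reported by name.
    """
    missing_genes = reference.values.index.difference(corrected.values.index)
    missing_models = reference.values.columns.difference(corrected.values.columns)
    if len(missing_genes) or len(missing_models):
        raise ValueError(
            f"external matrix {name!r} is missing "
            f"{len(missing_genes)} gene(s) {list(missing_genes[:10])} and "
            f"{len(missing_models)} model(s) {list(missing_models[:10])}"
        )
    aligned = corrected.values.loc[reference.values.index, reference.values.columns]
    return ScreenMatrix(aligned, level=reference.level, scale_tag="corrected", name=name)
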