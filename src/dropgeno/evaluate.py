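"""Detection statistics for variant genotyping in end-biased snRNA-seq.

Quantifies when a known variant is recoverable from droplet data: the
fraction of cells with any UMI covering the position, how that fraction
stratifies by distance from the kit-relevant transcript end and by gene
expression, the false-positive rate on a null set of variants the sample
cannot carry, per-cluster variant allele fractions, and the 5'-vs-3'
genotyped-cell asymmetry. All statistics are intended to be computed per
patient and per kit; pooling is the caller's explicit choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype import ALT, NO_CALL, REF, GenotypeMatrices


def detection_fraction(matrices: GenotypeMatrices) -> pd.Series:
    """Per-variant fraction of cells with UMI-level coverage (>= 1 ref or
    alt UMI) over all cells on the barcode axis."""
    n_cells = len(matrices.barcodes)
    if n_cells == 0:
        raise ValueError("no cells on the barcode axis")
    covered = (np.asarray(matrices.coverage.todense()) >= 1).sum(axis=0)
    return pd.Series(covered / n_cells, index=matrices.variant_ids(), name="detection_fraction")


def build_detection_records(
    matrices: GenotypeMatrices,
    distances: Mapping[str, dict],
    mean_expr: Optional[pd.Series] = None,
    kit: str = "3p",
) -> pd.DataFrame:
    """One row per variant joining detection fraction to its kit-matched end
    distance, effective (mispriming-aware) distance, and the mean
    log-normalized expression of its gene.

    ``distances`` maps variant id -> dict with keys dist_relevant and
    optionally effective_distance; ``mean_expr`` is indexed by gene id.
    """
    det = detection_fraction(matrices)
    rows = []
    for v in matrices.variants:
        d = distances.get(v.id, {})
        rows.append(
            {
                "variant": v.id,
                "gene_id": v.gene_id,
                "role": v.role,
                "kit": kit,
                "n_cells": len(matrices.barcodes),
                "n_covered": int(round(det[v.id] * len(matrices.barcodes))),
                "detection_fraction": float(det[v.id]),
                "dist_relevant": d.get("dist_relevant", np.nan),
                "effective_distance": d.get("effective_distance", d.get("dist_relevant", np.nan)),
                "mean_lognorm_expr": (
                    float(mean_expr.get(v.gene_id, np.nan)) if mean_expr is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def stratify_by_distance(
    records: pd.DataFrame,
    near_threshold: int = 100,
    far_threshold: int = 1000,
    detect_threshold: float = 0.05,
    distance_column: str = "dist_relevant",
) -> pd.DataFrame:
    """Fraction of variants detected in at least ``detect_threshold`` of
    cells, within cumulative distance strata of the kit-relevant end
    (<= near, <= far, > far). Empty strata report NaN, not 0."""
    d = records[distance_column]
    strata = {
        f"<={near_threshold}bp": d <= near_threshold,
        f"<={far_threshold}bp": d <= far_threshold,
        f">{far_threshold}bp": d > far_threshold,
    }
    rows = []
    for name, mask in strata.items():
        sub = records[mask]
        rows.append(
            {
                "stratum": name,
                "n_variants": len(sub),
                "n_detected": int((sub["detection_fraction"] >= detect_threshold).sum()),
                "fraction_detected": (
                    float((sub["detection_fraction"] >= detect_threshold).mean())
                    if len(sub)
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def stratify_by_expression(
    records: pd.DataFrame,
    expr_thresholds: Sequence[float] = (0.1, 5.0),
    detect_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fraction of variants detected, among variants whose gene's mean
    log-normalized expression exceeds each threshold."""
    rows = []
    for t in expr_thresholds:
        sub = records[records["mean_lognorm_expr"] > t]
        rows.append(
            {
                "stratum": f"expr>{t:g}",
                "n_variants": len(sub),
                "n_detected": int((sub["detection_fraction"] >= detect_threshold).sum()),
                "fraction_detected": (
                    float((sub["detection_fraction"] >= detect_threshold).mean())
                    if len(sub)
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FprResult:
    n_null_variants: int
    n_variants_with_alt: int
    per_variant_fpr: float
    n_cell_alt_calls: int
    per_cell_call_fpr: float
    single_nucleus_offenders: tuple[str, ...]  # offending variants with exactly one alt cell


def false_positive_rate(matrices: GenotypeMatrices) -> FprResult:
    """False-positive rate on a null variant set.

    The input matrices must be restricted to variants the sample cannot
    truly carry (e.g. another patient's private variants, absent from
    population databases). Reported per variant (fraction of null variants
    with any ALT call) and per cell call, flagging offenders whose alt
    evidence is a single nucleus.
    """
    null_idx = [j for j, v in enumerate(matrices.variants) if v.role == "null_set"]
    if not null_idx and matrices.variants:
        null_idx = list(range(len(matrices.variants)))  # caller pre-restricted
    if not null_idx:
        raise ValueError("empty null variant set")
    alt = np.asarray(matrices.alt_umis.todense())[:, null_idx]
    cov = np.asarray(matrices.coverage.todense())[:, null_idx]
    alt_cells_per_variant = (alt >= 1).sum(axis=0)
    offenders = np.nonzero(alt_cells_per_variant > 0)[0]
    genotyped_calls = int((cov >= 1).sum())
    n_alt_calls = int((alt >= 1).sum())
    return FprResult(
        n_null_variants=len(null_idx),
        n_variants_with_alt=int(len(offenders)),
        per_variant_fpr=float(len(offenders) / len(null_idx)),
        n_cell_alt_calls=n_alt_calls,
        per_cell_call_fpr=float(n_alt_calls / genotyped_calls) if genotyped_calls else 0.0,
        single_nucleus_offenders=tuple(
            matrices.variants[null_idx[k]].id
            for k in offenders
            if alt_cells_per_variant[k] == 1
        ),
    )


def per_cluster_vaf(annotated_calls: pd.DataFrame, variant: Optional[str] = None) -> pd.DataFrame:
    """Per-cluster call composition and variant allele fraction.

    vaf = n_alt / (n_alt + n_ref), over genotyped cells only (NO_CALL
    excluded from the denominator); an "of all cells" column is emitted
    alongside. Clusters with zero genotyped cells report NaN. A final
    'ALL' row gives the overall composition, whose alt fraction over all
    cells is the single-cell analogue of a bulk VAF for a mosaic variant.
    """
    if annotated_calls.empty:
        raise ValueError("empty call table")
    df = annotated_calls
    if variant is not None:
        df = df[df["variant"] == variant]
    if "cluster" not in df.columns:
        raise ValueError("calls must carry a 'cluster' column (join cell metadata first)")

    def summarize(sub: pd.DataFrame, label: str) -> dict:
        n_alt = int((sub["call"] == "alt").sum())
        n_ref = int((sub["call"] == "ref").sum())
        n_nocall = int((sub["call"] == "no_call").sum())
        genotyped = n_alt + n_ref
        return {
            "cluster": label,
            "n_alt": n_alt,
            "n_ref": n_ref,
            "n_nocall": n_nocall,
            "n_cells": len(sub),
            "vaf": n_alt / genotyped if genotyped else np.nan,
            "alt_fraction_all_cells": n_alt / len(sub) if len(sub) else np.nan,
        }

    rows = [summarize(grp, str(cl)) for cl, grp in df.groupby("cluster")]
    rows.append(summarize(df, "ALL"))
    return pd.DataFrame(rows)


def kit_genotyped_fraction(matrices_by_kit: Mapping[str, GenotypeMatrices]) -> pd.DataFrame:
    """Fraction of cells with a call other than NO_CALL, per kit, for the
    same variant panel — the 5'-vs-3' asymmetry for an end-proximal variant."""
    rows = []
    for kit, m in matrices_by_kit.items():
        genotyped = (m.calls != NO_CALL).any(axis=1).sum() if m.calls.size else 0
        per_variant = {
            v.id: float((m.calls[:, j] != NO_CALL).mean()) for j, v in enumerate(m.variants)
        }
        rows.append(
            {
                "kit": kit,
                "n_cells": len(m.barcodes),
                "fraction_genotyped": float(genotyped / len(m.barcodes)) if m.barcodes else 0.0,
                **{f"fraction[{k}]": f for k, f in per_variant.items()},
            }
        )
    return pd.DataFrame(rows)
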