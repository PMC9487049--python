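"""Targeted immune-panel expression analysis.

Normalization divides each sample's counts by the geometric mean of that
sample's housekeeping genes (counts floored at 1 first, so logs are always
defined); normalized values are then log2 transformed. Differential
expression regresses each endogenous gene's log2 value on the binary HPV
indicator by ordinary least squares — with a single binary covariate this
is the equal-variance two-sample t-test — and adjusts p-values across genes
by Benjamini-Hochberg. A gene is called differentially expressed when
|log2 fold change| > 1 and adjusted p < 0.05 (configurable).

Signature scores are unweighted means of a sample's log2 values over a
predefined gene set; ratios between two signatures are score differences
(log2 of the linear ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import (
    AnalysisConfig,
    ExpressionMatrix,
    ImmunotimeError,
    SignatureSet,
    ValidationError,
)

logger = logging.getLogger("immunotime")


@dataclass
class DEResult:
    gene: str
    log2_fold_change: float  # positive-group mean minus negative-group mean
    p_value: float
    adjusted_p: float
    is_deg: bool


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    signature: str
    score: float
    n_missing_genes: int = 0


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_housekeeping(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample ratio to the geometric mean of the housekeeping genes."""
    if matrix.scale != "raw_counts":
        raise ValidationError(f"expected raw_counts, got scale {matrix.scale!r}")
    if not matrix.housekeeping:
        raise ImmunotimeError("no housekeeping genes flagged — cannot normalize")
    hk = sorted(matrix.housekeeping)
    raw_hk = matrix.values.loc[hk]
    zero_rows = (raw_hk <= 0).all(axis=0)
    if zero_rows.any():
        logger.warning(
            "samples with all-zero housekeeping counts before flooring: %s",
            list(matrix.values.columns[zero_rows]),
        )
    floored = matrix.values.clip(lower=1.0)
    geomean = np.exp(np.log(floored.loc[hk]).mean(axis=0))  # per sample
    normalized = floored.divide(geomean, axis=1)
    return matrix.with_values(normalized, "normalized")


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    if matrix.scale != "normalized":
        raise ValidationError(f"expected normalized, got scale {matrix.scale!r}")
    if (matrix.values.values <= 0).any():
        raise ImmunotimeError("non-positive normalized value — upstream flooring broken")
    return matrix.with_values(np.log2(matrix.values), "log2")


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (input order preserved, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    group_labels: dict[str, str],
    config: AnalysisConfig | None = None,
) -> list[DEResult]:
    """Per-endogenous-gene two-group comparison on the log2 scale.

    ``group_labels`` maps sample ID → "positive" | "negative". The fold
    change is the positive-group mean minus the negative-group mean; the
    p-value comes from the OLS coefficient's t statistic (df = n − 2).
    Genes with zero residual variance get a missing p and are excluded from
    the BH family.
    """
    if config is None:
        config = AnalysisConfig()
    if matrix.scale != "log2":
        raise ValidationError(f"expected log2 scale, got {matrix.scale!r}")
    samples = matrix.samples
    labels = []
    for s in samples:
        if s not in group_labels:
            raise ValidationError(f"sample {s!r} has no group label")
        lab = group_labels[s]
        if lab not in ("positive", "negative"):
            raise ValidationError(f"sample {s!r}: unknown group {lab!r}")
        labels.append(lab)
    pos = np.array([lab == "positive" for lab in labels])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValidationError(
            f"need ≥2 samples per group (got {n_pos} positive, {n_neg} negative)"
        )

    genes = matrix.endogenous
    vals = matrix.values.loc[genes].to_numpy(float)
    mean_pos = vals[:, pos].mean(axis=1)
    mean_neg = vals[:, ~pos].mean(axis=1)
    lfc = mean_pos - mean_neg
    # pooled (equal-variance) residual variance of the two-group OLS fit
    ss = ((vals[:, pos] - mean_pos[:, None]) ** 2).sum(axis=1) + (
        (vals[:, ~pos] - mean_neg[:, None]) ** 2
    ).sum(axis=1)
    df_resid = n_pos + n_neg - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = ss / df_resid
        se = np.sqrt(s2 * (1.0 / n_pos + 1.0 / n_neg))
        t = lfc / se
    p = 2.0 * sps.t.sf(np.abs(t), df_resid)
    degenerate = se == 0
    if degenerate.any():
        logger.warning(
            "%d genes with zero residual variance excluded from testing",
            int(degenerate.sum()),
        )
    valid = ~degenerate
    adj = np.full(len(genes), np.nan)
    if valid.any():
        adj[valid] = bh_adjust(p[valid])

    results = []
    for i, g in enumerate(genes):
        if degenerate[i]:
            results.append(DEResult(g, float(lfc[i]), float("nan"), float("nan"), False))
        else:
            is_deg = bool(
                abs(lfc[i]) > config.deg_log2fc_threshold and adj[i] < config.deg_alpha
            )
            results.append(DEResult(g, float(lfc[i]), float(p[i]), float(adj[i]), is_deg))
    return results


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Signature scoring
# ---------------------------------------------------------------------------


def signature_score(
    matrix: ExpressionMatrix, signature: SignatureSet, sample_id: str
) -> SignatureScore:
    """Unweighted mean log2 expression of the signature's member genes."""
    if matrix.scale != "log2":
        raise ValidationError(f"expected log2 scale, got {matrix.scale!r}")
    if sample_id not in matrix.values.columns:
        raise ValidationError(f"unknown sample {sample_id!r}")
    present = [g for g in signature.genes if g in matrix.values.index]
    if not present:
        raise ImmunotimeError(
            f"signature {signature.name!r}: none of its genes are in the matrix"
        )
    missing = len(signature.genes) - len(present)
    if missing:
        logger.warning(
            "signature %s: %d/%d genes absent from matrix",
            signature.name,
            missing,
            len(signature.genes),
        )
    score = float(matrix.values.loc[present, sample_id].mean())
    return SignatureScore(sample_id, signature.name, score, missing)


def signature_ratio(score_a: SignatureScore, score_b: SignatureScore) -> float:
    """Score difference on the log2 scale (= log2 of the linear ratio)."""
    if score_a.sample_id != score_b.sample_id:
        raise ValidationError(
            f"scores from different samples: {score_a.sample_id!r} vs "
            f"{score_b.sample_id!r}"
        )
    return score_a.score - score_b.score


def score_matrix(
    matrix: ExpressionMatrix, signatures: list[SignatureSet]
) -> pd.DataFrame:
    """Signatures × samples score table."""
    rows = {}
    for sig in signatures:
        rows[sig.name] = [
            signature_score(matrix, sig, s).score for s in matrix.samples
        ]
    return pd.DataFrame(rows, index=matrix.samples).T


#: Editable placeholder cell-type / pathway gene lists (panel-style gene
#: symbols); real analyses should supply their own curated YAML.
DEFAULT_SIGNATURES: list[SignatureSet] = [
    SignatureSet("CD8 T cells", "cell_type", ("CD8A", "CD8B")),
    SignatureSet("Cytotoxic cells", "cell_type", ("GZMA", "GZMH", "GZMK", "PRF1", "GNLY", "KLRC1")),
    SignatureSet("Exhausted CD8", "cell_type", ("LAG3", "PDCD1", "CTLA4", "HAVCR2")),
    SignatureSet("Treg", "cell_type", ("FOXP3", "IL2RA")),
    SignatureSet("Macrophages", "cell_type", ("CD68", "CD163", "MARCO", "MSR1")),
    SignatureSet("Neutrophils", "cell_type", ("S100A12", "CXCL8", "FCGR3B")),
    SignatureSet("TILs", "cell_type", ("PTPRC", "CD3D", "CD3E", "CD8A", "CD4")),
    SignatureSet("Cytotoxicity pathway", "pathway", ("GZMA", "GZMB", "PRF1", "KLRK1")),
    SignatureSet("IFN-gamma signalling", "pathway", ("IFNG", "STAT1", "CXCL9", "CXCL10", "IDO1")),
]
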