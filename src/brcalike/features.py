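"""Gene-level methylation summarization and outlier-based event calling.

Methylation probes are restricted to those mapping within a window (default
300 nucleotides) of the gene's transcription start site; the gene-level beta
value per sample is the median over the retained probes.  Hypermethylated
tumors are right-tail outliers of the cohort-wide gene-level beta
distribution under a Method-II exponential fit with default parameters.
Unusually low expressors are left-tail outliers of a gene's expression
values under a Method-I lognormal fit with tail probability 1e-6 and fit
window (0.1, 0.9); zeros receive a per-gene half-minimum pseudocount before
the lognormal fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import AberrationEvent
from .errors import FitError, ValidationError
from .outliers import LEFT, RIGHT, OutlierParams, detect_outliers

logger = logging.getLogger(__name__)

DEFAULT_TSS_WINDOW = 300
HYPERMETHYLATION_PARAMS = OutlierParams(method="II", alpha=(0.05, 0.05), flim=(0.1, 0.9))
LOW_EXPRESSION_PARAMS = OutlierParams(method="I", alpha=(1e-6, 1e-6), flim=(0.1, 0.9))


@dataclass
class GeneMethylation:
    """Gene-level beta values (genes x samples) and probes used per gene."""

    betas: pd.DataFrame
    n_probes: pd.Series
    dropped_genes: list[str]


def summarize_gene_methylation(
    probes: pd.DataFrame,
    window: int = DEFAULT_TSS_WINDOW,
) -> GeneMethylation:
    """Median beta per gene per sample over near-TSS probes.

    ``probes`` columns: ``probe_id``, ``gene``, ``tss_distance`` and one
    column per sample.  Probes with a missing TSS distance or beyond the
    window are dropped; genes left without probes are omitted with a logged
    warning.
    """
    meta_cols = ["probe_id", "gene", "tss_distance"]
    for c in meta_cols:
        if c not in probes.columns:
            raise ValidationError(f"probe table missing column {c!r}")
    sample_cols = [c for c in probes.columns if c not in meta_cols]
    beta = probes[sample_cols].to_numpy(dtype=float)
    finite = beta[np.isfinite(beta)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValidationError("beta values must lie in [0, 1]")
    dist = pd.to_numeric(probes["tss_distance"], errors="coerce")
    if np.any(dist.dropna() < 0):
        raise ValidationError("TSS distances must be non-negative")
    keep = dist.notna() & (dist <= window)
    retained = probes.loc[keep]
    all_genes = probes["gene"].unique()
    grouped = retained.groupby("gene")[sample_cols]
    betas = grouped.median()
    n_probes = grouped.size()
    dropped = sorted(set(map(str, all_genes)) - set(map(str, betas.index)))
    for g in dropped:
        logger.warning("gene %s has no probes within %d nt of the TSS; omitted", g, window)
    betas.index.name = "gene"
    return GeneMethylation(betas=betas, n_probes=n_probes, dropped_genes=dropped)


def call_hypermethylation(
    gene_betas: pd.DataFrame,
    params: OutlierParams = HYPERMETHYLATION_PARAMS,
    min_samples: int = 10,
) -> list[AberrationEvent]:
    """Right-tail beta outliers per gene become hypermethylation events.

    ``gene_betas`` is genes x samples.  Genes with fewer than ``min_samples``
    non-missing values, or with a degenerate fit, are skipped with a warning.
    """
    events: list[AberrationEvent] = []
    for gene, row in gene_betas.iterrows():
        values = row.dropna()
        if len(values) < min_samples:
            logger.warning(
                "gene %s: only %d samples with beta values; skipped", gene, len(values)
            )
            continue
        try:
            fit = detect_outliers(values.to_numpy(), "exponential", params)
        except FitError as exc:
            logger.warning("gene %s: %s; skipped", gene, exc)
            continue
        for sample in values.index[fit.flags == RIGHT]:
            events.append(
                AberrationEvent(
                    patient_id=str(sample), gene=str(gene), event_type="hypermethylation"
                )
            )
    return events


def call_low_expression(
    expression: pd.DataFrame,
    params: OutlierParams = LOW_EXPRESSION_PARAMS,
    min_positive: int = 10,
) -> pd.DataFrame:
    """Left-tail lognormal outliers per gene: unusually low expressors.

    ``expression`` is genes x samples, non-negative.  Zeros are replaced per
    gene by half the smallest positive value before the lognormal fit.
    Returns a tidy frame with columns ``gene`` and ``sample``.
    """
    rows: list[tuple[str, str]] = []
    for gene, row in expression.iterrows():
        values = row.dropna().astype(float)
        if np.any(values < 0):
            raise ValidationError(f"gene {gene}: negative expression values")
        positive = values[values > 0]
        if len(positive) == 0:
            logger.warning("gene %s: all-zero expression; skipped", gene)
            continue
        if len(positive) < min_positive:
            logger.warning(
                "gene %s: only %d positive values; skipped", gene, len(positive)
            )
            continue
        pseudo = positive.min() / 2.0
        filled = values.where(values > 0, pseudo)
        try:
            fit = detect_outliers(filled.to_numpy(), "lognormal", params)
        except FitError as exc:
            logger.warning("gene %s: %s; skipped", gene, exc)
            continue
        for sample in filled.index[fit.flags == LEFT]:
            rows.append((str(gene), str(sample)))
    return pd.DataFrame(rows, columns=["gene", "sample"])
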