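"""Differential expression between tumor and normal samples.

The built-in test is a Wilcoxon rank-sum on log2 expression with
Benjamini–Hochberg correction across all genes.  Users who ran their own
differential-expression tool (e.g. DESeq2/limma) can load its output with
:func:`load_dea` instead and keep full fidelity to their pipeline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AlignedCohort, FormatError, _read_table

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene_symbol", "log2fc", "p_value", "fdr")

# exact rank-sum null is enumerated only for small tie-free groups;
# cohort-scale comparisons use the normal approximation
_EXACT_MAX_N = 12


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # zero-variance gene: no evidence either way
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (tie_free and max(len(x), len(y)) <= _EXACT_MAX_N) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def run_dea(expr: pd.DataFrame, cohort: AlignedCohort,
            fdr_max: float = 0.05, lfc_min: float = 1.0) -> pd.DataFrame:
    """Per-gene tumor-vs-normal rank-sum test on log2 expression.

    Returns the full gene table with columns gene_symbol, log2fc, p_value,
    fdr, direction, is_deg.  A gene is flagged as differentially expressed
    when fdr <= ``fdr_max`` and \\|log2fc\\| >= ``lfc_min``.
    """
    tumor = expr.loc[:, list(cohort.tumor)].to_numpy(dtype=float)
    normal = expr.loc[:, list(cohort.normal)].to_numpy(dtype=float)
    genes = expr.index.to_list()
    log2fc = np.nanmean(tumor, axis=1) - np.nanmean(normal, axis=1)
    pvals = np.empty(len(genes))
    n_flat = 0
    for i in range(len(genes)):
        t = tumor[i][np.isfinite(tumor[i])]
        n = normal[i][np.isfinite(normal[i])]
        p = _ranksum_p(t, n)
        if p == 1.0 and np.ptp(np.concatenate([t, n])) == 0:
            n_flat += 1
        pvals[i] = p
    if n_flat:
        logger.info("run_dea: %d zero-variance genes assigned p=1", n_flat)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(log2fc > 0, "up", "down")
    is_deg = (fdr <= fdr_max) & (np.abs(log2fc) >= lfc_min)
    return pd.DataFrame({
        "gene_symbol": genes,
        "log2fc": log2fc,
        "p_value": pvals,
        "fdr": fdr,
        "direction": direction,
        "is_deg": is_deg,
    })


def load_dea(path) -> pd.DataFrame:
    """Load an externally computed differential-expression table.

    Requires columns gene_symbol, log2fc, p_value, fdr; direction and
    is_deg are derived if absent.
    """
    df = _read_table(path)
    # tolerate the common short names
    df = df.rename(columns={"gene": "gene_symbol", "p": "p_value",
                            "padj": "fdr", "logFC": "log2fc"})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: DEA table missing columns {sorted(missing)}")
    df["gene_symbol"] = df["gene_symbol"].astype(str)
    for col in ("log2fc", "p_value", "fdr"):
        df[col] = df[col].astype(float)
    for col in ("p_value", "fdr"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise FormatError(f"{path}: {col} outside [0, 1]")
    if df["gene_symbol"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene symbols in DEA table")
    if "direction" not in df.columns:
        df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    if "is_deg" not in df.columns:
        df["is_deg"] = (df["fdr"] <= 0.05) & (df["log2fc"].abs() >= 1.0)
    df["is_deg"] = df["is_deg"].astype(bool)
    return df[["gene_symbol", "log2fc", "p_value", "fdr", "direction", "is_deg"]]
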