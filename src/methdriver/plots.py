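"""Deterministic, file-based visualizations of the pipeline outputs.

All figures are written as PNG and SVG with a fixed SVG hash salt, so
re-rendering the same input yields byte-identical payloads (CI-safe; no
interactive display).
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .io import AlignedCohort
from .methmix import BetaMixtureFit

logger = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "methdriver"

_EVIDENCE_ORDER = ["Agreement_OCG", "Agreement_TSG", "Conflicting",
                   "Mixed", "NoEvidence"]


def _save(fig, path: Path) -> list[Path]:
    path = Path(path)
    written = []
    for suffix in (".png", ".svg"):
        target = path.with_suffix(suffix)
        fig.savefig(target, metadata={"Date": None} if suffix == ".svg" else None)
        written.append(target)
    plt.close(fig)
    return written


def plot_gma(summary: pd.DataFrame, path) -> list[Path]:
    """Heatmap of hypo/hyper/dual CpG counts per mediator.

    Rows are ordered by evidence category then gene symbol.  Mediators
    with zero CpGs everywhere produce no file (warning).
    """
    counts = summary[["n_hypo", "n_hyper", "n_dual"]].to_numpy()
    keep = counts.sum(axis=1) > 0
    if not keep.any():
        logger.warning("plot_gma: no mediator has any functional CpG; not plotting")
        return []
    sub = summary[keep].copy()
    sub["_ev"] = pd.Categorical(sub["evidence"], categories=_EVIDENCE_ORDER,
                                ordered=True)
    sub = sub.sort_values(["_ev", "gene_symbol"])
    mat = sub[["n_hypo", "n_hyper", "n_dual"]].to_numpy()
    fig, ax = plt.subplots(figsize=(4, max(2, 0.25 * len(sub) + 1)))
    im = ax.imshow(mat, cmap="viridis", aspect="auto")
    ax.set_xticks(range(3), ["hypo", "hyper", "dual"])
    ax.set_yticks(range(len(sub)), sub["gene_symbol"])
    ax.set_title("Functional CpG counts per mediator")
    fig.colorbar(im, ax=ax, label="CpG count")
    fig.tight_layout()
    return _save(fig, Path(path))


def plot_moonlight_met(ura: pd.DataFrame, drivers, growing: str, blocking: str,
                       path) -> list[Path]:
    """Process-effect heatmap (z scores) for the predicted driver genes."""
    rows = [(g, "OCG") for g in drivers.ocgs] + [(g, "TSG") for g in drivers.tsgs]
    if not rows:
        logger.warning("plot_moonlight_met: empty driver set; not plotting")
        return []
    missing = [g for g, _ in rows if g not in ura.index]
    if missing:
        raise KeyError(f"driver genes absent from URA matrix: {missing}")
    rows.sort(key=lambda t: (t[1], t[0]))
    genes = [g for g, _ in rows]
    mat = ura.loc[genes, [growing, blocking]].to_numpy()
    lim = max(1.0, np.abs(mat).max())
    fig, ax = plt.subplots(figsize=(4, max(2, 0.25 * len(genes) + 1)))
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(2), [growing, blocking])
    ax.set_yticks(range(len(genes)),
                  [f"{g} ({r})" for g, r in rows])
    ax.set_title("Driver effects on processes (URA z)")
    fig.colorbar(im, ax=ax, label="z")
    fig.tight_layout()
    return _save(fig, Path(path))


def plot_met_exp(fit: BetaMixtureFit, expr_row: pd.Series,
                 cohort: AlignedCohort, path) -> list[Path]:
    """Two panels: beta histogram with fitted mixture densities, and the
    gene's tumor expression split by mixture component."""
    if fit.sample_ids is None:
        raise ValueError("fit carries no sample ids")
    missing = [s for s in fit.sample_ids if s not in expr_row.index]
    if missing:
        raise KeyError(f"samples missing from expression row: {missing[:3]}")
    x = np.linspace(1e-3, 1 - 1e-3, 400)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    dens = np.zeros_like(x)
    for w, mu, phi in zip(fit.weights, fit.means, fit.precisions):
        comp = w * beta_dist.pdf(x, mu * phi, (1 - mu) * phi)
        ax1.plot(x, comp, lw=1.5)
        dens += comp
    ax1.plot(x, dens, "k--", lw=1, label="mixture")
    ax1.set_xlabel("beta value")
    ax1.set_ylabel("density")
    ax1.set_title(f"{fit.probe_id} (K={fit.k})")
    ax1.legend(frameon=False)

    assign = fit.assignments
    groups, labels = [], []
    for j in range(fit.k):
        members = [s for s, a in zip(fit.sample_ids, assign) if a == j]
        if members:
            groups.append(expr_row[members].to_numpy(dtype=float))
            state = (fit.component_states[j] if fit.component_states
                     else f"comp{j}")
            labels.append(f"{state}\n(n={len(members)})")
    if cohort.normal:
        normals = [s for s in cohort.normal if s in expr_row.index]
        if normals:
            groups.append(expr_row[normals].to_numpy(dtype=float))
            labels.append(f"normal\n(n={len(normals)})")
    ax2.boxplot(groups, tick_labels=labels)
    ax2.set_ylabel(f"{expr_row.name} log2 expression")
    ax2.set_title("expression by methylation group")
    fig.tight_layout()
    return _save(fig, Path(path))
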