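"""End-to-end orchestration: expression layer then methylation layer."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import AlignedCohort, SignatureSet, align_cohort
from .dea import run_dea
from .primary import Regulon, build_grn, run_ura, run_pra
from .gma import GmaConfig, GmaOutputs, run_gma


@dataclass
class PrimaryConfig:
    """Knobs of the expression layer."""

    fdr_max: float = 0.05
    lfc_min: float = 1.0
    n_perm: int = 100
    alpha: float = 0.05
    pra_t: float = 1.0
    growing: str = "proliferation"
    blocking: str = "apoptosis"
    seed: int = 0


@dataclass
class PrimaryResults:
    deg_table: pd.DataFrame
    regulons: list[Regulon]
    ura: pd.DataFrame
    mediators: pd.DataFrame


def run_primary(expr: pd.DataFrame, cohort: AlignedCohort, sigs: SignatureSet,
                config: PrimaryConfig | None = None) -> PrimaryResults:
    """DEA → GRN → URA → PRA: from a cohort to oncogenic mediators."""
    config = config or PrimaryConfig()
    degs = run_dea(expr, cohort, fdr_max=config.fdr_max, lfc_min=config.lfc_min)
    regulons = build_grn(expr, degs, cohort, n_perm=config.n_perm,
                         alpha=config.alpha, seed=config.seed)
    ura = run_ura(regulons, degs, sigs)
    mediators = run_pra(ura, config.growing, config.blocking, t=config.pra_t)
    return PrimaryResults(deg_table=degs, regulons=regulons, ura=ura,
                          mediators=mediators)


@dataclass
class FullResults:
    cohort: AlignedCohort
    primary: PrimaryResults
    gma: GmaOutputs


def run_full(expr: pd.DataFrame, meth: pd.DataFrame, sheet: pd.DataFrame,
             manifest: pd.DataFrame, sigs: SignatureSet,
             primary_config: PrimaryConfig | None = None,
             gma_config: GmaConfig | None = None) -> FullResults:
    """Run both layers from raw inputs to the final driver-gene set."""
    primary_config = primary_config or PrimaryConfig()
    gma_config = gma_config or GmaConfig(seed=primary_config.seed)
    cohort = align_cohort(expr, meth, sheet, min_tumor=gma_config.min_tumor,
                          min_normal=gma_config.min_normal)
    primary = run_primary(expr, cohort, sigs, primary_config)
    gma_out = run_gma(expr, meth, sheet, primary.mediators, primary.deg_table,
                      manifest, gma_config, cohort=cohort)
    return FullResults(cohort=cohort, primary=primary, gma=gma_out)
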