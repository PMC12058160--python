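"""Gene-level integration of methylation evidence with putative driver roles.

The epigenetic mechanism: promoter hypomethylation can activate an
oncogene, promoter hypermethylation can silence a tumor suppressor.  A
putative oncogene whose functional CpGs are all hypomethylated therefore
has *agreeing* methylation evidence; a hypermethylated putative oncogene
(or hypomethylated putative suppressor) is *conflicting*.  Only genes
with agreement evidence are promoted from oncogenic mediator to final
driver gene.

Evidence rule table (CpG gene state × putative role):

===========  =============  ==============
gene state   putative_OCG   putative_TSG
===========  =============  ==============
Hypo         Agreement_OCG  Conflicting
Hyper        Conflicting    Agreement_TSG
Mixed        Mixed          Mixed
Dual-only    NoEvidence     NoEvidence
None         NoEvidence     NoEvidence
===========  =============  ==============

Dual CpGs (hypomethylated in some patients, hypermethylated in others)
are counted but never determine the gene state: a gene must show the same
abnormal direction in all its non-dual CpGs to be labeled Hypo or Hyper.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .io import AlignedCohort, align_cohort, write_table
from .primary import ROLE_OCG, ROLE_TSG
from . import methmix

logger = logging.getLogger(__name__)

EV_AGREE_OCG = "Agreement_OCG"
EV_AGREE_TSG = "Agreement_TSG"
EV_CONFLICT = "Conflicting"
EV_MIXED = "Mixed"
EV_NONE = "NoEvidence"

GENE_HYPO = "Hypo"
GENE_HYPER = "Hyper"
GENE_DUAL_ONLY = "Dual-only"
GENE_MIXED = "Mixed"
GENE_NONE = "None"

SUMMARY_COLUMNS = ("gene_symbol", "putative_role", "n_hypo", "n_hyper",
                   "n_dual", "gene_state", "evidence")


@dataclass(frozen=True)
class DriverGeneSet:
    """Final predicted drivers: mediators with agreement evidence."""

    tsgs: tuple[str, ...]
    ocgs: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.tsgs) & set(self.ocgs):
            raise ValueError("TSG and OCG driver lists must be disjoint")

    @property
    def all_genes(self) -> set[str]:
        return set(self.tsgs) | set(self.ocgs)


@dataclass
class GmaConfig:
    """Knobs of the methylation-evidence layer."""

    dm_min: float = 0.10          # minimum |DM value| to call a component abnormal
    assoc_fdr_max: float = 0.05   # FDR cut for CpG–expression association
    promoter_only: bool = True    # regular mode: promoter probes only
    k_max: int = 3
    seed: int = 0
    min_tumor: int = 5
    min_normal: int = 5


@dataclass
class GmaOutputs:
    drivers: DriverGeneSet
    mediator_summary: pd.DataFrame
    deg_annotation: pd.DataFrame
    functional_pairs: pd.DataFrame
    tested_pairs: pd.DataFrame
    fits: list
    cohort: AlignedCohort
    config: GmaConfig


def summarize_cpgs(mediators: pd.DataFrame,
                   pairs: pd.DataFrame) -> pd.DataFrame:
    """Count functional CpG states per mediator and derive the gene state.

    Dual CpGs are tallied but never decide Hypo/Hyper: a gene is Hypo only
    when it has ≥1 hypo and 0 hyper CpGs (and symmetrically), Mixed when
    both directions occur, Dual-only when only dual CpGs exist, None when
    the gene has no functional pairs.
    """
    counts = {}
    if not pairs.empty:
        tab = pairs.groupby("gene_symbol")["cpg_state"].value_counts().unstack(
            fill_value=0)
        for state in (methmix.STATE_HYPO, methmix.STATE_HYPER, methmix.STATE_DUAL):
            if state not in tab.columns:
                tab[state] = 0
        counts = tab.to_dict(orient="index")
    rows = []
    for _, med in mediators.iterrows():
        gene = med["gene_symbol"]
        c = counts.get(gene, {})
        n_hypo = int(c.get(methmix.STATE_HYPO, 0))
        n_hyper = int(c.get(methmix.STATE_HYPER, 0))
        n_dual = int(c.get(methmix.STATE_DUAL, 0))
        if n_hypo > 0 and n_hyper > 0:
            gene_state = GENE_MIXED
        elif n_hypo > 0:
            gene_state = GENE_HYPO
        elif n_hyper > 0:
            gene_state = GENE_HYPER
        elif n_dual > 0:
            gene_state = GENE_DUAL_ONLY
        else:
            gene_state = GENE_NONE
        rows.append((gene, med["putative_role"], n_hypo, n_hyper, n_dual,
                     gene_state, ""))
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def classify_evidence(gene_state: str, putative_role: str) -> str:
    """Apply the evidence rule table to one (gene state, role) pair."""
    if putative_role not in (ROLE_OCG, ROLE_TSG):
        raise ValueError(f"unknown putative role {putative_role!r}")
    if gene_state == GENE_HYPO:
        return EV_AGREE_OCG if putative_role == ROLE_OCG else EV_CONFLICT
    if gene_state == GENE_HYPER:
        return EV_AGREE_TSG if putative_role == ROLE_TSG else EV_CONFLICT
    if gene_state == GENE_MIXED:
        return EV_MIXED
    if gene_state in (GENE_DUAL_ONLY, GENE_NONE):
        return EV_NONE
    raise ValueError(f"unknown gene state {gene_state!r}")


def classify_summary(summary: pd.DataFrame) -> pd.DataFrame:
    summary = summary.copy()
    summary["evidence"] = [
        classify_evidence(s, r)
        for s, r in zip(summary["gene_state"], summary["putative_role"])
    ]
    return summary


def drivers_from_summary(summary: pd.DataFrame) -> DriverGeneSet:
    ocgs = summary.loc[summary["evidence"] == EV_AGREE_OCG, "gene_symbol"]
    tsgs = summary.loc[summary["evidence"] == EV_AGREE_TSG, "gene_symbol"]
    return DriverGeneSet(tsgs=tuple(sorted(tsgs)), ocgs=tuple(sorted(ocgs)))


def run_gma(expr: pd.DataFrame, meth: pd.DataFrame, sheet: pd.DataFrame,
            mediators: pd.DataFrame, deg_table: pd.DataFrame,
            manifest: pd.DataFrame, config: GmaConfig | None = None,
            cohort: AlignedCohort | None = None) -> GmaOutputs:
    """Run the full methylation-evidence layer over a cohort.

    Orchestrates mixture fitting, state calling, expression pairing, and
    evidence classification.  Emits the driver set, the mediator summary,
    a per-DEG annotation table, and the raw fit/pair tables.
    """
    config = config or GmaConfig()
    if cohort is None:
        cohort = align_cohort(expr, meth, sheet,
                              min_tumor=config.min_tumor,
                              min_normal=config.min_normal)
    fits = methmix.fit_cohort(meth, cohort, k_max=config.k_max,
                              dm_min=config.dm_min, seed=config.seed)
    pairs, tested = methmix.pair_with_expression(
        fits, manifest, expr, cohort,
        assoc_fdr_max=config.assoc_fdr_max,
        promoter_only=config.promoter_only)
    summary = classify_summary(summarize_cpgs(mediators, pairs))
    drivers = drivers_from_summary(summary)

    # conservation check: the evidence categories partition the mediators
    n_cat = summary["evidence"].isin(
        [EV_AGREE_OCG, EV_AGREE_TSG, EV_CONFLICT, EV_MIXED, EV_NONE]).sum()
    assert n_cat == len(mediators), "evidence categories must partition mediators"

    ann = deg_table.copy()
    med_idx = summary.set_index("gene_symbol")
    ann["is_mediator"] = ann["gene_symbol"].isin(med_idx.index)
    for col in ("putative_role", "n_hypo", "n_hyper", "n_dual",
                "gene_state", "evidence"):
        ann[col] = ann["gene_symbol"].map(med_idx[col])
    ann["is_driver"] = ann["gene_symbol"].isin(drivers.all_genes)

    return GmaOutputs(drivers=drivers, mediator_summary=summary,
                      deg_annotation=ann, functional_pairs=pairs,
                      tested_pairs=tested, fits=fits, cohort=cohort,
                      config=config)


def write_gma_outputs(out: GmaOutputs, outdir, extra_manifest: dict | None = None
                      ) -> None:
    """Write the four standard output tables plus a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drivers = pd.DataFrame(
        [(g, "TSG") for g in out.drivers.tsgs]
        + [(g, "OCG") for g in out.drivers.ocgs],
        columns=["gene_symbol", "role"])
    write_table(drivers, outdir / "drivers.tsv")
    write_table(out.mediator_summary, outdir / "mediator_summary.tsv")
    write_table(out.deg_annotation, outdir / "deg_annotation.tsv")
    write_table(out.tested_pairs, outdir / "raw_pairs.tsv")
    write_table(methmix.fits_to_frame(out.fits), outdir / "raw_fits.tsv")
    manifest = {"config": asdict(out.config),
                "n_tumor": len(out.cohort.tumor),
                "n_normal": len(out.cohort.normal),
                "n_mediators": int(len(out.mediator_summary)),
                "n_drivers": len(out.drivers.all_genes)}
    if extra_manifest:
        manifest.update(extra_manifest)
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
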