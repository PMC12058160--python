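"""Synthetic tumor/normal cohorts with planted methylation-driven drivers.

The generator emulates the mechanism the pipeline is built to detect:
promoter hypomethylation activating an oncogene and promoter
hypermethylation silencing a tumor suppressor.  For each planted driver,
an *abnormal* subset of tumor samples carries both the shifted
methylation component (normal mean ± delta_meth) and the corresponding
expression shift (± delta_expr) — the coupling is generated at the
sample level, matching the assumption of the mixture-group association
test.  Each driver also regulates dedicated signature genes (activated
process genes move with the driver, blocked-process genes move against
it) so the expression layer can recover its putative role.

Beta values are drawn from beta distributions parameterized by mean and
precision; expression is Gaussian on the log2 scale.  Null genes and
decoy signature genes are identical between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SignatureSet, write_matrix, write_table
from .primary import ROLE_OCG, ROLE_TSG

GROWING = "proliferation"
BLOCKING = "apoptosis"


@dataclass
class SimConfig:
    """Cohort layout and planted effect sizes (the defaults are the
    reference conditions used throughout the test-suite)."""

    n_tumor: int = 30
    n_normal: int = 20
    n_null_genes: int = 200
    n_hypo_ocg: int = 10            # planted oncogenes, promoter hypomethylated
    n_hyper_tsg: int = 10           # planted suppressors, promoter hypermethylated
    n_probes_per_gene: int = 2
    delta_meth: float = 0.4         # |abnormal component mean − normal mean|
    delta_expr: float = 2.0         # log2 expression shift in abnormal samples
    abnormal_fraction: float = 0.7  # fraction of tumors carrying the aberration
    noise_sd: float = 0.5           # log2 expression noise
    beta_precision: float = 30.0    # phi of the beta draws
    base_expr: float = 8.0          # baseline log2 expression
    driver_meth_mean: float = 0.5   # normal-tissue beta at driver promoters
    n_targets_per_process: int = 16  # regulon targets per driver per process
    n_decoy_signature: int = 20     # uncoupled signature genes per process
    coupling: float = 1.0           # regulon target coupling to driver expression
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("abnormal_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not np.isfinite(self.delta_expr):
            raise ValueError("delta_expr must be finite")
        n_planted = self.n_hypo_ocg + self.n_hyper_tsg
        if n_planted and round(self.abnormal_fraction * self.n_tumor) < 3:
            raise ValueError(
                "infeasible config: abnormal_fraction × n_tumor < 3 — the "
                "abnormal mixture group would be untestable")


@dataclass
class SimulatedCohort:
    expression: pd.DataFrame
    methylation: pd.DataFrame
    sample_sheet: pd.DataFrame
    manifest: pd.DataFrame
    signatures: SignatureSet
    truth: pd.DataFrame
    config: SimConfig


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate one fully specified cohort; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    tumor_ids = [f"T{i:03d}" for i in range(cfg.n_tumor)]
    normal_ids = [f"N{i:03d}" for i in range(cfg.n_normal)]
    samples = normal_ids + tumor_ids
    phi = cfg.beta_precision

    def rbeta(mean: float, size) -> np.ndarray:
        return rng.beta(mean * phi, (1.0 - mean) * phi, size=size)

    ocgs = [f"OCG{i:02d}" for i in range(cfg.n_hypo_ocg)]
    tsgs = [f"TSG{i:02d}" for i in range(cfg.n_hyper_tsg)]
    nulls = [f"NULL{i:03d}" for i in range(cfg.n_null_genes)]

    expr_rows: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []
    sig_entries: dict[str, dict[str, str]] = {GROWING: {}, BLOCKING: {}}

    def base_expr(n: int) -> np.ndarray:
        return cfg.base_expr + rng.normal(0.0, cfg.noise_sd, size=n)

    n_abn = round(cfg.abnormal_fraction * cfg.n_tumor)
    abnormal_sets: dict[str, np.ndarray] = {}

    # Planted drivers model independent aberration events.  At cohort
    # scale, unconstrained random subsets occasionally overlap far from
    # expectation, which correlates two drivers' expression programs by
    # accident; subsets are therefore drawn with a cap on the pairwise
    # overlap deviation so the planted events stay effectively
    # uncorrelated.
    expected_overlap = n_abn * n_abn / cfg.n_tumor
    overlap_sd = np.sqrt(n_abn**2 * (cfg.n_tumor - n_abn)**2
                         / (cfg.n_tumor**2 * max(cfg.n_tumor - 1, 1)))
    overlap_tol = max(2.0, 1.5 * overlap_sd)

    def draw_abnormal() -> np.ndarray:
        best, best_dev = None, np.inf
        for _ in range(500):
            abn = np.zeros(cfg.n_tumor, dtype=bool)
            abn[rng.choice(cfg.n_tumor, size=n_abn, replace=False)] = True
            devs = [abs(float((abn & other).sum()) - expected_overlap)
                    for other in abnormal_sets.values()]
            dev = max(devs, default=0.0)
            if dev <= overlap_tol:
                return abn
            if dev < best_dev:
                best, best_dev = abn, dev
        return best

    for gene, role in [(g, ROLE_OCG) for g in ocgs] + [(g, ROLE_TSG) for g in tsgs]:
        abn = draw_abnormal()
        abnormal_sets[gene] = abn
        shift = cfg.delta_expr if role == ROLE_OCG else -cfg.delta_expr
        tumor_expr = base_expr(cfg.n_tumor) + np.where(abn, shift, 0.0)
        expr_rows[gene] = np.concatenate([base_expr(cfg.n_normal), tumor_expr])
        meth_state = "Hypo" if role == ROLE_OCG else "Hyper"
        truth_rows.append(dict(gene_symbol=gene, role=role, meth_state=meth_state,
                               is_driver=True, category="driver"))
        # regulon targets track the driver's deviation from baseline:
        # growing-process genes follow it, blocking-process genes mirror
        # it.  An activated oncogene (up) therefore pushes proliferation
        # genes up and apoptosis genes down; a silenced suppressor (down)
        # pulls proliferation down and apoptosis up.
        deviation = tumor_expr - cfg.base_expr
        for process in (GROWING, BLOCKING):
            sign = 1.0 if process == GROWING else -1.0
            for t in range(cfg.n_targets_per_process):
                tname = f"{gene}_{process[:3].upper()}{t}"
                tumor_t = (cfg.base_expr
                           + sign * cfg.coupling * deviation
                           + rng.normal(0.0, cfg.noise_sd, cfg.n_tumor))
                expr_rows[tname] = np.concatenate([base_expr(cfg.n_normal), tumor_t])
                sig_entries[process][tname] = "increase"
                truth_rows.append(dict(gene_symbol=tname, role="",
                                       meth_state="None", is_driver=False,
                                       category="target"))

    for process, prefix in ((GROWING, "SIGP"), (BLOCKING, "SIGA")):
        for i in range(cfg.n_decoy_signature):
            gene = f"{prefix}{i:02d}"
            expr_rows[gene] = base_expr(len(samples))
            sig_entries[process][gene] = "increase"
            truth_rows.append(dict(gene_symbol=gene, role="", meth_state="None",
                                   is_driver=False, category="signature_decoy"))

    for gene in nulls:
        expr_rows[gene] = base_expr(len(samples))
        truth_rows.append(dict(gene_symbol=gene, role="", meth_state="None",
                               is_driver=False, category="null"))

    genes = sorted(expr_rows)
    expression = pd.DataFrame([expr_rows[g] for g in genes], index=genes,
                              columns=samples)
    expression.index.name = "gene_symbol"

    # methylation: every gene gets n_probes_per_gene promoter probes
    meth_rows: dict[str, np.ndarray] = {}
    manifest_rows: list[dict] = []
    probe_no = 0
    driver_state = {g: "Hypo" for g in ocgs}
    driver_state.update({g: "Hyper" for g in tsgs})
    for gene in genes:
        for _ in range(cfg.n_probes_per_gene):
            probe = f"cg{probe_no:06d}"
            probe_no += 1
            if gene in driver_state:
                mu_n = cfg.driver_meth_mean
                mu_ab = (mu_n - cfg.delta_meth if driver_state[gene] == "Hypo"
                         else mu_n + cfg.delta_meth)
                abn = abnormal_sets[gene]
                tumor_b = np.where(abn, rbeta(mu_ab, cfg.n_tumor),
                                   rbeta(mu_n, cfg.n_tumor))
                vals = np.concatenate([rbeta(mu_n, cfg.n_normal), tumor_b])
            else:
                mu = rng.uniform(0.2, 0.8)
                vals = rbeta(mu, len(samples))
            meth_rows[probe] = vals
            manifest_rows.append(dict(probe_id=probe, gene_symbol=gene,
                                      chrom="chr1", start=probe_no * 1000,
                                      end=probe_no * 1000 + 2,
                                      region_class="promoter"))
    methylation = pd.DataFrame([meth_rows[p] for p in sorted(meth_rows)],
                               index=sorted(meth_rows), columns=samples)
    methylation.index.name = "probe_id"

    sheet = pd.DataFrame({
        "sample_id": samples,
        "group": ["normal"] * cfg.n_normal + ["tumor"] * cfg.n_tumor,
    })
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows).sort_values("gene_symbol").reset_index(drop=True)
    return SimulatedCohort(expression=expression, methylation=methylation,
                           sample_sheet=sheet, manifest=manifest,
                           signatures=SignatureSet(processes=sig_entries),
                           truth=truth, config=cfg)


def write_cohort(sim: SimulatedCohort, outdir) -> None:
    """Write every standard pipeline input plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(sim.expression, outdir / "expression.tsv", "gene_symbol")
    write_matrix(sim.methylation, outdir / "methylation.tsv", "probe_id")
    write_table(sim.sample_sheet, outdir / "samples.tsv")
    write_table(sim.manifest, outdir / "manifest.tsv")
    sig_rows = [(p, g, d) for p, gd in sorted(sim.signatures.processes.items())
                for g, d in sorted(gd.items())]
    write_table(pd.DataFrame(sig_rows, columns=["process", "gene", "direction"]),
                outdir / "signatures.tsv")
    write_table(sim.truth, outdir / "truth.tsv")
    import json
    (outdir / "sim_config.json").write_text(json.dumps(asdict(sim.config), indent=2))
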