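"""Benchmarking predicted gene sets against a reference driver census.

Precision = 100·TP/(TP+FP) and sensitivity = 100·TP/(TP+FN), where TP is
the overlap between the predicted set and the census, FP the predicted
genes absent from the census, and FN the census genes that were not
predicted.  Association with the census is additionally quantified by a
two-sided Fisher's exact test on the 2×2 table (predicted yes/no ×
census yes/no) over a stated gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd
from scipy import stats


@dataclass
class EvalReport:
    gene_set_name: str
    tp: int
    fp: int
    fn: int
    universe_size: int
    precision: float | None = None   # percent; None when tp+fp == 0
    sensitivity: float | None = None
    fisher_p: float | None = None
    odds_ratio: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_vs_census(genes: set[str], census: set[str], universe: set[str],
                        name: str = "gene_set") -> EvalReport:
    """Confusion counts of a predicted gene set against the census.

    The census is restricted to the universe before counting; the
    predicted genes must lie within the universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    genes = set(genes)
    if not genes <= universe:
        raise ValueError(f"{len(genes - universe)} predicted genes outside universe")
    census_u = set(census) & universe
    tp = len(genes & census_u)
    fp = len(genes - census_u)
    fn = len(census_u - genes)
    report = EvalReport(gene_set_name=name, tp=tp, fp=fp, fn=fn,
                        universe_size=len(universe))
    if tp + fp > 0:
        report.precision = 100.0 * tp / (tp + fp)
    if tp + fn > 0:
        report.sensitivity = 100.0 * tp / (tp + fn)
    return report


def fisher_association(report: EvalReport) -> EvalReport:
    """Two-sided Fisher's exact test of set-vs-census association.

    The 2×2 table is [[tp, fp], [fn, neither]] over the universe.  The
    odds ratio is the sample (a·d)/(b·c) with the Haldane–Anscombe +0.5
    correction applied to all cells when any cell is zero.
    """
    a, b, c = report.tp, report.fp, report.fn
    d = report.universe_size - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative contingency cell in [[{a},{b}],[{c},{d}]]")
    report.fisher_p = float(stats.fisher_exact([[a, b], [c, d]],
                                               alternative="two-sided")[1])
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    report.odds_ratio = (a * d) / (b * c)
    return report


def evaluate_gene_set(genes: set[str], census: set[str], universe: set[str],
                      name: str = "gene_set") -> EvalReport:
    """Confusion counts plus Fisher association in one call."""
    return fisher_association(confusion_vs_census(genes, census, universe, name))


def set_overlap(a: set[str], b: set[str]) -> tuple[int, int, int]:
    """Venn counts: (only in a, shared, only in b)."""
    a, b = set(a), set(b)
    return len(a - b), len(a & b), len(b - a)


def reports_to_frame(reports: list[EvalReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])
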