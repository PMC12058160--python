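"""Expression-based prediction of oncogenic mediators.

Three chained steps:

1. **GRN** — a mutual-information network around each differentially
   expressed gene (DEG), with edges kept only above a per-regulator
   permutation threshold.
2. **URA** — an upstream-regulator effect score: for each regulator and
   biological process, the concordance of its network targets' expression
   changes with the direction expected under process activation,
   ``z = sum(s_i) / sqrt(n)`` with s_i = ±1.
3. **PRA** — pattern recognition: a gene whose score pattern is
   (growing ≥ +t, blocking ≤ −t) is a putative oncogene; the mirrored
   pattern gives a putative tumor suppressor.

Mutual information is estimated on equal-frequency discretized expression
(B = max(2, floor(sqrt(n))) bins) over tumor samples, reflecting the
disease state in which drivers act.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlignedCohort, FormatError, _read_table

logger = logging.getLogger(__name__)

ROLE_OCG = "putative_OCG"
ROLE_TSG = "putative_TSG"

_ROLE_ALIASES = {
    "ocg": ROLE_OCG, "putative_ocg": ROLE_OCG, "oncogene": ROLE_OCG,
    "tsg": ROLE_TSG, "putative_tsg": ROLE_TSG, "tumor_suppressor": ROLE_TSG,
}

MEDIATOR_COLUMNS = ("gene_symbol", "putative_role", "z_growing", "z_blocking")


@dataclass
class Regulon:
    """A regulator gene and its network targets with MI edge weights."""

    regulator: str
    targets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets.pop(self.regulator, None)  # no self-target
        if any(w < 0 for w in self.targets.values()):
            raise ValueError("mi_weight must be nonnegative")


def equal_frequency_codes(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize each row into ``n_bins`` equal-frequency bins.

    Ranks are split evenly; a constant row lands entirely in bin 0, which
    makes its entropy (and any MI with it) exactly zero.
    """
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    if single:
        values = values[None, :]
    n = values.shape[1]
    order = np.argsort(values, axis=1, kind="stable")
    bins = (np.arange(n) * n_bins) // n
    codes = np.empty_like(values, dtype=np.int64)
    np.put_along_axis(codes, order, np.broadcast_to(bins, values.shape), axis=1)
    # collapse ties that straddle a bin boundary onto one bin so identical
    # values always share a code (keeps MI(X,X) maximal and well defined)
    sorted_vals = np.take_along_axis(values, order, axis=1)
    for i in range(values.shape[0]):
        sv = sorted_vals[i]
        sb = codes[i][order[i]]
        for j in range(1, n):
            if sv[j] == sv[j - 1] and sb[j] != sb[j - 1]:
                sb[j] = sb[j - 1]
        codes[i][order[i]] = sb
    return codes[0] if single else codes


def _entropy_from_counts(counts: np.ndarray, n: int, axis=None) -> np.ndarray:
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=axis)


def _mi_many_vs_many(r_codes: np.ndarray, target_codes: np.ndarray,
                     n_bins: int) -> np.ndarray:
    """MI (nats) between each of R code vectors and each of G code rows.

    One flattened bincount builds all R×G joint tables at once; returns
    an (R, G) matrix.
    """
    r_codes = np.atleast_2d(r_codes)
    R, n = r_codes.shape
    G = target_codes.shape[0]
    b2 = n_bins * n_bins
    flat = ((np.arange(R)[:, None, None] * G + np.arange(G)[None, :, None]) * b2
            + target_codes[None, :, :] * n_bins + r_codes[:, None, :])
    joint = np.bincount(flat.ravel(), minlength=R * G * b2).reshape(R, G,
                                                                    n_bins,
                                                                    n_bins)
    h_joint = _entropy_from_counts(joint, n, axis=(2, 3))
    h_r = _entropy_from_counts(joint.sum(axis=2), n, axis=2)   # (R, G) = H(r)
    h_t = _entropy_from_counts(joint.sum(axis=3), n, axis=2)   # (R, G) = H(t)
    return np.maximum(h_r + h_t - h_joint, 0.0)


def _mi_one_vs_many(r_codes: np.ndarray, target_codes: np.ndarray,
                    n_bins: int) -> np.ndarray:
    """MI (nats) between one code vector and each row of a code matrix."""
    return _mi_many_vs_many(r_codes[None, :], target_codes, n_bins)[0]


def mutual_information(x: np.ndarray, y: np.ndarray,
                       n_bins: int | None = None) -> float:
    """Pairwise MI under shared equal-frequency discretization."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if n_bins is None:
        n_bins = max(2, int(np.sqrt(len(x))))
    cx = equal_frequency_codes(x, n_bins)
    cy = equal_frequency_codes(y, n_bins)
    return float(_mi_one_vs_many(cx, cy[None, :], n_bins)[0])


def build_grn(expr: pd.DataFrame, degs: pd.DataFrame, cohort: AlignedCohort,
              n_perm: int = 100, alpha: float = 0.05, seed: int = 0,
              tumor_only: bool = True) -> list[Regulon]:
    """Mutual-information regulons for every DEG regulator.

    Per regulator, the edge threshold is the (1 − alpha) quantile of the
    null MI distribution obtained from ``n_perm`` seeded permutations of
    the regulator's values against all candidate targets; edges at or
    below the threshold are dropped.
    """
    samples = list(cohort.tumor) if tumor_only else list(cohort.samples)
    if len(samples) < 8:
        raise ValueError(f"build_grn needs ≥8 samples, got {len(samples)}")
    mat = expr.loc[:, samples].to_numpy(dtype=float)
    mat = np.where(np.isfinite(mat), mat, np.nanmean(mat))  # rare missing → grand mean
    genes = list(expr.index)
    n = len(samples)
    n_bins = max(2, int(np.sqrt(n)))
    codes = equal_frequency_codes(mat, n_bins)
    gene_pos = {g: i for i, g in enumerate(genes)}
    regulators = [g for g, flag in zip(degs["gene_symbol"], degs["is_deg"])
                  if flag and g in gene_pos]
    rng = np.random.default_rng(seed)
    regulons: list[Regulon] = []
    for reg in regulators:
        ri = gene_pos[reg]
        r_codes = codes[ri]
        mi = _mi_one_vs_many(r_codes, codes, n_bins)
        perms = np.array([r_codes[rng.permutation(n)] for _ in range(n_perm)])
        null = _mi_many_vs_many(perms, codes, n_bins)
        thr = float(np.quantile(null.ravel(), 1.0 - alpha))
        targets = {g: float(mi[j]) for j, g in enumerate(genes)
                   if j != ri and mi[j] > thr}
        regulons.append(Regulon(regulator=reg, targets=targets))
    return regulons


def run_ura(regulons: list[Regulon], degs: pd.DataFrame,
            sigs) -> pd.DataFrame:
    """Effect scores of each regulator on each signature process.

    For regulator g and process P, over targets i in regulon(g) ∩
    signature(P): s_i = +1 when the sign of the target's log2FC matches
    the direction expected under process activation, −1 otherwise;
    z = Σ s_i / sqrt(|intersection|), 0 when empty.
    """
    lfc = dict(zip(degs["gene_symbol"], degs["log2fc"]))
    processes = sigs.process_names
    rows = {}
    n_skipped = 0
    for reg in regulons:
        z_row = {}
        for proc in processes:
            sig = sigs.genes(proc)
            scores = []
            for target in reg.targets:
                if target not in sig:
                    continue
                if target not in lfc:
                    n_skipped += 1
                    continue
                observed = "increase" if lfc[target] > 0 else "decrease"
                scores.append(1.0 if observed == sig[target] else -1.0)
            z_row[proc] = (sum(scores) / np.sqrt(len(scores))) if scores else 0.0
        rows[reg.regulator] = z_row
    if n_skipped:
        logger.info("run_ura: skipped %d target hits absent from the DEG table",
                    n_skipped)
    ura = pd.DataFrame.from_dict(rows, orient="index", columns=processes)
    ura.index.name = "gene_symbol"
    return ura


def run_pra(ura: pd.DataFrame, growing: str, blocking: str,
            t: float = 1.0) -> pd.DataFrame:
    """Classify regulators into putative oncogenes / tumor suppressors.

    A putative OCG activates the cancer-growing process and represses the
    cancer-blocking one (z_growing ≥ +t and z_blocking ≤ −t); a putative
    TSG shows the mirrored pattern.  Everything else is not a mediator.
    """
    for proc in (growing, blocking):
        if proc not in ura.columns:
            raise KeyError(f"process {proc!r} not in URA matrix")
    zg = ura[growing]
    zb = ura[blocking]
    is_ocg = (zg >= t) & (zb <= -t)
    is_tsg = (zg <= -t) & (zb >= t)
    out = pd.DataFrame({
        "gene_symbol": ura.index,
        "putative_role": np.where(is_ocg, ROLE_OCG,
                                  np.where(is_tsg, ROLE_TSG, "")),
        "z_growing": zg.to_numpy(),
        "z_blocking": zb.to_numpy(),
    })
    out = out[out["putative_role"] != ""].reset_index(drop=True)
    return out


def load_pra(path) -> pd.DataFrame:
    """Load an externally produced mediator table (gene, role).

    Role accepts case-insensitive aliases TSG/OCG; anything else is an
    error.  An empty file yields an empty table with a warning.
    """
    try:
        df = _read_table(path)
    except FormatError:
        logger.warning("%s: empty mediator table", path)
        return pd.DataFrame(columns=list(MEDIATOR_COLUMNS))
    df = df.rename(columns={"gene": "gene_symbol", "role": "putative_role"})
    if not {"gene_symbol", "putative_role"}.issubset(df.columns):
        raise FormatError(f"{path}: mediator table needs gene and role columns")
    if df.empty:
        logger.warning("%s: empty mediator table", path)
        return pd.DataFrame(columns=list(MEDIATOR_COLUMNS))
    roles = df["putative_role"].astype(str).str.strip().str.lower()
    unknown = sorted(set(roles) - set(_ROLE_ALIASES))
    if unknown:
        raise FormatError(f"{path}: unknown putative roles {unknown}")
    out = pd.DataFrame({
        "gene_symbol": df["gene_symbol"].astype(str),
        "putative_role": [_ROLE_ALIASES[r] for r in roles],
        "z_growing": df.get("z_growing", np.nan),
        "z_blocking": df.get("z_blocking", np.nan),
    })
    if out["gene_symbol"].duplicated().any():
        raise FormatError(f"{path}: duplicate genes in mediator table")
    return out


def regulons_to_frame(regulons: list[Regulon]) -> pd.DataFrame:
    rows = [(r.regulator, t, w) for r in regulons
            for t, w in sorted(r.targets.items())]
    return pd.DataFrame(rows, columns=["regulator", "target", "mi"])
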