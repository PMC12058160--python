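"""Readers, writers and validation for every table the pipeline touches.

All matrices are tab-separated with the feature identifier in the first
column and sample identifiers in the header row.  Readers tolerate gzip
(by file extension).  Downstream stages only ever see validated,
deterministically ordered structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: beta values are clamped into [BETA_EPS, 1 - BETA_EPS] on read — the beta
#: likelihood is undefined at exactly 0 or 1; clamping keeps the sample count.
BETA_EPS = 1e-3

VALID_GROUPS = frozenset({"tumor", "normal"})
VALID_REGIONS = frozenset({"promoter", "other"})
VALID_DIRECTIONS = frozenset({"increase", "decrease"})


class FormatError(ValueError):
    """A file is malformed or violates a table contract."""


class CohortError(ValueError):
    """The tumor/normal cohort is unusable (too small, disjoint, ...)."""


@dataclass(frozen=True)
class AlignedCohort:
    """Sample intersection of expression, methylation and the sample sheet.

    Orders are lexicographic so every downstream seeded computation is
    reproducible regardless of input file row order.
    """

    samples: tuple[str, ...]
    tumor: tuple[str, ...]
    normal: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.tumor) & set(self.normal):
            raise CohortError("tumor and normal sample sets overlap")


@dataclass(frozen=True)
class SignatureSet:
    """Biological-process signatures: gene lists with the direction each
    gene is expected to move when the process is activated."""

    processes: dict[str, dict[str, str]] = field(default_factory=dict)

    def genes(self, process: str) -> dict[str, str]:
        return self.processes[process]

    @property
    def process_names(self) -> list[str]:
        return sorted(self.processes)


def _read_table(path, **kw) -> pd.DataFrame:
    # pandas infers gzip from the .gz suffix
    try:
        df = pd.read_csv(path, sep="\t", **kw)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    return df


def _check_matrix_layout(df: pd.DataFrame, path, kind: str) -> None:
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no sample columns in {kind} matrix")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dup}")
    non_numeric = [c for c in df.columns
                   if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise FormatError(
            f"{path}: non-numeric sample columns {non_numeric} — malformed header?")


def read_expression(path) -> pd.DataFrame:
    """Read a genes × samples log2-expression matrix.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean expression (logged); an all-duplicate id set is fatal.
    """
    df = _read_table(path, index_col=0)
    df.index = df.index.astype(str)
    _check_matrix_layout(df, path, "expression")
    if df.index.duplicated().any():
        n_unique = df.index.nunique()
        if n_unique == 1 and len(df) > 1:
            raise FormatError(f"{path}: all gene ids are duplicates of one id")
        means = df.mean(axis=1, skipna=True)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        n_before = len(df)
        df = df[~df.index.duplicated(keep="first")]
        logger.warning("%s: collapsed %d duplicate gene rows (kept max-mean row)",
                       path, n_before - len(df))
        df = df.sort_index()
    vals = df.to_numpy(dtype=float)
    if np.isinf(vals).any():
        raise FormatError(f"{path}: infinite expression values")
    if np.all(np.isnan(vals)):
        raise FormatError(f"{path}: matrix contains no data")
    return df


def read_methylation(path) -> pd.DataFrame:
    """Read a probes × samples beta-value matrix.

    Values outside [-0.01, 1.01] are fatal (wrong scale — likely M-values);
    in-range values are clamped into [1e-3, 1-1e-3] for mixture fitting.
    """
    df = _read_table(path, index_col=0)
    df.index = df.index.astype(str)
    _check_matrix_layout(df, path, "methylation")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate probe ids")
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < -0.01 or finite.max() > 1.01):
        raise FormatError(
            f"{path}: beta values outside [-0.01, 1.01] "
            f"(range {finite.min():.3g}..{finite.max():.3g}) — wrong scale, likely M-values")
    clamped = np.clip(vals, BETA_EPS, 1.0 - BETA_EPS)
    n_clamped = int(np.sum((vals != clamped) & np.isfinite(vals)))
    if n_clamped:
        logger.info("%s: clamped %d beta values into [%g, %g]",
                    path, n_clamped, BETA_EPS, 1 - BETA_EPS)
    return pd.DataFrame(clamped, index=df.index, columns=df.columns)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet (columns ``sample_id``, ``group``)."""
    df = _read_table(path)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample sheet needs columns {sorted(required)}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["group"] = df["group"].astype(str).str.lower()
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in sheet")
    bad = set(df["group"]) - VALID_GROUPS
    if bad:
        raise FormatError(f"{path}: unknown sample groups {sorted(bad)}")
    return df[["sample_id", "group"]]


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest (probe → gene, coordinates, region class).

    Accepts either a TSV with columns probe_id, gene_symbol, chrom, start,
    end, region_class, or a 6-column BED whose name field encodes
    ``probe_id|gene_symbol[|region_class]`` (BED has no native columns for
    the gene symbol or region class).  One row per probe-gene pair; probes
    mapping to several genes simply repeat.
    """
    head = _read_table(path, nrows=1)
    if "probe_id" in head.columns:
        df = _read_table(path)
        required = {"probe_id", "gene_symbol", "chrom", "start", "end", "region_class"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
        df = df[["probe_id", "gene_symbol", "chrom", "start", "end", "region_class"]].copy()
    else:
        bed = _read_table(path, header=None)
        if bed.shape[1] < 4:
            raise FormatError(f"{path}: BED manifest needs ≥4 columns")
        names = bed.iloc[:, 3].astype(str).str.split("|")
        if (names.str.len() < 2).any():
            raise FormatError(
                f"{path}: BED name field must be 'probe_id|gene_symbol[|region_class]'")
        df = pd.DataFrame({
            "probe_id": names.str[0],
            "gene_symbol": names.str[1],
            "chrom": bed.iloc[:, 0].astype(str),
            "start": bed.iloc[:, 1],
            "end": bed.iloc[:, 2],
            "region_class": names.apply(lambda p: p[2] if len(p) > 2 else "other"),
        })
    df["probe_id"] = df["probe_id"].astype(str)
    df["gene_symbol"] = df["gene_symbol"].astype(str)
    df["region_class"] = df["region_class"].astype(str).str.lower()
    bad = set(df["region_class"]) - VALID_REGIONS
    if bad:
        raise FormatError(f"{path}: unknown region classes {sorted(bad)}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] < 0).any() or (df["end"] < df["start"]).any():
        raise FormatError(f"{path}: invalid coordinates (0-based half-open expected)")
    if df.duplicated(["probe_id", "gene_symbol"]).any():
        raise FormatError(f"{path}: duplicate probe-gene pairs")
    return df.reset_index(drop=True)


def read_signatures(path) -> SignatureSet:
    """Read process signatures (columns ``process``, ``gene``, ``direction``)."""
    df = _read_table(path)
    required = {"process", "gene", "direction"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: signatures need columns {sorted(required)}")
    df["direction"] = df["direction"].astype(str).str.lower()
    bad = set(df["direction"]) - VALID_DIRECTIONS
    if bad:
        raise FormatError(f"{path}: unknown directions {sorted(bad)}")
    if df.duplicated(["process", "gene"]).any():
        raise FormatError(f"{path}: duplicate gene within a process")
    processes: dict[str, dict[str, str]] = {}
    for proc, sub in df.groupby("process"):
        processes[str(proc)] = dict(zip(sub["gene"].astype(str), sub["direction"]))
    return SignatureSet(processes=processes)


def read_census(path) -> set[str]:
    """Read a reference driver-gene census: one symbol per line."""
    genes: set[str] = set()
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.add(sym)
    return genes


def align_cohort(expr: pd.DataFrame, meth: pd.DataFrame, sheet: pd.DataFrame,
                 min_tumor: int = 5, min_normal: int = 5) -> AlignedCohort:
    """Intersect the three sample universes and partition tumor/normal.

    Fatal when the intersection leaves fewer than ``min_tumor`` tumor or
    ``min_normal`` normal samples.
    """
    shared = set(expr.columns) & set(meth.columns) & set(sheet["sample_id"])
    group = dict(zip(sheet["sample_id"], sheet["group"]))
    tumor = tuple(sorted(s for s in shared if group[s] == "tumor"))
    normal = tuple(sorted(s for s in shared if group[s] == "normal"))
    if len(tumor) < min_tumor or len(normal) < min_normal:
        raise CohortError(
            f"cohort too small after intersection: {len(tumor)} tumor "
            f"(need ≥{min_tumor}), {len(normal)} normal (need ≥{min_normal})")
    return AlignedCohort(samples=tuple(sorted(shared)), tumor=tumor, normal=normal)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    """Write a feature × sample matrix; round-trips values exactly."""
    df.to_csv(path, sep="\t", index_label=index_label)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
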