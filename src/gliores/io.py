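"""Validated containers and readers/writers for every external format the pipeline touches.

All tabular formats are plain text: TSV/CSV (UTF-8, "." decimal, mandatory header),
MatrixMarket triplets with one-id-per-line sidecars, BED-like gene position tables
(0-based half-open), and a JSON report. Floats round-trip at 15 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__

logger = logging.getLogger(__name__)

SCALE_TAGS = ("counts", "lognorm")
FLOAT_FMT = "%.15g"


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x samples (or genes x cells) nonnegative expression grid.

    ``scale`` records whether values are raw counts or log-normalized
    (per-sample library-size scaling followed by log2(x + 1)).
    """

    data: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in SCALE_TAGS:
            raise ValueError(f"scale must be one of {SCALE_TAGS}, got {self.scale!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        if (vals < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_lognorm(self, target_sum: float = 1e4) -> "ExpressionMatrix":
        """Scale each sample to ``target_sum`` total, then log2(x + 1).

        Already log-normalized matrices are returned unchanged.
        """
        if self.scale == "lognorm":
            return self
        totals = self.data.sum(axis=0)
        totals = totals.replace(0, 1.0)
        scaled = self.data / totals * target_sum
        return ExpressionMatrix(np.log2(scaled + 1.0), scale="lognorm")


def read_expression(path: str | Path, format: str | None = None,
                    scale: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix from TSV or MatrixMarket triplet format.

    TSV: genes in rows (first column = gene id header), samples in columns.
    MTX: ``<stem>.mtx`` with sidecars ``<stem>.genes.txt`` and ``<stem>.cells.txt``
    holding one id per line (rows and columns respectively).
    """
    path = Path(path)
    if format is None:
        format = "mtx_triplet" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.columns.size == 0:
            raise ValueError(f"malformed header in {path}")
        return ExpressionMatrix(df, scale=scale)
    if format == "mtx_triplet":
        mat = spio.mmread(path)
        genes = _read_id_sidecar(path.with_suffix(".genes.txt"))
        cells = _read_id_sidecar(path.with_suffix(".cells.txt"))
        mat = sparse.coo_matrix(mat).toarray()
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)")
        df = pd.DataFrame(mat, index=genes, columns=cells)
        return ExpressionMatrix(df, scale=scale)
    raise ValueError(f"unknown format {format!r}")


def _read_id_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing id sidecar {path}")
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate ids in {path}")
    return ids


def write_expression(em: ExpressionMatrix, path: str | Path,
                     format: str | None = None) -> Path:
    path = Path(path)
    if format is None:
        format = "mtx_triplet" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        df = em.data.copy()
        df.index.name = df.index.name or "gene"
        df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    elif format == "mtx_triplet":
        spio.mmwrite(str(path), sparse.coo_matrix(em.data.to_numpy()))
        path.with_suffix(".genes.txt").write_text("\n".join(map(str, em.genes)) + "\n")
        path.with_suffix(".cells.txt").write_text("\n".join(map(str, em.samples)) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Gene positions (BED-like, 0-based half-open)
# ---------------------------------------------------------------------------

POSITION_COLUMNS = ["chrom", "start", "end", "gene"]


def validate_positions(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort a (chrom, start, end, gene) table by (chrom, start)."""
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"position table missing columns {missing}")
    df = df[POSITION_COLUMNS].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene"].tolist()
        raise ValueError(f"start >= end for genes {bad[:5]} (0-based half-open expected)")
    if df["gene"].duplicated().any():
        bad = df.loc[df["gene"].duplicated(), "gene"].unique().tolist()
        raise ValueError(f"duplicate genes in position table: {bad[:5]}")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df


def read_positions(path: str | Path, chrom_convention: str | None = None) -> pd.DataFrame:
    """Read a 4+ column BED-like TSV (chrom, start, end, gene).

    ``chrom_convention`` normalizes chromosome naming: "chr" prefixes bare
    labels ("7" -> "chr7"), "" strips a "chr" prefix, None leaves labels as-is.
    """
    df = pd.read_csv(path, sep="\t", header=0)
    df = validate_positions(df)
    if chrom_convention == "chr":
        df["chrom"] = [c if str(c).startswith("chr") else f"chr{c}" for c in df["chrom"]]
    elif chrom_convention == "":
        df["chrom"] = [str(c)[3:] if str(c).startswith("chr") else str(c) for c in df["chrom"]]
    return validate_positions(df)


def write_positions(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_positions(df).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Dose-response matrices
# ---------------------------------------------------------------------------

def read_dose_matrix(path: str | Path):
    """Read a CSV inhibition grid: first column = agent-A doses, header = agent-B doses.

    Both dose axes must include 0; axes are reordered ascending on ingest.
    Entries are clamped to [0, 100] for analysis with the raw grid preserved.
    """
    from .pharm import DoseResponseMatrix

    df = pd.read_csv(path, index_col=0)
    try:
        doses_a = df.index.to_numpy(dtype=float)
        doses_b = df.columns.to_numpy(dtype=float)
        grid = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"nonnumeric cells or dose labels in {path}: {exc}") from exc
    order_a = np.argsort(doses_a)
    order_b = np.argsort(doses_b)
    return DoseResponseMatrix(doses_a[order_a], doses_b[order_b],
                              grid[np.ix_(order_a, order_b)])


def write_dose_matrix(matrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(matrix.raw, index=matrix.doses_a, columns=matrix.doses_b)
    df.index.name = "dose_a"
    df.to_csv(path, float_format=FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in items]
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(map(str, obj.columns)),
                "index": list(map(str, obj.index)),
                "values": _jsonable(obj.to_numpy().tolist())}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(results: dict, outdir: str | Path, config: dict | None = None,
                 seed: int | None = None) -> Path:
    """Write per-stage TSV tables plus a single JSON summary.

    DataFrame-valued entries are written as ``<stage>.tsv``; everything is also
    embedded in ``report.json`` together with the package version, the config
    hash and the master seed, so a report is reproducible from its own header.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, value in results.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(outdir / f"{name}.tsv", sep="\t", float_format=FLOAT_FMT)
    summary = {
        "pipeline_version": __version__,
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "config": _jsonable(config or {}),
        "results": _jsonable(results),
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    return report_path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
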