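"""Plain-text readers/writers for the pipeline's on-disk formats.

BED6 (0-based half-open) for reads and regions, TSV for gene annotation and
tables, CSV for count matrices and FRAP traces.  Every writer can prepend a
provenance header of ``#``-prefixed comment lines.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .frap import FrapCurve

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def file_sha256(path: str | Path, n_hex: int = 12) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:n_hex]


def provenance_header(
    stage: str, seed: int | None = None, params: dict | None = None,
    inputs: dict[str, str] | None = None,
) -> list[str]:
    """Comment lines recording tool version, stage, seed, params, checksums."""
    lines = [f"# promdyn v{__version__} stage={stage}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if params:
        kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"# params: {kv}")
    for name, digest in (inputs or {}).items():
        lines.append(f"# input {name} sha256={digest}")
    return lines


def _write_with_header(
    text: str, path: str | Path, header: list[str] | None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(line.rstrip("\n") + "\n")
        fh.write(text)


def write_tsv(
    df: pd.DataFrame, path: str | Path, header: list[str] | None = None,
    index: bool = False,
) -> None:
    _write_with_header(df.to_csv(sep="\t", index=index), path, header)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_csv_matrix(
    df: pd.DataFrame, path: str | Path, header: list[str] | None = None
) -> None:
    _write_with_header(df.to_csv(), path, header)


def read_csv_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def write_bed6(
    df: pd.DataFrame, path: str | Path, header: list[str] | None = None
) -> None:
    """Write a BED6(+extra) frame without column names, tab-separated."""
    _write_with_header(df.to_csv(sep="\t", index=False, header=False), path, header)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    ncol = df.shape[1]
    names = BED6_COLUMNS[:ncol] + [f"extra{i}" for i in range(max(0, ncol - 6))]
    df.columns = names[:ncol]
    return df


def write_frap_csv(
    curves: list[FrapCurve], path: str | Path, header: list[str] | None = None
) -> None:
    """Column 1 time_s, one column per cell; bleach frame in a comment line."""
    if not curves:
        raise ValueError("no curves to write")
    bleach = curves[0].bleach_index
    times = curves[0].times
    for c in curves:
        if c.bleach_index != bleach or not np.allclose(c.times, times):
            raise ValueError("curves must share a time grid and bleach frame")
    df = pd.DataFrame({"time_s": times})
    for c in curves:
        df[c.cell_id or f"cell{len(df.columns)}"] = c.intensities
    lines = list(header or []) + [f"#bleach_frame={bleach}"]
    _write_with_header(df.to_csv(index=False), path, lines)


def read_frap_csv(path: str | Path) -> list[FrapCurve]:
    bleach = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#bleach_frame="):
                bleach = int(line.strip().split("=", 1)[1])
            elif not line.startswith("#"):
                break
    if bleach is None:
        raise ValueError("missing #bleach_frame= header line")
    df = pd.read_csv(path, comment="#")
    times = df["time_s"].to_numpy(dtype=float)
    return [
        FrapCurve(times=times.copy(), intensities=df[c].to_numpy(dtype=float),
                  bleach_index=bleach, cell_id=str(c))
        for c in df.columns
        if c != "time_s"
    ]
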