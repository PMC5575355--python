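"""Reading and writing matrices, orderings, traces and run manifests.

Matrices travel as TSV/CSV with bin identifiers in the first row and
sample identifiers in the first column.  Numbers are serialized with 17
significant digits so a write/read round trip reproduces every value
bit-exactly; identifiers are opaque strings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ReadDepthMatrix, SampleOrdering
from .errors import InvalidInputError
from .solver import TCPResult

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_result",
    "read_ordering",
    "write_labels",
    "read_labels",
]

_FLOAT_FMT = "%.17g"


def _sep(fmt: str) -> str:
    if fmt not in ("tsv", "csv"):
        raise InvalidInputError(f"unknown format {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "tsv"


def read_matrix(
    path: str | Path, fmt: str | None = None, transpose: bool = False
) -> ReadDepthMatrix:
    """Parse a samples-by-bins matrix file.

    First row holds bin identifiers, first column sample identifiers
    (``transpose=True`` for bins-in-rows files).  Ragged rows, non-numeric
    cells and duplicate identifiers are rejected with the offending
    coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    sep = _sep(_infer_format(path, fmt))
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise InvalidInputError(f"{path}: ragged or malformed table: {exc}") from exc
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise InvalidInputError(f"{path}: duplicate sample ids {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise InvalidInputError(f"{path}: duplicate bin ids {dupes}")
    values = np.empty(df.shape)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise InvalidInputError(
                    f"{path}: non-numeric cell {raw[i, j]!r} at sample "
                    f"{df.index[i]!r}, bin {df.columns[j]!r}"
                ) from None
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise InvalidInputError(
            f"{path}: non-finite cell at sample {df.index[i]!r}, bin {df.columns[j]!r}"
        )
    return ReadDepthMatrix(values, list(df.index), list(df.columns))


def write_matrix(B: ReadDepthMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    sep = _sep(_infer_format(path, fmt))
    df = pd.DataFrame(B.values, index=B.sample_ids, columns=B.bin_ids)
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def write_labels(labels, sample_ids, path: str | Path) -> None:
    pd.DataFrame({"sample": sample_ids, "label": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path, sample_ids: list[str] | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns or "label" not in df.columns:
        raise InvalidInputError(f"{path}: expected columns 'sample' and 'label'")
    if sample_ids is not None:
        lookup = dict(zip(df["sample"], df["label"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise InvalidInputError(f"{path}: no label for samples {missing[:5]}")
        return np.asarray([lookup[s] for s in sample_ids])
    return df["label"].to_numpy()


def read_ordering(path: str | Path) -> SampleOrdering:
    df = pd.read_csv(path, sep="\t")
    if "source_index" not in df.columns:
        raise InvalidInputError(f"{path}: expected a 'source_index' column")
    return SampleOrdering(df["source_index"].to_numpy())


def write_result(
    result: TCPResult,
    output_dir: str | Path,
    config_record: dict | None = None,
) -> dict[str, Path]:
    """Write the four standard outputs of a solver run.

    recovered.tsv (denoised matrix, rows in final order), ordering.tsv
    (position -> original sample), trace.csv (per-iteration records) and
    manifest.json (config, convergence flag, versions).
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "recovered": output_dir / "recovered.tsv",
        "ordering": output_dir / "ordering.tsv",
        "trace": output_dir / "trace.csv",
        "manifest": output_dir / "manifest.json",
    }
    write_matrix(result.recovered, paths["recovered"])
    order = result.state.ordering.order
    pd.DataFrame(
        {
            "position": np.arange(order.size),
            "source_index": order,
            "sample": result.recovered.sample_ids,
        }
    ).to_csv(paths["ordering"], sep="\t", index=False)
    pd.DataFrame(result.trace).to_csv(paths["trace"], index=False)
    manifest = {
        "converged": bool(result.converged),
        "iterations": int(result.state.iteration),
        "final_objective": float(result.state.objective_history[-1]),
        "config": config_record or {},
        "versions": _versions(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths


def _versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "tcperm": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
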