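"""Tab-delimited readers/writers, gene-set files, and the run manifest.

The interchange format is plain TSV: first column holds gene/protein
identifiers, remaining column headers carry the design as
``condition:time[:replicate]`` sample identifiers (four-pool fraction
files instead use ``pool1..pool4`` columns, with the condition and
replicate encoded in the file name or passed explicitly).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "write_manifest",
]

LAYERS = ("fractions", "mrna", "counts")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_matrix(path, layer: str = "mrna") -> pd.DataFrame:
    """Read a tab-delimited matrix with typed sample headers.

    ``layer`` selects the header contract: ``fractions`` expects the
    four ``pool1..pool4`` columns; ``mrna`` expects
    ``condition:time`` (replicate optional); ``counts`` expects
    ``condition:time:replicate``. Duplicate identifiers and non-numeric
    cells are rejected with the line number.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty and len(df.columns) == 0:
        raise ParseError(f"{path}: no data columns in header")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = list(df.index).index(dup) + 3  # header + first occurrence
        raise ParseError(f"{path}:{line}: duplicate identifier {dup!r}")
    _check_header(path, df.columns, layer)
    try:
        out = df.astype(float)
    except ValueError:
        for i, (_, row) in enumerate(df.iterrows(), start=2):
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}:{i}: non-numeric value {cell!r} in column {col!r}"
                    ) from None
        raise
    if out.empty:
        warnings.warn(f"{path}: empty data section")
    out.index.name = df.index.name or "id"
    return out


def _check_header(path, columns, layer: str) -> None:
    if layer == "fractions":
        expected = [f"pool{k}" for k in range(1, 5)]
        if list(columns) != expected:
            raise ParseError(f"{path}:1: fraction header must be {expected}")
        return
    want = 2 if layer == "mrna" else 3
    for col in columns:
        parts = str(col).split(":")
        if len(parts) < want or len(parts) > 3:
            raise ParseError(
                f"{path}:1: malformed sample id {col!r} "
                f"(expected condition:time{':replicate' if want == 3 else '[:replicate]'})"
            )
        try:
            float(parts[1])
        except ValueError:
            raise ParseError(f"{path}:1: non-numeric time in sample id {col!r}") from None
        if len(parts) == 3:
            try:
                int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}:1: non-integer replicate in sample id {col!r}"
                ) from None


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix as TSV, full float precision, preserving order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_sets(path) -> dict[str, set]:
    """Read gene sets: one per line, ``name<TAB>gene1,gene2,...``."""
    sets: dict[str, set] = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{i}: expected 'name<TAB>comma-separated genes'")
        name, members = parts
        if name in sets:
            raise ParseError(f"{path}:{i}: duplicate set name {name!r}")
        sets[name] = {g for g in members.split(",") if g}
    return sets


def write_gene_sets(sets: dict[str, set], path) -> None:
    lines = [f"{name}\t{','.join(sorted(genes))}" for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir, config: dict, inputs: list, outputs: list) -> Path:
    """Write a JSON run manifest: config, seed, input checksums, outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
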