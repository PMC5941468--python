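"""Delimited-text readers/writers for matrices, sample sheets and gene sets.

Matrices are stored probes-x-samples on disk (array convention) and
samples-x-probes in memory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd


def read_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a probes-x-samples matrix; returns samples x probes."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.T


def write_matrix(matrix: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a samples-x-probes matrix as probes x samples."""
    matrix.T.to_csv(path, sep=sep)


def read_sample_sheet(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0)


def read_table(path: str | Path, sep: str = "\t", index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_gene_set(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from one-gene-per-line text or GMT-style lines.

    GMT lines are ``name<tab>description<tab>gene1<tab>gene2...``; a file
    without tabs is treated as a single unnamed one-per-line set.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if any("\t" in ln for ln in lines):
        sets = {}
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {ln[:60]!r}")
            sets[parts[0]] = parts[2:]
        return sets
    return {path.stem: lines}


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_probe_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
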