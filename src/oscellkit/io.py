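"""Readers and writers for the standard interchange formats.

10x-style MTX triplets (MatrixMarket coordinate matrix + barcodes/features
TSVs, optionally gzipped), GMT gene-set files, CNV state TSVs, and generic
TSV/CSV tables.  On-disk MTX is features x barcodes with 1-based indices per
the MatrixMarket standard; in memory everything is 0-based cells x genes.
TSV outputs carry a leading '#' provenance comment (stage + parameter hash)
which all readers skip.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .synthetic import GeneSet


def params_hash(params: dict) -> str:
    payload = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance_line(stage: str, params: dict | None) -> str:
    h = params_hash(params or {})
    return f"# oscellkit stage={stage} params={h}\n"


def _open_maybe_gz(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}(.gz) not found in {dirpath}")


def read_mtx_triplet(dirpath) -> tuple[sp.csr_matrix, list[str], pd.DataFrame]:
    """Read a 10x MTX triplet; returns (cells x genes CSR, barcodes, features)."""
    dirpath = Path(dirpath)
    mtx_path = _find(dirpath, "matrix.mtx")
    with _open_maybe_gz(mtx_path, "rb") as fh:
        matrix = mmread(fh)
    matrix = sp.csr_matrix(matrix)
    with _open_maybe_gz(_find(dirpath, "barcodes.tsv")) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(_find(dirpath, "features.tsv")) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    features = pd.DataFrame(
        [(r[0], r[1] if len(r) > 1 else r[0]) for r in feat_rows],
        columns=["gene_id", "gene_name"])
    if matrix.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix is {matrix.shape} but triplet declares "
            f"{len(features)} features x {len(barcodes)} barcodes")
    return matrix.T.tocsr(), barcodes, features


def write_mtx_triplet(dirpath, counts, barcodes, features) -> None:
    """Write a plain-text 10x MTX triplet (features x barcodes on disk)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    matrix = sp.csr_matrix(counts).T.tocoo()
    mmwrite(str(dirpath / "matrix.mtx"), matrix, field="integer")
    with open(dirpath / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{b}\n" for b in barcodes)
    if isinstance(features, pd.DataFrame):
        rows = zip(features["gene_id"], features["gene_name"])
    else:
        rows = ((g, g) for g in features)
    with open(dirpath / "features.tsv", "w") as fh:
        fh.writelines(f"{gid}\t{name}\tGene Expression\n" for gid, name in rows)


def read_gmt(path) -> list[GeneSet]:
    """Read GMT: one set per line (name, description, members...)."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with _open_maybe_gz(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, description, *members = fields
            if name in names:
                raise ValueError(f"duplicate gene set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name, tuple(members), description))
    return sets


def write_gmt(path, sets: list[GeneSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def write_table(
    df: pd.DataFrame, path, stage: str, params: dict | None = None,
    index: bool = True,
) -> None:
    """Write a TSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_line(stage, params))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata table with a sniffed delimiter (CSV or TSV)."""
    return pd.read_csv(path, sep=None, engine="python", comment="#",
                       index_col=0)


def write_json(payload: dict, path, stage: str, params: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = dict(payload)
    body["_provenance"] = {"stage": stage, "params": params_hash(params or {})}
    with open(path, "w") as fh:
        json.dump(body, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def read_cnv_states(path) -> pd.DataFrame:
    """Read a CNV state TSV (first column cell id, header of gene ids)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def hash_outputs(paths, root) -> dict[str, str]:
    out = {}
    for p in paths:
        rel = os.path.relpath(p, root)
        out[rel] = file_sha256(p)
    return out
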