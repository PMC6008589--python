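"""Delimited-text readers and writers for phenotypes, genotypes, kinship
matrices and pedigrees, plus the reproducibility manifest."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .relmat import GenotypeMatrix, KinshipMatrix, PedigreeTable

__all__ = [
    "read_phenotypes", "write_phenotypes",
    "read_kinship", "write_kinship",
    "read_genotypes", "write_genotypes",
    "read_pedigree", "write_pedigree",
    "write_manifest", "read_manifest",
]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_phenotypes(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read (ids, y, n_counts) from a delimited file with header columns
    id, value and optional n.  Missing n means n_i = 1."""
    df = pd.read_csv(path, sep=_sep(path))
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "value" not in cols:
        raise ValueError(f"{path}: expected columns 'id' and 'value'")
    ids = df[cols["id"]].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    vals = pd.to_numeric(df[cols["value"]], errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0]) + 2  # 1-based incl. header
        raise ValueError(f"{path}: non-numeric or missing value at line {row}")
    y = vals.to_numpy(dtype=float)
    if "n" in cols:
        n = pd.to_numeric(df[cols["n"]], errors="coerce").fillna(1.0)
        n_counts = n.to_numpy(dtype=float)
    else:
        n_counts = np.ones(len(y))
    return ids, y, n_counts


def write_phenotypes(path, ids, y, n_counts=None) -> None:
    df = pd.DataFrame({"id": ids, "value": np.asarray(y, dtype=float)})
    if n_counts is not None:
        df["n"] = np.asarray(n_counts, dtype=float)
    df.to_csv(path, sep=_sep(path), index=False)


def read_kinship(path, kind: str = "custom") -> KinshipMatrix:
    """Read a labeled square matrix; header and row labels must agree."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError(f"{path}: matrix not symmetric to 1e-10")
    return KinshipMatrix(labels=list(df.index.astype(str)), values=values,
                         kind=kind)


def write_kinship(K: KinshipMatrix, path) -> None:
    """Write K with labels, 12 significant digits (round-trip exact)."""
    df = pd.DataFrame(K.values, index=K.labels, columns=K.labels)
    df.to_csv(path, sep=_sep(path), float_format="%.12g")


def read_genotypes(path, missing: str = "NA") -> GenotypeMatrix:
    """Read a dosage matrix: header row = marker ids, first column =
    sample ids.  Also accepts the PLINK .raw additive dialect (leading
    FID/IID/PAT/MAT/SEX/PHENOTYPE columns, whitespace-separated)."""
    if str(path).endswith(".raw"):
        df = pd.read_csv(path, sep=r"\s+", na_values=[missing])
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if not set(meta).issubset(df.columns):
            raise ValueError(f"{path}: not a PLINK .raw additive file")
        ids = df["IID"].astype(str).tolist()
        dos = df.drop(columns=meta)
    else:
        df = pd.read_csv(path, sep=_sep(path), index_col=0,
                         na_values=[missing])
        ids = list(df.index.astype(str))
        dos = df
    X = dos.to_numpy(dtype=float)
    observed = X[~np.isnan(X)]
    ploidy = 1 if observed.size and observed.max() <= 1 else 2
    return GenotypeMatrix(sample_ids=ids,
                          marker_ids=list(dos.columns.astype(str)),
                          dosages=X, ploidy=ploidy)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.sample_ids,
                      columns=geno.marker_ids)
    df.to_csv(path, sep=_sep(path), na_rep="NA", float_format="%g")


def read_pedigree(path) -> PedigreeTable:
    """Read 3-column (id, sire, dam) delimited text; '0'/'NA' = unknown."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pedigree needs 3 columns (id, sire, dam)")
    records = [
        (str(r.iloc[0]), r.iloc[1], r.iloc[2]) for _, r in df.iterrows()
    ]
    return PedigreeTable(records=records)


def write_pedigree(ped: PedigreeTable, path) -> None:
    df = pd.DataFrame(
        [(i, s or "0", d or "0") for i, s, d in ped.records],
        columns=["id", "sire", "dam"],
    )
    df.to_csv(path, sep=_sep(path), index=False)


def write_manifest(path, config: dict) -> None:
    """YAML manifest recording the configuration and seeds of a run."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
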