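"""Readers, writers and run manifests.

Formats are plain delimited text:

* coded genotype CSV — header ``marker_id,chrom,pos,<sample ids...>``, one
  marker per row with numeric {1, 0, -1} codes (blank/NA allowed);
* hapmap-like genotype CSV — same layout but with two-letter allele calls
  (``AA``, ``AG``...), encoded through :func:`mrmlm.encoding.encode_genotypes`;
* phenotype TSV — two columns (sample id, value), aligned to the genotype
  sample order;
* kinship CSV — square matrix with a sample-id header;
* results TSV + JSON sidecars — numeric fields written with 12 significant
  digits so a round trip reproduces them bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ScanThresholds
from .encoding import encode_genotypes

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "read_kinship",
    "write_kinship",
    "write_results",
    "read_results",
    "RunManifest",
]

_META_COLS = ("marker_id", "chrom", "pos")


def read_genotypes(path, format: str = "coded-csv") -> GenotypeMatrix:
    """Read a genotype matrix from delimited text.

    ``format`` is ``"coded-csv"`` (numeric codes) or ``"hapmap-like"``
    (two-letter calls).  Malformed rows raise with their line number;
    duplicate marker ids raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty genotype file")
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    sample_ids = [c for c in df.columns if c not in _META_COLS]
    if not sample_ids:
        raise ValueError(f"{path}: no sample columns")
    snp_map = df[list(_META_COLS)].copy()
    try:
        snp_map["pos"] = snp_map["pos"].astype(np.int64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer position ({exc})") from None
    calls = df[sample_ids].to_numpy(dtype=object)

    if format == "hapmap-like":
        return encode_genotypes(calls, snp_map=snp_map, sample_ids=sample_ids)
    if format != "coded-csv":
        raise ValueError(f"unknown genotype format {format!r}")

    values = np.empty(calls.shape, dtype=float)
    for i in range(calls.shape[0]):
        for j in range(calls.shape[1]):
            cell = calls[i, j]
            if cell is None or str(cell).strip() in ("", "NA", "nan"):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: malformed value {cell!r} at line {i + 2}"
                ) from None
    # impute residual missing entries with the marker mean
    for i in range(values.shape[0]):
        row = values[i]
        if np.isnan(row).any():
            if np.isnan(row).all():
                raise ValueError(f"{path}: all-missing marker at line {i + 2}")
            row[np.isnan(row)] = np.nanmean(row)
    return GenotypeMatrix(values=values.T, snp_map=snp_map, sample_ids=sample_ids)


def read_phenotypes(path, sample_ids=None) -> np.ndarray:
    """Two-column (id, value) TSV/CSV; reordered to ``sample_ids`` if given."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, header=None, names=["sample_id", "value"], dtype=str)
    if df.iloc[0]["value"] is not None:
        try:
            float(df.iloc[0]["value"])
        except (TypeError, ValueError):  # header row
            df = df.iloc[1:]
    df["sample_id"] = df["sample_id"].astype(str)
    df["value"] = df["value"].astype(float)
    if sample_ids is None:
        return df["value"].to_numpy()
    lookup = dict(zip(df["sample_id"], df["value"]))
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"{path}: phenotypes missing for samples {missing[:5]}")
    return np.array([lookup[s] for s in sample_ids])


def read_kinship(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(map(str, df.columns))


def write_kinship(K: np.ndarray, sample_ids, path) -> None:
    pd.DataFrame(K, index=sample_ids, columns=sample_ids).to_csv(
        path, float_format="%.12g"
    )


def write_results(records: pd.DataFrame, thresholds, manifest, out_dir) -> dict:
    """Write a results TSV plus thresholds/manifest JSON sidecars.

    Returns the paths written.  Numeric fields use 12 significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"results": out_dir / "results.tsv"}
    records.to_csv(paths["results"], sep="\t", index=False, float_format="%.12g")
    if thresholds is not None:
        paths["thresholds"] = out_dir / "thresholds.json"
        payload = {
            "m_e": thresholds.m_e,
            "alpha_genome": thresholds.alpha_genome,
            "p_threshold": thresholds.p_threshold,
            "m": thresholds.m,
        }
        paths["thresholds"].write_text(json.dumps(payload, indent=2))
    if manifest is not None:
        paths["manifest"] = out_dir / "manifest.json"
        manifest.to_json(paths["manifest"])
    return paths


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to rerun an analysis: inputs, config, thresholds."""

    command: str
    inputs: dict = field(default_factory=dict)      # path -> sha256
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    software: dict = field(default_factory=dict)

    @classmethod
    def create(cls, command: str, input_paths=(), config=None, seeds=None, thresholds=None):
        from . import __version__

        return cls(
            command=command,
            inputs={str(p): _hash_file(p) for p in input_paths},
            config=dict(config or {}),
            seeds=dict(seeds or {}),
            thresholds=dict(thresholds or {}),
            software={"mrmlm": __version__, "python": platform.python_version()},
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
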