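"""Readers, writers and run configuration.

Genotypes travel as plain text in one of two layouts:

* ``matrix-tsv`` — a header row of SNP ids, one row per sample with the
  sample id in the first column and cells 0/1/2 or NA;
* ``plink-raw`` — the PLINK ``--recode A`` additive dosage export: six
  metadata columns (FID IID PAT MAT SEX PHENOTYPE) followed by one
  dosage column per SNP, whitespace-delimited.

Phenotypes are a one-column numeric file (positional alignment) or a
two-column ``sample_id<TAB>value`` file (realigned to the genotype
sample order by id).  Missing genotypes are encoded ``NA`` in files and
``-1`` in the in-memory int8 matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import AdaptiveResult

__all__ = [
    "GenotypeMatrix",
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_results",
    "results_frame",
    "load_config",
]

logger = logging.getLogger(__name__)

MISSING = -1  # in-memory sentinel for an NA genotype


@dataclass
class GenotypeMatrix:
    """n x m additive dosage matrix with sample and SNP labels."""

    values: np.ndarray  # int8, entries in {0, 1, 2} or MISSING
    snp_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("label lengths do not match matrix dimensions")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype value {self.values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def _validated_dosages(raw: pd.DataFrame, path, snp_ids, sample_ids) -> np.ndarray:
    values = np.full(raw.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(raw.columns):
        cell = pd.to_numeric(raw[col], errors="coerce")
        na_in = raw[col].isna() | raw[col].astype(str).str.upper().isin(("NA", "NAN"))
        bad = cell.isna() & ~na_in
        ok = cell.notna() & ~cell.isin((0, 1, 2))
        if bad.any() or ok.any():
            i = int(np.argmax(bad.to_numpy() | ok.to_numpy()))
            raise ValueError(
                f"{path}: malformed genotype {raw[col].iloc[i]!r} at row "
                f"{sample_ids[i]!r}, column {snp_ids[j]!r}"
            )
        values[cell.notna().to_numpy(), j] = cell.dropna().astype(np.int8)
    return values


def read_genotypes(path, fmt: str = "matrix-tsv") -> GenotypeMatrix:
    """Load a genotype file; ``fmt`` is ``matrix-tsv`` or ``plink-raw``."""
    path = Path(path)
    if fmt == "matrix-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif fmt == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        meta = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
        missing_meta = [c for c in meta if c not in df.columns]
        if missing_meta:
            raise ValueError(f"{path}: not a PLINK .raw file (missing {missing_meta})")
        df = df.set_index("IID").drop(columns=[c for c in meta if c != "IID"])
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no genotype data found")
    snp_ids = [str(c) for c in df.columns]
    sample_ids = [str(i) for i in df.index]
    values = _validated_dosages(df, path, snp_ids, sample_ids)
    return GenotypeMatrix(values=values, snp_ids=snp_ids, sample_ids=sample_ids)


def write_genotypes(gm: GenotypeMatrix, path, fmt: str = "matrix-tsv") -> None:
    path = Path(path)
    cells = gm.values.astype(object)
    df = pd.DataFrame(cells, index=gm.sample_ids, columns=gm.snp_ids)
    df = df.where(gm.values != MISSING, "NA")
    if fmt == "matrix-tsv":
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    elif fmt == "plink-raw":
        out = pd.DataFrame({
            "FID": gm.sample_ids, "IID": gm.sample_ids,
            "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9,
        })
        out = pd.concat([out, df.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def read_phenotype(path, sample_ids: Optional[Sequence[str]] = None) -> np.ndarray:
    """Length-n trait vector, id-aligned to ``sample_ids`` when both sides
    carry ids, positional otherwise."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python", header=None, dtype=str)
    if df.shape[1] == 1:
        values = pd.to_numeric(df[0], errors="coerce")
        bad = values.isna() & ~df[0].str.upper().isin(("NA", "NAN"))
        if bad.any():
            i = int(bad.idxmax())
            raise ValueError(f"{path}: non-numeric phenotype {df[0].iloc[i]!r} at line {i + 1}")
        y = values.to_numpy(dtype=float)
        if sample_ids is not None and y.size != len(sample_ids):
            raise ValueError(
                f"{path}: phenotype length {y.size} does not match "
                f"{len(sample_ids)} genotype samples"
            )
        return y
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")
    ids = df[0].astype(str)
    values = pd.to_numeric(df[1], errors="coerce")
    bad = values.isna() & ~df[1].str.upper().isin(("NA", "NAN"))
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(f"{path}: non-numeric phenotype {df[1].iloc[i]!r} for sample {ids.iloc[i]!r}")
    series = pd.Series(values.to_numpy(dtype=float), index=ids)
    if series.index.duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    if sample_ids is None:
        return series.to_numpy()
    missing = [s for s in sample_ids if s not in series.index]
    if missing:
        raise ValueError(f"{path}: no phenotype for sample ids {missing}")
    return series.reindex([str(s) for s in sample_ids]).to_numpy()


def results_frame(results: Sequence[AdaptiveResult]) -> pd.DataFrame:
    """Adaptive scan results as a tidy DataFrame (input SNP order)."""
    return pd.DataFrame({
        "snp_id": [r.snp_id for r in results],
        "stat": [r.observed_stat for r in results],
        "R": [r.R for r in results],
        "B": [r.B for r in results],
        "p_hat": [r.p_hat for r in results],
        "stopped_early": [r.stopped_early for r in results],
        "untestable": [r.untestable for r in results],
        "significant": [r.significant for r in results],
    })


def write_results(results: Sequence[AdaptiveResult], path) -> None:
    """TSV result table; untestable markers carry NA statistics."""
    path = Path(path)
    if len(results) == 0:
        logger.warning("writing empty result table to %s", path)
    df = results_frame(results)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


@dataclass
class RunConfig:
    """Flat configuration for an association run.

    Either the design inputs (``m``, ``alpha_e``, ``c``) or an explicit
    ``(b, r)`` pair must be given; an explicit pair wins.
    """

    geno: str = ""
    pheno: str = ""
    geno_format: str = "matrix-tsv"
    out: str = "results.tsv"
    m: Optional[int] = None
    alpha_e: float = 0.05
    c: float = 0.1
    b: Optional[int] = None
    r: Optional[int] = None
    statistic: str = "oneway_anova"
    tie: str = "geq"
    seed: int = 0
    replicate_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.b is not None and self.r is not None and self.r > self.b:
            raise ValueError("explicit r must not exceed b")


def load_config(path, **overrides) -> RunConfig:
    """Read a YAML key-value config; keyword overrides win over the file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
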