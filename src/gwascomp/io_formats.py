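"""Readers and writers for every external artifact the pipeline touches.

All tables are tab-separated UTF-8 with a header row.  The SNP covariance
reference uses the 4-column ``GENE RSID1 RSID2 VALUE`` text format (gzip
accepted, detected by the ``.gz`` suffix); networks are 2-column edge lists;
expression matrices are genes x samples with the gene id in the first column.
Every reader/writer pair round-trips exactly, and readers order their output
deterministically.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import EigengeneModel, ModuleWeights
from .datatypes import (
    DirectedNetwork,
    ExpressionMatrix,
    FormatError,
    GwasSummary,
    PredictionModel,
    SnpCovariance,
    ValidationError,
)
from .signatures import CharacteristicDirection

logger = logging.getLogger(__name__)

__all__ = [
    "read_gwas_summary", "write_gwas_summary",
    "read_prediction_model", "write_prediction_model",
    "read_snp_covariance", "write_snp_covariance",
    "read_expression_matrix", "write_expression_matrix",
    "read_network", "write_network",
    "read_eigengene_model", "write_eigengene_model",
    "read_signature", "write_signature",
]

_GWAS_STANDARD = ("snp_id", "effect_allele", "non_effect_allele", "z", "beta", "se")


def read_gwas_summary(path, column_map: dict | None = None) -> GwasSummary:
    """Load GWAS summary statistics from a TSV.

    ``column_map`` maps standard names (snp_id, effect_allele,
    non_effect_allele, z, beta, se) to the file's column headers.  Either a
    ``z`` column or both ``beta`` and ``se`` must be present; when ``z`` is
    absent it is computed as beta/se.  Rows with non-finite statistics or
    non-positive se are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    column_map = column_map or {}
    rename = {column_map.get(k, k): k for k in _GWAS_STANDARD if column_map.get(k, k) in df.columns}
    df = df.rename(columns=rename)
    for col in ("snp_id", "effect_allele", "non_effect_allele"):
        if col not in df.columns:
            raise FormatError(f"GWAS summary {path} is missing column {col!r}")
    if "z" in df.columns:
        df["z"] = pd.to_numeric(df["z"], errors="coerce")
    elif "beta" in df.columns and "se" in df.columns:
        beta = pd.to_numeric(df["beta"], errors="coerce")
        se = pd.to_numeric(df["se"], errors="coerce")
        se = se.where(se > 0)
        df["z"] = beta / se
    else:
        raise FormatError(f"GWAS summary {path} needs a 'z' column or 'beta' and 'se'")
    keep = np.isfinite(df["z"].to_numpy(float))
    if (~keep).any():
        logger.info("dropped %d GWAS rows with non-finite statistics", int((~keep).sum()))
    df = df.loc[keep]
    return GwasSummary(df[["snp_id", "effect_allele", "non_effect_allele", "z"]].reset_index(drop=True))


def write_gwas_summary(gwas: GwasSummary, path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False)


def read_prediction_model(path) -> PredictionModel:
    """Load a PrediXcan-schema weight table (rsid, gene, weight, ref/eff allele)."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "gene": str}, float_precision="round_trip")
    for col in ("rsid", "gene", "weight", "ref_allele", "eff_allele"):
        if col not in df.columns:
            raise FormatError(f"prediction model {path} is missing column {col!r}")
    df["weight"] = pd.to_numeric(df["weight"])
    return PredictionModel(df[["gene", "rsid", "weight", "ref_allele", "eff_allele"]])


def write_prediction_model(model: PredictionModel, path) -> None:
    model.table[["rsid", "gene", "weight", "ref_allele", "eff_allele"]].to_csv(
        path, sep="\t", index=False
    )


def _opener(path):
    return gzip.open if str(path).endswith(".gz") else open


def read_snp_covariance(path) -> SnpCovariance:
    """Load per-gene SNP covariance records ``GENE RSID1 RSID2 VALUE``.

    Either triangle (or both) may be supplied; symmetric completion is
    performed and duplicate entries that disagree by more than 1e-10 raise a
    validation error.  A header line is detected and skipped.
    """
    entries: dict[str, dict[tuple[str, str], float]] = {}
    with _opener(path)(path, "rt") as fh:
        for lineno, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno + 1}: expected 4 columns, got {len(parts)}")
            gene, s1, s2, raw = parts
            if lineno == 0 and raw.upper() in ("VALUE", "COVARIANCE"):
                continue  # header
            try:
                value = float(raw)
            except ValueError:
                raise FormatError(f"{path}:{lineno + 1}: non-numeric covariance {raw!r}") from None
            key = (s1, s2) if s1 <= s2 else (s2, s1)
            block = entries.setdefault(gene, {})
            if key in block and abs(block[key] - value) > 1e-10:
                raise ValidationError(
                    f"conflicting covariance for {gene} {s1}/{s2}: {block[key]} vs {value}"
                )
            block[key] = value
    blocks = {}
    for gene, block in entries.items():
        snps = sorted({s for pair in block for s in pair})
        index = {s: k for k, s in enumerate(snps)}
        mat = np.zeros((len(snps), len(snps)))
        for (s1, s2), value in block.items():
            mat[index[s1], index[s2]] = value
            mat[index[s2], index[s1]] = value
        blocks[gene] = (snps, mat)
    return SnpCovariance(blocks)


def write_snp_covariance(cov: SnpCovariance, path) -> None:
    """Write the upper triangle of every block as GENE RSID1 RSID2 VALUE."""
    with _opener(path)(path, "wt") as fh:
        fh.write("GENE\tRSID1\tRSID2\tVALUE\n")
        for gene in cov.genes:
            snps, mat = cov.block(gene)
            for i, s1 in enumerate(snps):
                for j in range(i, len(snps)):
                    fh.write(f"{gene}\t{s1}\t{snps[j]}\t{float(mat[i, j])!r}\n")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Load a genes x samples expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        raise FormatError(f"missing values (ragged rows?) in expression matrix {path}")
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy(float)
    )


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    df = expr.to_frame()
    df.index.name = "gene_id"
    # repr-roundtrip float formatting keeps read(write(x)) bitwise equal
    df.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def read_network(path) -> DirectedNetwork:
    """Load a 2-column (parent, child) TSV edge list into a validated DAG."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"network {path} needs two columns (parent, child)")
    edges = list(df.iloc[:, :2].itertuples(index=False, name=None))
    return DirectedNetwork.from_edges(edges)


def write_network(net: DirectedNetwork, path) -> None:
    pd.DataFrame(net.edges, columns=["parent", "child"]).to_csv(path, sep="\t", index=False)


def read_eigengene_model(path) -> EigengeneModel:
    """Load a module weight table (module_id, gene_id, weight, gene_sd)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    for col in ("module_id", "gene_id", "weight", "gene_sd"):
        if col not in df.columns:
            raise FormatError(f"module table {path} is missing column {col!r}")
    modules = {}
    for module_id, sub in df.groupby("module_id"):
        modules[int(module_id)] = ModuleWeights(
            sub["gene_id"].tolist(),
            sub["weight"].to_numpy(float),
            sub["gene_sd"].to_numpy(float),
        )
    return EigengeneModel(modules)


def write_eigengene_model(model: EigengeneModel, path) -> None:
    rows = []
    for module_id in model.module_ids:
        mw = model.modules[module_id]
        for g, w, s in zip(mw.genes, mw.weights, mw.gene_sds):
            rows.append((module_id, g, repr(float(w)), repr(float(s))))
    pd.DataFrame(rows, columns=["module_id", "gene_id", "weight", "gene_sd"]).to_csv(
        path, sep="\t", index=False
    )


def read_signature(path) -> CharacteristicDirection:
    """Load a signature TSV (gene_id, weight); unit-normalized on load."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    for col in ("gene_id", "weight"):
        if col not in df.columns:
            raise FormatError(f"signature {path} is missing column {col!r}")
    v = df["weight"].to_numpy(float)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValidationError(f"signature {path} is identically zero")
    return CharacteristicDirection(df["gene_id"].tolist(), v / nrm)


def write_signature(sig: CharacteristicDirection, path) -> None:
    pd.DataFrame({"gene_id": sig.gene_ids, "weight": [repr(float(w)) for w in sig.direction]}).to_csv(
        path, sep="\t", index=False
    )
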