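"""Readers and writers for the package's plain-text formats.

On-disk genotype call matrices are markers x samples (the usual array-export
orientation); in memory everything is samples x markers.  Coordinates are
1-based inclusive, as in VCF.  Report floats are rendered with six decimals
so that reruns diff cleanly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CALL_ALIASES,
    CALL_SYMBOLS,
    CallMatrix,
    InvariantError,
    MarkerMap,
    ParseError,
    PhenotypeTable,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"

_VALID_TOKENS = set(CALL_SYMBOLS) | set(CALL_ALIASES)


def read_calls_tsv(path) -> CallMatrix:
    """Read the TSV call-matrix dialect.

    Header: ``marker_id  chrom  pos  <sample...>``; one row per marker;
    cells in {AA, AB, BB, FF} (aliases BA -> AB, NA -> FF, ``--`` -> FF are
    normalized).  Returns a samples x markers :class:`CallMatrix`.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["marker_id", "chrom", "pos"]:
            raise ParseError(
                f"{path}: header must start with marker_id, chrom, pos "
                f"(got {header[:3]})"
            )
        sample_ids = header[3:]
        if len(set(sample_ids)) != len(sample_ids):
            raise InvariantError(f"{path}: duplicate sample id in header")
        marker_ids, chroms, poss, rows = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 + len(sample_ids):
                raise ParseError(
                    f"{path}:{lineno}: expected {3 + len(sample_ids)} fields, "
                    f"got {len(fields)}"
                )
            marker_ids.append(fields[0])
            chroms.append(fields[1])
            poss.append(int(fields[2]))
            row = []
            for col, tok in enumerate(fields[3:]):
                if tok not in _VALID_TOKENS:
                    raise ParseError(
                        f"{path}:{lineno}: unknown call token {tok!r} for marker "
                        f"{fields[0]!r}, sample {sample_ids[col]!r}"
                    )
                row.append(CALL_ALIASES.get(tok, tok))
            rows.append(row)
    marker_map = MarkerMap(marker_ids, chroms, poss)
    symbols = np.asarray(rows, dtype=object).T if rows else np.empty((len(sample_ids), 0), dtype=object)
    cm = CallMatrix.from_symbols(symbols, sample_ids, marker_map)
    log.info("read %s: %d markers x %d samples", path, cm.n_markers, cm.n_samples)
    return cm


def write_calls_tsv(cm: CallMatrix, path) -> None:
    """Write a CallMatrix in the TSV dialect (markers x samples)."""
    path = Path(path)
    symbols = cm.to_symbols()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["marker_id", "chrom", "pos", *map(str, cm.sample_ids)]))
        fh.write("\n")
        for j in range(cm.n_markers):
            fh.write(
                "\t".join(
                    [
                        str(cm.map.marker_id[j]),
                        str(cm.map.chrom[j]),
                        str(cm.map.pos[j]),
                        *symbols[:, j],
                    ]
                )
            )
            fh.write("\n")


def read_calls_vcf(path) -> tuple[CallMatrix, int]:
    """Read genotype calls from a VCF file.

    GT mapping: ``0/0`` -> AA, ``0/1``/``1/0`` -> AB, ``1/1`` -> BB,
    ``./.`` or ``.`` -> FF; phased separators are treated as unphased.
    Multiallelic sites are skipped with a warning.  Returns the call matrix
    and the number of skipped multiallelic sites.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    marker_ids, chroms, poss, rows = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            log.warning(
                "skipping multiallelic site %s:%d (ALT=%s)",
                var.CHROM, var.POS, ",".join(var.ALT),
            )
            continue
        gts = var.genotypes  # per sample [allele0, allele1, phased]; -1 = missing
        if gts is None:
            raise ParseError(f"{path}: record {var.CHROM}:{var.POS} lacks GT")
        alleles = np.asarray([g[:2] for g in gts], dtype=int)
        row = np.where(
            (alleles < 0).any(axis=1), "FF", CALL_SYMBOLS[alleles.clip(0).sum(axis=1)]
        )
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(row)
    symbols = (
        np.asarray(rows, dtype=object).T
        if rows
        else np.empty((len(sample_ids), 0), dtype=object)
    )
    cm = CallMatrix.from_symbols(symbols, sample_ids, MarkerMap(marker_ids, chroms, poss))
    log.info(
        "read %s: %d biallelic sites x %d samples (%d multiallelic skipped)",
        path, cm.n_markers, cm.n_samples, n_skipped,
    )
    return cm, n_skipped


def read_phenotypes_tsv(path, traits=None, covariates=None) -> PhenotypeTable:
    """Read a phenotype TSV: header ``sample_id  <trait...>  <covariate...>``.

    Columns not named in *covariates* are treated as traits unless listed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    covariates = list(covariates or [])
    if traits is None:
        traits = [c for c in df.columns if c not in covariates]
    return PhenotypeTable(df, trait_names=list(traits), covariate_names=covariates)


def write_phenotypes_tsv(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT)


def write_report_tsv(frame: pd.DataFrame, path) -> None:
    """Write a tabular report (filter report, CV results) deterministically.

    Column order is preserved; floats are rendered with six decimals.
    """
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_report_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix_tsv(values: np.ndarray, ids, path) -> None:
    """Write a square labelled matrix (e.g. a GRM) with id header row/column."""
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t", index_label="id")


def read_matrix_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), np.asarray(df.index, dtype=object)
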