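"""Readers and writers for the package's tabular formats.

TSV is the canonical on-disk format: expression and genotype matrices are
stored features-in-rows / samples-in-columns; purity, truth, annotation, cis
pair and result tables are plain headered TSVs.  Every file written carries
``#``-prefixed header comments recording the package version, the seed and a
config hash, and every reader skips such comments.  A minimal VCF reader
(biallelic sites, GT field) is provided as a convenience via pysam.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .models import RESULT_COLUMNS

__all__ = [
    "config_hash",
    "write_expression",
    "read_expression",
    "write_genotypes",
    "read_genotypes",
    "write_purity",
    "read_purity",
    "write_truth",
    "read_truth",
    "write_table",
    "read_table",
    "write_results",
    "read_results",
    "write_vcf",
    "read_vcf",
    "read_annotation",
    "write_manifest",
]


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict | None) -> str:
    meta = dict(meta or {})
    meta.setdefault("pureqtl", __version__)
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _write_tsv(df: pd.DataFrame, path, meta: dict | None, index: bool, index_label=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def _read_tsv(path, index_col=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows (truncated file?)")
    return df


# --- matrices (features in rows, samples in columns on disk) ---------------

def write_expression(expr: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a samples x genes expression matrix as genes x samples TSV."""
    _write_tsv(expr.T, path, meta, index=True, index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV back into a samples x genes DataFrame."""
    return _read_tsv(path, index_col=0).T.rename_axis(index=None, columns=None)


def write_genotypes(geno: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a samples x variants dosage matrix as variants x samples TSV."""
    _write_tsv(geno.T, path, meta, index=True, index_label="variant_id")


def read_genotypes(path, format: str = "tsv"):
    """Read genotype dosages from TSV (or a minimal VCF with ``format='vcf'``).

    TSV returns a samples x variants DataFrame; VCF returns
    ``(dosages, variants)`` where variants carries chrom/pos coordinates.
    """
    if format == "vcf":
        return read_vcf(path)
    return _read_tsv(path, index_col=0).T.rename_axis(index=None, columns=None)


# --- small tables -----------------------------------------------------------

def write_purity(purity: pd.Series, path, meta: dict | None = None) -> None:
    df = pd.DataFrame({"sample_id": purity.index, "purity": purity.to_numpy()})
    _write_tsv(df, path, meta, index=False)


def read_purity(path) -> pd.Series:
    df = _read_tsv(path)
    index = pd.Index(df["sample_id"].to_numpy(), name=None)
    return pd.Series(df["purity"].to_numpy(), index=index, name="purity")


def write_truth(truth: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(truth[["gene_id", "group", "beta_cancer", "beta_normal"]], path, meta, index=False)


def read_truth(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Generic headered-TSV writer (cis pairs, covariates, sweeps, ...)."""
    _write_tsv(df, path, meta, index=False)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_results(results: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a scan result table with the stable column order."""
    _write_tsv(results[RESULT_COLUMNS], path, meta, index=False)


def read_results(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: result table missing columns {missing}")
    return df


def read_annotation(path, kind: str) -> pd.DataFrame:
    """Read a BED-like feature annotation TSV.

    ``kind='variant'`` expects (variant_id, chrom, pos); ``kind='gene'``
    expects (gene_id, chrom) plus tss or start/end(/strand).  Coordinates are
    1-based inclusive.
    """
    df = _read_tsv(path)
    required = {"variant": ["variant_id", "chrom", "pos"], "gene": ["gene_id", "chrom"]}[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation missing columns {missing}")
    if kind == "gene" and not ({"tss", "start"} & set(df.columns)):
        raise ValueError(f"{path}: gene annotation needs a 'tss' or 'start' column")
    return df


# --- VCF --------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(
    geno: pd.DataFrame, path, variants: pd.DataFrame | None = None, meta: dict | None = None
) -> None:
    """Write dosages as a minimal VCFv4.2 (GT only, one line per variant).

    ``variants`` may supply chrom/pos (and ref/alt) per variant_id; otherwise
    synthetic coordinates chrom "1", pos 1000*(i+1) are used.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    variant_ids = list(geno.columns)
    if variants is not None:
        ann = variants.set_index("variant_id").loc[variant_ids]
        chroms = ann["chrom"].astype(str).tolist()
        poss = ann["pos"].astype(int).tolist()
    else:
        chroms = ["1"] * len(variant_ids)
        poss = [1000 * (i + 1) for i in range(len(variant_ids))]
    samples = list(geno.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=pureqtl-{__version__}\n")
        for c in sorted(set(chroms)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        dosages = geno.to_numpy()
        for j, vid in enumerate(variant_ids):
            gts = "\t".join(
                _GT_STRINGS.get(int(d), "./.") if not (isinstance(d, float) and np.isnan(d)) else "./."
                for d in dosages[:, j]
            )
            fh.write(f"{chroms[j]}\t{poss[j]}\t{vid}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (samples x variants dosages, variant annotation).

    Restricted to biallelic sites with a GT field; multi-allelic or malformed
    records are skipped with a counted warning.  Missing genotypes become NaN
    (complete-case handling happens at fit time).
    """
    import pysam

    skipped = 0
    cols: dict[str, np.ndarray] = {}
    ann_rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            try:
                if rec.alts is None or len(rec.alts) != 1:
                    skipped += 1
                    continue
                dosage = np.full(len(samples), np.nan)
                for i, s in enumerate(samples):
                    gt = rec.samples[s].get("GT")
                    if gt is not None and None not in gt:
                        dosage[i] = sum(1 for a in gt if a == 1)
                vid = rec.id or f"{rec.chrom}:{rec.pos}"
                cols[vid] = dosage
                ann_rows.append((vid, str(rec.chrom), int(rec.pos)))
            except (ValueError, KeyError):
                skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} multi-allelic/malformed VCF record(s)", stacklevel=2)
    dosages = pd.DataFrame(cols, index=samples)
    variants = pd.DataFrame(ann_rows, columns=["variant_id", "chrom", "pos"])
    return dosages, variants


def write_manifest(path, config: dict, seed: int, outputs: list[str]) -> None:
    """Record provenance of a run: version, seed, config hash, artifacts."""
    manifest = {
        "pureqtl": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "outputs": outputs,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
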