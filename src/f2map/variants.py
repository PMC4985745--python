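"""Variant-call merging, high-quality locus filtering and parent-unique SNP classification.

Per-sample VCF files (minimal dialect: CHROM, POS, REF, ALT plus GT/DP)
are merged into one wide locus table, filtered by how many samples carry
a call at each locus, and split into P1-unique / P2-unique / discarded
classes based on the parental genotypes.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "LocusConflictError",
    "read_sample_vcf",
    "merge_calls",
    "sample_names",
    "filter_high_quality",
    "classify_parent_snps",
    "is_indel",
    "summarize_sequencing",
    "mean_variants_per_sample",
]

GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"


class LocusConflictError(ValueError):
    """Two input files disagree on the REF (or ALT) allele at one locus."""


def read_sample_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a single-sample VCF into a call table.

    Returns a frame with columns ``scaffold, pos, ref, alt, gt, dp`` where
    ``gt`` is one of ``hom_ref / het / hom_alt`` or NA for missing calls.
    """
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected a single-sample VCF, found {len(vcf.samples)}")
    rows = []
    for rec in vcf:
        a1, a2 = rec.genotypes[0][:2]
        if a1 < 0 or a2 < 0:
            gt = None
        elif a1 == a2:
            gt = GT_HOM_REF if a1 == 0 else GT_HOM_ALT
        else:
            gt = GT_HET
        dp = rec.format("DP")
        dp = int(dp[0][0]) if dp is not None else 0
        alt = rec.ALT[0] if rec.ALT else None
        rows.append((rec.CHROM, rec.POS, rec.REF, alt, gt, dp))
    return pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt", "gt", "dp"])


def merge_calls(paths: Mapping[str, str | os.PathLike]) -> pd.DataFrame:
    """Merge per-sample call files into one wide locus table.

    The result has one row per (scaffold, pos) locus with ``ref``/``alt``
    columns and per-sample ``gt:<name>`` / ``dp:<name>`` columns; loci
    absent from a sample's file are missing for that sample.

    Raises :class:`LocusConflictError` if two files disagree on REF (or on
    a non-missing ALT) at the same position.
    """
    if not paths:
        raise ValueError("no input files")
    long = pd.concat(
        [read_sample_vcf(p).assign(sample=name) for name, p in paths.items()],
        ignore_index=True,
    )
    for allele in ("ref", "alt"):
        per_locus = long.dropna(subset=[allele]).groupby(["scaffold", "pos"])[allele].nunique()
        bad = per_locus[per_locus > 1]
        if len(bad):
            scaf, pos = bad.index[0]
            raise LocusConflictError(
                f"conflicting {allele.upper()} alleles at {scaf}:{pos}"
            )
    alleles = (
        long.groupby(["scaffold", "pos"], sort=False)[["ref", "alt"]].first().reset_index()
    )
    gt = long.pivot(index=["scaffold", "pos"], columns="sample", values="gt")
    dp = long.pivot(index=["scaffold", "pos"], columns="sample", values="dp")
    gt.columns = [f"gt:{s}" for s in gt.columns]
    dp.columns = [f"dp:{s}" for s in dp.columns]
    table = alleles.set_index(["scaffold", "pos"]).join(gt).join(dp).reset_index()
    table = table.sort_values(["scaffold", "pos"], kind="mergesort").reset_index(drop=True)
    return table


def sample_names(table: pd.DataFrame) -> list[str]:
    """Sample names present in a merged locus table."""
    return [c.split(":", 1)[1] for c in table.columns if c.startswith("gt:")]


def filter_high_quality(
    table: pd.DataFrame, min_calls: int = 20, max_calls: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Keep loci whose non-missing call count lies in ``[min_calls, max_calls]``.

    ``max_calls`` defaults to the number of samples (no upper cut).  The
    call tally counts parents and progeny alike.  Returns the filtered
    table and a report of discard counts by reason.
    """
    names = sample_names(table)
    if max_calls is None:
        max_calls = len(names)
    if not 0 <= min_calls <= max_calls:
        raise ValueError("require 0 <= min_calls <= max_calls")
    if max_calls > len(names):
        raise ValueError("max_calls exceeds the number of samples")
    counts = table[[f"gt:{s}" for s in names]].notna().sum(axis=1)
    keep = (counts >= min_calls) & (counts <= max_calls)
    report = {
        "input": int(len(table)),
        "retained": int(keep.sum()),
        "discarded_below_min": int((counts < min_calls).sum()),
        "discarded_above_max": int((counts > max_calls).sum()),
        "min_calls": min_calls,
        "max_calls": max_calls,
    }
    return table[keep].reset_index(drop=True), report


def is_indel(table: pd.DataFrame) -> pd.Series:
    """Boolean mask of loci whose REF or ALT allele is not a single base."""
    ref_len = table["ref"].astype(str).str.len()
    alt_len = table["alt"].astype(str).str.len().where(table["alt"].notna(), 1)
    return (ref_len != 1) | (alt_len != 1)


def classify_parent_snps(
    table: pd.DataFrame, p1: str = "P1", p2: str = "P2"
) -> tuple[pd.DataFrame, dict]:
    """Assign each locus a parental origin or a discard reason.

    A locus is P1-unique when P1 is homozygous ALT and P2 homozygous REF
    (and vice versa for P2-unique).  Loci where either parent is
    heterozygous, missing, or where both parents share the same homozygous
    genotype are discarded.  Every locus receives exactly one label.
    """
    for parent in (p1, p2):
        if f"gt:{parent}" not in table.columns:
            raise ValueError(f"parent column gt:{parent} missing from table")
    g1 = table[f"gt:{p1}"]
    g2 = table[f"gt:{p2}"]
    origin = np.full(len(table), "discarded", dtype=object)
    reason = np.full(len(table), "", dtype=object)
    missing = g1.isna() | g2.isna()
    het = (g1 == GT_HET) | (g2 == GT_HET)
    shared = (g1 == g2) & ~missing & ~het
    p1_unique = (g1 == GT_HOM_ALT) & (g2 == GT_HOM_REF)
    p2_unique = (g2 == GT_HOM_ALT) & (g1 == GT_HOM_REF)
    reason[missing.to_numpy()] = "parent_missing"
    reason[(het & ~missing).to_numpy()] = "parent_heterozygous"
    reason[shared.to_numpy()] = "shared_between_parents"
    origin[p1_unique.to_numpy()] = "P1"
    origin[p2_unique.to_numpy()] = "P2"
    reason[p1_unique.to_numpy() | p2_unique.to_numpy()] = ""
    origins = table[["scaffold", "pos"]].copy()
    origins["origin"] = origin
    origins["reason"] = reason
    counts = {
        "P1_unique": int((origin == "P1").sum()),
        "P2_unique": int((origin == "P2").sum()),
        "discarded": int((origin == "discarded").sum()),
        "discard_reasons": pd.Series(reason[origin == "discarded"]).value_counts().to_dict(),
    }
    return origins, counts


def summarize_sequencing(read_count: int, read_length: int, genome_size: int) -> float:
    """Sequencing depth (x) = reads * read length / genome size, to 2 decimals."""
    if read_count <= 0 or read_length <= 0 or genome_size <= 0:
        raise ValueError("read_count, read_length and genome_size must be > 0")
    return round(read_count * read_length / genome_size, 2)


def mean_variants_per_sample(total_variants: int, n_samples: int) -> int:
    """Mean variant count per sample, rounded to the nearest integer."""
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    return int(round(total_variants / n_samples))
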