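"""Shared fixtures: record builders, raw-VCF writer, small simulated cohort."""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from rnatmb import Callset, CohortSimConfig, VariantRecord, simulate_cohort
from rnatmb.features import default_registry


def make_variant(
    chrom: str = "chr1",
    pos: int = 100,
    ref: str = "C",
    alt: str = "T",
    sample_id: str = "S1",
    **kwargs,
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=sample_id, **kwargs
    )


def make_callset(
    variants, source: str = "rnaseq_tumor_only", sample_id: str = "S1"
) -> Callset:
    return Callset(sample_id=sample_id, source=source, variants=list(variants))


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=248956422>
    ##contig=<ID=chr2,length=242193529>
    ##FILTER=<ID=germline_risk,Description="g">
    ##FILTER=<ID=panel_of_normals,Description="p">
    ##FILTER=<ID=base_qual,Description="b">
    ##INFO=<ID=TLOD,Number=1,Type=Float,Description="t">
    ##INFO=<ID=ECNT,Number=1,Type=Integer,Description="e">
    ##INFO=<ID=SA_MAP_AF,Number=.,Type=Float,Description="s">
    ##INFO=<ID=ExAC_nontcga_ALL,Number=1,Type=Float,Description="x">
    ##INFO=<ID=ExAC_ALL,Number=1,Type=Float,Description="x">
    ##INFO=<ID=dbSNP150_ID,Number=1,Type=String,Description="d">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="g">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">
    """
)


def write_vcf(path: Path, body_lines, sample: str = "TUMOR", header: str = VCF_HEADER):
    """Write a raw VCF from tab-joined body rows (list of field lists)."""
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    lines = [header.rstrip("\n"), cols]
    for row in body_lines:
        lines.append("\t".join(str(f) for f in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def random_callset(rng, n: int, source: str = "rnaseq_tumor_only",
                   sample_id: str = "S1", n_positions: int = 500) -> Callset:
    """Random small callset over a confined coordinate space (forces overlap)."""
    variants = []
    seen = set()
    for _ in range(n):
        chrom = f"chr{rng.integers(1, 4)}"
        pos = int(rng.integers(1, n_positions))
        ref = "ACGT"[rng.integers(4)]
        alt = ref
        while alt == ref:
            alt = "ACGT"[rng.integers(4)]
        if (chrom, pos, ref, alt) in seen:
            continue
        seen.add((chrom, pos, ref, alt))
        variants.append(make_variant(chrom, pos, ref, alt, sample_id=sample_id))
    variants.sort(key=VariantRecord.sort_key)
    return make_callset(variants, source, sample_id)


def separable_fixture(n: int = 2000, seed: int = 7):
    """Linearly separable signal/noise set on the default 31-column registry.

    Two informative columns (TLOD and SA_MAP_AF_2) separate the classes;
    every other column is missing, which the boosted trees route natively.
    """
    rng = np.random.default_rng(seed)
    registry = default_registry()
    y = rng.integers(0, 2, size=n)
    X = pd.DataFrame(
        np.nan, index=[f"v{i}" for i in range(n)], columns=list(registry.names)
    )
    X["TLOD"] = np.where(y == 1, rng.normal(30, 3, n), rng.normal(5, 3, n))
    X["SA_MAP_AF_2"] = np.where(y == 1, rng.normal(0.4, 0.05, n), rng.normal(0.05, 0.05, n))
    labels = np.where(y == 1, "signal", "noise").astype(object)
    return X, labels, registry


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Six-sample simulated cohort shared across read-only tests."""
    out = tmp_path_factory.mktemp("cohort")
    config = CohortSimConfig(n_samples=6, seed=3)
    return simulate_cohort(config, out)
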