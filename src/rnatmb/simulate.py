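"""Synthetic paired RNA-seq / WES tumor callset generator with known truth.

Each simulated sample carries four variant classes:

* **somatic** — the quantity TMB measures; per-sample counts are Poisson with
  mean = (true TMB) x (region megabases), true TMB drawn log-normally;
* **germline** — common variants carrying dbSNP identifiers and ExAC
  population frequencies, which tumor-only pipelines must filter out;
* **ffpe_artifact** — formalin-fixation damage, strongly C>T (G>A) enriched,
  present only in the RNA-seq callset;
* **rna_noise** — residual RNA-seq-specific calling noise.

The WES callset contains somatic and germline variants (germline flagged
non-PASS when a matched normal is modeled).  The RNA-seq callset applies a
depth-dependent detection curve to somatic and germline variants — a
saturating function of mean gene-mapped reads — plus the artifact and noise
classes.  Depth affects only detection thinning and the AD/DP fields, never
the underlying truth, so sweeping depth isolates the coverage effect.

Thinning is coupled across depth levels: each true variant draws one uniform
``u`` and is detected at depth d iff ``u < p_detect(d)``, so a deeper run
detects a superset of a shallower run, per sample, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .vcf_io import (
    ANNOT_DBSNP,
    ANNOT_EXAC_ALL,
    ANNOT_EXAC_NONTCGA,
    Callset,
    ContractError,
    RegionSet,
    VariantRecord,
    write_callset,
    write_regions,
)

VARIANT_CLASSES = ("somatic", "germline", "ffpe_artifact", "rna_noise")

_BASES = "ACGT"


def default_exome_regions(total_mb: float = 3.0, n_intervals: int = 66) -> RegionSet:
    """Exonic-style intervals spread over chr1-chr22 totaling ``total_mb``."""
    length = int(total_mb * 1e6) // n_intervals
    intervals = []
    for i in range(n_intervals):
        chrom = f"chr{(i % 22) + 1}"
        start = 1_000_000 + (i // 22) * 5_000_000
        intervals.append((chrom, start, start + length))
    return RegionSet(intervals)


@dataclass
class CohortSimConfig:
    """Study conditions for the paired-callset simulator.

    Defaults emulate a desk-scale version of an FFPE tumor cohort: a 3 Mb
    analyzed exonic footprint, log-normal true TMB with median 5 Mut/Mb
    (about a quarter of samples above 10, matching pan-cancer FFPE cohorts),
    a heavy germline background, C>T-enriched FFPE artifacts, and a
    saturating detection curve in mean gene-mapped reads spanning the
    ~11M / ~23M / ~68M read regimes.
    """

    n_samples: int = 40
    regions: RegionSet = field(default_factory=default_exome_regions)
    # true-TMB distribution (mutations per Mb)
    tmb_median: float = 5.0
    tmb_sigma: float = 1.0
    high_tmb_fraction: float | None = None  # optional forced fraction >= 10
    # germline background
    germline_per_mb: float = 150.0
    germline_dbsnp_prob: float = 0.95
    germline_rare_prob: float = 0.02  # fraction absent from ExAC
    # FFPE artifacts and RNA-seq noise (RNA-seq callset only)
    ffpe_artifact_per_mb: float = 30.0
    ffpe_ct_fraction: float = 0.8
    rna_noise_per_mb: float = 20.0
    somatic_indel_fraction: float = 0.10
    noise_indel_fraction: float = 0.05
    # depth / detection model
    mean_gene_mapped_reads: float = 23e6
    detection_half_saturation: float = 15e6
    detection_max: float = 0.95
    wes_detection_prob: float = 1.0
    # class-conditional TLOD log-normal (log-mean, log-sd)
    tlod_params: dict = field(
        default_factory=lambda: {
            "somatic": (3.4, 0.8),
            "germline": (3.7, 0.8),
            "ffpe_artifact": (2.1, 0.8),
            "rna_noise": (1.6, 0.8),
        }
    )
    wes_mode: str = "matched"  # "matched" or "tumor_only"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "germline_per_mb",
            "ffpe_artifact_per_mb",
            "rna_noise_per_mb",
        ):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be >= 0")
        for name in ("germline_dbsnp_prob", "germline_rare_prob", "ffpe_ct_fraction",
                     "detection_max", "wes_detection_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ContractError(f"{name} must be in [0,1]")
        if self.n_samples < 0:
            raise ContractError("n_samples must be >= 0")
        if self.tmb_median <= 0 or self.tmb_sigma <= 0:
            raise ContractError("tmb_median and tmb_sigma must be positive")
        if self.mean_gene_mapped_reads <= 0 or self.detection_half_saturation < 0:
            raise ContractError("depth parameters must be positive")
        if self.wes_mode not in ("matched", "tumor_only"):
            raise ContractError("wes_mode must be 'matched' or 'tumor_only'")

    def detection_probability(self, mean_reads: float) -> float:
        """Monotone saturating detection curve in mean gene-mapped reads."""
        if mean_reads <= 0:
            raise ContractError("mean reads must be positive")
        return self.detection_max * mean_reads / (mean_reads + self.detection_half_saturation)


@dataclass
class _SimVariant:
    """Skeleton record: everything about a variant except depth-dependent
    fields, frozen before any depth level is emitted."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str
    vaf: float
    tlod: float
    u_detect: float  # coupling uniform for depth thinning
    u_wes: float
    rna_filters: frozenset
    rsid: str | None = None
    exac_freq: float | None = None
    mbq: float = 30.0
    mmq: float = 60.0
    mpos: float = 25.0
    ecnt: int = 1
    popaf: float = 6.0
    sa_present: bool = True
    sa_map_af: tuple[float, float] = (0.0, 0.0)
    mfrl: tuple[float, float] = (180.0, 180.0)


@dataclass
class SimulatedCohort:
    sample_ids: list[str]
    rnaseq_paths: dict[str, Path]
    wes_paths: dict[str, Path]
    bed_path: Path
    truth: pd.DataFrame
    true_tmb: dict[str, float]
    regions: RegionSet
    config: CohortSimConfig
    mean_reads: float

    @property
    def wes_source(self) -> str:
        return "wes_matched" if self.config.wes_mode == "matched" else "wes_tumor_only"


# ---------------------------------------------------------------------------
# skeleton construction


def _draw_position(regions: RegionSet, used: set, rng) -> tuple[str, int]:
    lengths = np.array([end - start for _, start, end in regions.intervals])
    cum = np.cumsum(lengths)
    for _ in range(200):
        offset = int(rng.integers(0, cum[-1]))
        idx = int(np.searchsorted(cum, offset, side="right"))
        chrom, start, _ = regions.intervals[idx]
        base = offset - (cum[idx - 1] if idx else 0)
        pos = start + base + 1  # 1-based
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos
    raise ContractError("region set too small for requested variant density")


def _substitution(rng) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = ref
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _ct_substitution(rng) -> tuple[str, str]:
    return ("C", "T") if rng.random() < 0.5 else ("G", "A")


def _indel(rng) -> tuple[str, str]:
    anchor = _BASES[rng.integers(4)]
    extra = _BASES[rng.integers(4)]
    if rng.random() < 0.5:
        return anchor, anchor + extra  # insertion
    return anchor + extra, anchor  # deletion


def _alleles(var_class: str, config: CohortSimConfig, rng) -> tuple[str, str]:
    if var_class == "ffpe_artifact":
        if rng.random() < config.ffpe_ct_fraction:
            return _ct_substitution(rng)
        return _substitution(rng)
    if var_class == "somatic" and rng.random() < config.somatic_indel_fraction:
        return _indel(rng)
    if var_class == "rna_noise" and rng.random() < config.noise_indel_fraction:
        return _indel(rng)
    return _substitution(rng)


def _rna_filters(var_class: str, rng) -> frozenset:
    u = rng.random()
    if var_class in ("somatic", "germline"):
        # tumor-only callers flag most real variants germline_risk
        if u < 0.70:
            return frozenset({"germline_risk"})
        if u < 0.95:
            return frozenset()
        return frozenset({"panel_of_normals", "germline_risk"})
    # artifacts/noise: most slip past the caller's own filters
    if u < 0.55:
        return frozenset({"germline_risk"})
    if u < 0.70:
        return frozenset()
    if u < 0.85:
        return frozenset({"base_qual"})
    return frozenset({"weak_evidence"})


_VAF_BETA = {
    "somatic": (8.0, 14.0),  # mean ~0.36, subclonal spread
    "germline": (20.0, 20.0),  # mean 0.5, het
    "ffpe_artifact": (2.0, 18.0),  # mean 0.10
    "rna_noise": (2.0, 23.0),  # mean 0.08
}


def _true_tmb_draw(config: CohortSimConfig, rng) -> float:
    mu = float(np.log(config.tmb_median))
    draw = lambda: float(rng.lognormal(mu, config.tmb_sigma))
    if config.high_tmb_fraction is None:
        return draw()
    want_high = rng.random() < config.high_tmb_fraction
    for _ in range(10_000):
        val = draw()
        if (val >= 10) == want_high:
            return val
    return val


def _make_variant(
    sample_id: str,
    var_class: str,
    config: CohortSimConfig,
    used: set,
    rng,
    rs_counter: list,
) -> _SimVariant:
    chrom, pos = _draw_position(config.regions, used, rng)
    ref, alt = _alleles(var_class, config, rng)
    a, b = _VAF_BETA[var_class]
    vaf = float(np.clip(rng.beta(a, b), 0.01, 0.99))
    log_mu, log_sd = config.tlod_params[var_class]
    tlod = float(rng.lognormal(log_mu, log_sd))
    rsid = None
    exac = None
    if var_class == "germline":
        if rng.random() >= config.germline_rare_prob:
            exac = float(10 ** rng.uniform(-4.0, np.log10(0.5)))
        if rng.random() < config.germline_dbsnp_prob:
            rs_counter[0] += 1
            rsid = f"rs{100000 + rs_counter[0]}"
    real = var_class in ("somatic", "germline")
    if real:
        sa_map_af = (float(rng.uniform(0.0, 0.05)), vaf)
        mbq = float(rng.normal(32.0, 2.5))
        mpos = float(rng.normal(25.0, 6.0))
    else:
        # artifact model fits better than the no-artifact model
        sa_map_af = (vaf, float(rng.uniform(0.0, 0.05)))
        mbq = float(rng.normal(26.0, 3.5))
        mpos = float(rng.normal(12.0, 6.0))
    popaf = float(rng.uniform(0.3, 3.0)) if var_class == "germline" else float(
        rng.uniform(5.0, 7.3)
    )
    return _SimVariant(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        var_class=var_class,
        vaf=vaf,
        tlod=tlod,
        u_detect=float(rng.random()),
        u_wes=float(rng.random()),
        rna_filters=_rna_filters(var_class, rng),
        rsid=rsid,
        exac_freq=exac,
        mbq=max(2.0, mbq),
        mmq=float(np.clip(rng.normal(58.0, 3.0), 20.0, 60.0)),
        mpos=max(1.0, mpos),
        ecnt=1 + int(rng.poisson(0.3)),
        popaf=popaf,
        sa_present=bool(rng.random() < 0.9),
        sa_map_af=sa_map_af,
        mfrl=(float(rng.normal(180, 15)), float(rng.normal(180, 15))),
    )


def _build_skeleton(
    config: CohortSimConfig, rng
) -> tuple[list[str], dict[str, list[_SimVariant]], dict[str, float]]:
    mb = config.regions.total_megabases
    if mb <= 0:
        raise ContractError("region set has zero area")
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    variants: dict[str, list[_SimVariant]] = {}
    true_tmb: dict[str, float] = {}
    rs_counter = [0]
    for sid in sample_ids:
        used: set = set()
        target = _true_tmb_draw(config, rng)
        n_somatic = int(rng.poisson(target * mb))
        counts = {
            "somatic": n_somatic,
            "germline": int(rng.poisson(config.germline_per_mb * mb)),
            "ffpe_artifact": int(rng.poisson(config.ffpe_artifact_per_mb * mb)),
            "rna_noise": int(rng.poisson(config.rna_noise_per_mb * mb)),
        }
        sample_variants = []
        for var_class in VARIANT_CLASSES:
            for _ in range(counts[var_class]):
                sample_variants.append(
                    _make_variant(sid, var_class, config, used, rng, rs_counter)
                )
        variants[sid] = sample_variants
        true_tmb[sid] = n_somatic / mb  # truth is the realized count
    return sample_ids, variants, true_tmb


# ---------------------------------------------------------------------------
# emission at one depth level


def _depths(vaf: float, mean_reads: float, rng) -> tuple[int, int]:
    """Overdispersed site depth scaled with mean reads, AD split by VAF."""
    mu = max(2.0, mean_reads / 1e6)
    lam = rng.gamma(2.0, mu / 2.0)
    dp = 1 + int(rng.poisson(lam))
    ad_alt = max(1, int(rng.binomial(dp, vaf)))
    ad_alt = min(ad_alt, dp)
    return dp - ad_alt, ad_alt


def _record(
    sv: _SimVariant,
    filters: frozenset,
    ad_ref: int,
    ad_alt: int,
    rng,
    annotate_exac_all: bool,
) -> VariantRecord:
    dp = ad_ref + ad_alt
    f1r2_alt = int(rng.binomial(ad_alt, 0.5))
    f1r2_ref = int(rng.binomial(ad_ref, 0.5))
    caller_info = {
        "TLOD": round(sv.tlod, 3),
        "ECNT": float(sv.ecnt),
        "POPAF": round(sv.popaf, 3),
        "GERMQ": float(int(np.clip(sv.tlod * 2, 1, 93))),
        "MBQ": round(sv.mbq, 1),
        "MMQ": round(sv.mmq, 1),
        "MPOS": round(sv.mpos, 1),
        "MFRL_ref": round(sv.mfrl[0], 1),
        "MFRL_alt": round(sv.mfrl[1], 1),
        "AD_ref": float(ad_ref),
        "AD_alt": float(ad_alt),
        "AF": round(ad_alt / dp, 4) if dp else 0.0,
        "DP": float(dp),
        "F1R2_ref": float(f1r2_ref),
        "F1R2_alt": float(f1r2_alt),
        "F2R1_ref": float(ad_ref - f1r2_ref),
        "F2R1_alt": float(ad_alt - f1r2_alt),
    }
    if sv.sa_present:
        caller_info["SA_MAP_AF_1"] = round(sv.sa_map_af[0], 4)
        caller_info["SA_MAP_AF_2"] = round(sv.sa_map_af[1], 4)
        caller_info["SA_POST_PROB_1"] = round(
            float(np.clip(sv.sa_map_af[0] / (sv.sa_map_af[0] + sv.sa_map_af[1] + 1e-9), 0, 1)), 4
        )
        caller_info["SA_POST_PROB_2"] = round(
            1.0 - caller_info["SA_POST_PROB_1"], 4
        )
    annotations: dict[str, object] = {}
    if sv.exac_freq is not None:
        annotations[ANNOT_EXAC_NONTCGA] = sv.exac_freq
        if annotate_exac_all:
            annotations[ANNOT_EXAC_ALL] = sv.exac_freq
    if sv.rsid is not None:
        annotations[ANNOT_DBSNP] = sv.rsid
    return VariantRecord(
        chrom=sv.chrom,
        pos=sv.pos,
        ref=sv.ref,
        alt=sv.alt,
        rsid=sv.rsid,
        filter_labels=filters,
        caller_info=caller_info,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        annotations=annotations,
        sample_id=sv.sample_id,
    )


def _emit_cohort(
    sample_ids: list[str],
    skeleton: dict[str, list[_SimVariant]],
    true_tmb: dict[str, float],
    config: CohortSimConfig,
    mean_reads: float,
    out_dir: Path,
    rng,
) -> SimulatedCohort:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p_detect = config.detection_probability(mean_reads)
    wes_source = "wes_matched" if config.wes_mode == "matched" else "wes_tumor_only"
    rnaseq_paths: dict[str, Path] = {}
    wes_paths: dict[str, Path] = {}
    truth_rows = []
    for sid in sample_ids:
        rna_records, wes_records = [], []
        for sv in skeleton[sid]:
            in_wes = in_rna = False
            if sv.var_class in ("somatic", "germline"):
                if sv.var_class == "germline" or sv.u_wes < config.wes_detection_prob:
                    in_wes = True
                    if sv.var_class == "germline" and config.wes_mode == "matched":
                        wes_filters = frozenset({"germline_risk"})
                    else:
                        wes_filters = frozenset()
                    ad_ref, ad_alt = _depths(sv.vaf, 100e6, rng)
                    wes_records.append(
                        _record(sv, wes_filters, ad_ref, ad_alt, rng,
                                annotate_exac_all=True)
                    )
                in_rna = sv.u_detect < p_detect
            else:
                in_rna = True
            if in_rna:
                ad_ref, ad_alt = _depths(sv.vaf, mean_reads, rng)
                rna_records.append(
                    _record(sv, sv.rna_filters, ad_ref, ad_alt, rng,
                            annotate_exac_all=False)
                )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "chrom": sv.chrom,
                    "pos": sv.pos,
                    "ref": sv.ref,
                    "alt": sv.alt,
                    "var_class": sv.var_class,
                    "emitted_wes": in_wes,
                    "emitted_rnaseq": in_rna,
                }
            )
        rna_callset = Callset(
            sample_id=sid,
            source="rnaseq_tumor_only",
            variants=sorted(rna_records, key=VariantRecord.sort_key),
            provenance=["simulate_cohort"],
        )
        wes_callset = Callset(
            sample_id=sid,
            source=wes_source,
            variants=sorted(wes_records, key=VariantRecord.sort_key),
            provenance=["simulate_cohort"],
        )
        rnaseq_paths[sid] = write_callset(rna_callset, out_dir / f"{sid}.rnaseq.vcf")
        wes_paths[sid] = write_callset(wes_callset, out_dir / f"{sid}.wes.vcf")
    bed_path = write_regions(config.regions, out_dir / "regions.bed")
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id", "chrom", "pos", "ref", "alt",
            "var_class", "emitted_wes", "emitted_rnaseq",
        ],
    )
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": sample_ids, "true_tmb": [true_tmb[s] for s in sample_ids]}
    ).to_csv(out_dir / "true_tmb.tsv", sep="\t", index=False)
    return SimulatedCohort(
        sample_ids=sample_ids,
        rnaseq_paths=rnaseq_paths,
        wes_paths=wes_paths,
        bed_path=bed_path,
        truth=truth,
        true_tmb=dict(true_tmb),
        regions=config.regions,
        config=config,
        mean_reads=mean_reads,
    )


# ---------------------------------------------------------------------------
# public entry points


def simulate_cohort(config: CohortSimConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate paired RNA-seq/WES VCFs, a BED region file and a truth table.

    Byte-identical output for identical config + seed.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids, skeleton, true_tmb = _build_skeleton(config, rng)
    rng_emit = np.random.default_rng([config.seed, 7])
    return _emit_cohort(
        sample_ids, skeleton, true_tmb, config,
        config.mean_gene_mapped_reads, Path(out_dir), rng_emit,
    )


def depth_sweep(
    config: CohortSimConfig,
    depth_levels: Sequence[float],
    out_dir: str | Path,
) -> dict[float, SimulatedCohort]:
    """Emit the same cohort truth at several mean-read depths.

    Truth (and every non-depth record attribute) is shared across levels;
    only detection thinning and AD/DP fields differ, and thinning is coupled
    so a deeper level detects a superset of true variants per sample.
    """
    if len(depth_levels) < 2:
        raise ContractError("depth_sweep needs at least two depth levels")
    if any(d <= 0 for d in depth_levels):
        raise ContractError("depth levels must be positive")
    rng = np.random.default_rng(config.seed)
    sample_ids, skeleton, true_tmb = _build_skeleton(config, rng)
    out_dir = Path(out_dir)
    cohorts: dict[float, SimulatedCohort] = {}
    for i, level in enumerate(depth_levels):
        rng_emit = np.random.default_rng([config.seed, 1000 + i])
        cohorts[level] = _emit_cohort(
            sample_ids, skeleton, true_tmb, config, float(level),
            out_dir / f"depth_{int(level)}", rng_emit,
        )
    return cohorts
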