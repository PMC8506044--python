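"""Tumor mutation burden: mutations per megabase of analyzed sequence.

TMB = (number of somatic variant calls inside the analyzed regions) divided
by the region size in megabases.  Substitutions and indels both count,
irrespective of functional consequence.  The denominator is always an
explicit :class:`~rnatmb.vcf_io.RegionSet`; there is no hidden default
constant, and an empty region set is refused rather than yielding infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .vcf_io import Callset, ContractError, RegionSet

TMB_MODES = ("isec", "rule", "ml", "wes_matched", "wes_tumor_only", "truth")

#: clinically relevant high/low dichotomization cutoffs (mutations per Mb)
CLINICAL_THRESHOLDS = (6, 10, 20)


@dataclass
class TMBEstimate:
    sample_id: str
    variant_count: int
    region_megabases: float
    tmb: float
    mode: str

    def __post_init__(self) -> None:
        if self.variant_count < 0:
            raise ContractError("variant_count must be nonnegative")
        if self.region_megabases <= 0:
            raise ContractError("region_megabases must be positive")


def compute_tmb(callset: Callset, regions: RegionSet, mode: str) -> TMBEstimate:
    """Count callset variants inside ``regions`` and divide by megabases.

    The callset must already be filtered per ``mode``; variants outside the
    analyzed regions are excluded from the numerator.
    """
    if mode not in TMB_MODES:
        raise ContractError(f"unknown TMB mode {mode!r}; expected one of {TMB_MODES}")
    mb = regions.total_megabases
    if mb <= 0:
        raise ContractError(
            "region set is empty: TMB denominator must be > 0 megabases"
        )
    count = sum(1 for v in callset.variants if regions.contains(v.chrom, v.pos))
    return TMBEstimate(
        sample_id=callset.sample_id,
        variant_count=count,
        region_megabases=mb,
        tmb=count / mb,
        mode=mode,
    )


def classify_tmb(tmb: float, threshold: float) -> str:
    """Dichotomize a TMB value: 'high' iff tmb >= threshold (inclusive)."""
    if tmb < 0:
        raise ContractError(f"tmb must be nonnegative, got {tmb}")
    if threshold <= 0:
        raise ContractError(f"threshold must be positive, got {threshold}")
    return "high" if tmb >= threshold else "low"
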