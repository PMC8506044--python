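"""Deterministic rule-based germline/artifact filtering recipes.

Three recipes, one per callset flavor:

* matched-normal WES — keep PASS variants only (the matched caller already
  flagged germline);
* tumor-only WES — PASS, plus population rarity (ExAC ALL < threshold) and no
  dbSNP membership;
* tumor-only RNA-seq — FILTER-label whitelist (a tumor-only caller flags most
  true somatics ``germline_risk``), non-TCGA ExAC rarity, no dbSNP membership.

A variant absent from ExAC is treated as rare: an unobserved allele passes the
frequency filter.  All filters are idempotent and only ever shrink a callset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .vcf_io import Callset, ContractError, VariantRecord

#: FoundationOne-style rarity criterion for somatic candidacy
DEFAULT_EXAC_THRESHOLD = 0.000033

#: FILTER-label sets kept by the RNA-seq tumor-only recipe.  PASS is kept by
#: default alongside the germline_risk-flagged sets; the stricter reading
#: (germline_risk-flagged only) is available by dropping the empty set.
DEFAULT_RNASEQ_WHITELIST = (
    frozenset(),
    frozenset({"germline_risk"}),
    frozenset({"panel_of_normals", "germline_risk"}),
)


@dataclass
class FilterConfig:
    exac_threshold: float = DEFAULT_EXAC_THRESHOLD
    allowed_rnaseq_filter_sets: tuple[frozenset[str], ...] = DEFAULT_RNASEQ_WHITELIST
    require_no_dbsnp: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.exac_threshold < 1):
            raise ContractError(
                f"exac_threshold must be in (0,1), got {self.exac_threshold}"
            )
        self.allowed_rnaseq_filter_sets = tuple(
            frozenset(s) for s in self.allowed_rnaseq_filter_sets
        )

    def to_dict(self) -> dict:
        return {
            "exac_threshold": self.exac_threshold,
            "allowed_rnaseq_filter_sets": [
                sorted(s) for s in self.allowed_rnaseq_filter_sets
            ],
            "require_no_dbsnp": self.require_no_dbsnp,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FilterConfig":
        kwargs = {}
        if "exac_threshold" in data:
            kwargs["exac_threshold"] = float(data["exac_threshold"])
        if "allowed_rnaseq_filter_sets" in data:
            kwargs["allowed_rnaseq_filter_sets"] = tuple(
                frozenset(s) for s in data["allowed_rnaseq_filter_sets"]
            )
        if "require_no_dbsnp" in data:
            kwargs["require_no_dbsnp"] = bool(data["require_no_dbsnp"])
        return cls(**kwargs)


def _require_source(callset: Callset, expected: str, op: str) -> None:
    if callset.source != expected:
        raise ContractError(
            f"{op} expects source {expected!r}, got {callset.source!r}"
        )


def _rare(freq: float | None, threshold: float) -> bool:
    # absent from the population resource => rare (passes), strict inequality
    return freq is None or freq < threshold


def _dbsnp_ok(v: VariantRecord, config: FilterConfig) -> bool:
    return not (config.require_no_dbsnp and v.in_dbsnp)


def filter_wes_matched(callset: Callset) -> Callset:
    """Matched-normal WES recipe: FILTER==PASS."""
    _require_source(callset, "wes_matched", "filter_wes_matched")
    kept = [v for v in callset.variants if v.is_pass]
    return callset.with_variants(kept, "filter_wes_matched:PASS")


def filter_wes_tumor_only(
    callset: Callset, config: FilterConfig | None = None
) -> Callset:
    """Tumor-only WES recipe: PASS + ExAC ALL rarity + no dbSNP identifier."""
    config = config or FilterConfig()
    _require_source(callset, "wes_tumor_only", "filter_wes_tumor_only")
    kept = [
        v
        for v in callset.variants
        if v.is_pass
        and _rare(v.exac_all, config.exac_threshold)
        and _dbsnp_ok(v, config)
    ]
    return callset.with_variants(
        kept, f"filter_wes_tumor_only:exac<{config.exac_threshold}"
    )


def filter_rnaseq_tumor_only(
    callset: Callset, config: FilterConfig | None = None
) -> Callset:
    """Tumor-only RNA-seq recipe: FILTER-label whitelist + non-TCGA ExAC
    rarity + no dbSNP identifier."""
    config = config or FilterConfig()
    _require_source(callset, "rnaseq_tumor_only", "filter_rnaseq_tumor_only")
    whitelist = set(config.allowed_rnaseq_filter_sets)
    kept = [
        v
        for v in callset.variants
        if v.filter_labels in whitelist
        and _rare(v.exac_nontcga_all, config.exac_threshold)
        and _dbsnp_ok(v, config)
    ]
    return callset.with_variants(
        kept, f"filter_rnaseq_tumor_only:exac<{config.exac_threshold}"
    )


def rule_filter(callset: Callset, config: FilterConfig | None = None) -> Callset:
    """Dispatch to the recipe matching the callset's source tag."""
    if callset.source == "wes_matched":
        return filter_wes_matched(callset)
    if callset.source == "wes_tumor_only":
        return filter_wes_tumor_only(callset, config)
    return filter_rnaseq_tumor_only(callset, config)
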