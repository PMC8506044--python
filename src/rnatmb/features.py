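"""Per-variant numeric feature construction for the noise classifier.

The default registry has 31 features: 23 taken from the caller's VCF output
(depths, allele fraction, TLOD, strand-artifact allele-fraction estimates,
median qualities, ...), one population-frequency annotation (non-TCGA ExAC),
and seven engineered from REF/ALT/AD — four Boolean flags (insertion,
deletion, C>T/G>A transition, C>A/G>T transversion) and three integers
(total depth, REF length, ALT length).

Fields absent from a record become NaN, the missing-marker the boosted-tree
ensemble handles natively; they are never imputed to zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .vcf_io import ANNOT_EXAC_NONTCGA, Callset, ContractError

CALLER_FEATURES = (
    "AD_ref",
    "AD_alt",
    "AF",
    "DP",
    "TLOD",
    "ECNT",
    "POPAF",
    "GERMQ",
    "MBQ",
    "MFRL_ref",
    "MFRL_alt",
    "MMQ",
    "MPOS",
    "SA_MAP_AF_1",
    "SA_MAP_AF_2",
    "SA_POST_PROB_1",
    "SA_POST_PROB_2",
    "F1R2_ref",
    "F1R2_alt",
    "F2R1_ref",
    "F2R1_alt",
    "NLOD",
    "SEQQ",
)

ANNOTATION_FEATURES = (ANNOT_EXAC_NONTCGA,)

ENGINEERED_FEATURES = (
    "INS",
    "DEL",
    "CT_transition",
    "CA_transversion",
    "total_depth",
    "ref_length",
    "alt_length",
)


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered feature names with per-feature origin tags."""

    names: tuple[str, ...]
    origins: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ContractError("feature names must be unique")
        missing = set(ENGINEERED_FEATURES) - set(self.names)
        if missing:
            raise ContractError(f"registry lacks engineered features: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def digest(self) -> str:
        return hashlib.sha256("\x1f".join(self.names).encode()).hexdigest()[:16]


def default_registry() -> FeatureRegistry:
    """31-feature default: 23 caller + 1 annotation + 7 engineered."""
    names = CALLER_FEATURES + ANNOTATION_FEATURES + ENGINEERED_FEATURES
    origins = {name: "caller_vcf" for name in CALLER_FEATURES}
    origins.update({name: "annotation" for name in ANNOTATION_FEATURES})
    origins.update({name: "engineered" for name in ENGINEERED_FEATURES})
    return FeatureRegistry(names=names, origins=origins)


class VariantFlags(NamedTuple):
    INS: int
    DEL: int
    CT_transition: int
    CA_transversion: int
    ref_length: int
    alt_length: int


_CT_PAIRS = {("C", "T"), ("G", "A")}
_CA_PAIRS = {("C", "A"), ("G", "T")}


def engineer_variant_flags(ref: str, alt: str) -> VariantFlags:
    """Boolean indel/substitution-type flags plus literal allele lengths.

    Transition/transversion flags apply to 1-bp substitutions only; indels
    and longer alleles get 0 for both.
    """
    if not ref or not alt:
        raise ContractError("ref and alt must be nonempty")
    ins = int(len(alt) > len(ref))
    dele = int(len(alt) < len(ref))
    is_snv = len(ref) == 1 and len(alt) == 1
    ct = int(is_snv and (ref, alt) in _CT_PAIRS)
    ca = int(is_snv and (ref, alt) in _CA_PAIRS)
    return VariantFlags(ins, dele, ct, ca, len(ref), len(alt))


def total_depth(ad_ref: int, ad_alt: int) -> int:
    """Total depth at the site from the FORMAT AD pair."""
    if ad_ref < 0 or ad_alt < 0:
        raise ContractError("AD values must be nonnegative")
    return ad_ref + ad_alt


def row_key(v) -> str:
    return f"{v.sample_id}|{v.chrom}:{v.pos}:{v.ref}>{v.alt}"


def build_feature_matrix(
    callset: Callset, registry: FeatureRegistry | None = None
) -> pd.DataFrame:
    """One row per variant (keyed by origin sample + variant key), columns in
    registry order, NaN for absent fields."""
    registry = registry or default_registry()
    keys = [row_key(v) for v in callset.variants]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})[:5]
        raise ContractError(f"duplicate feature rows: {dupes}")
    nan = float("nan")
    rows = np.full((len(keys), len(registry.names)), np.nan)
    col_idx = {name: i for i, name in enumerate(registry.names)}
    for i, v in enumerate(callset.variants):
        flags = engineer_variant_flags(v.ref, v.alt)
        values = dict(v.caller_info)
        values[ANNOT_EXAC_NONTCGA] = (
            v.exac_nontcga_all if v.exac_nontcga_all is not None else nan
        )
        values.update(flags._asdict())
        if v.ad_ref is not None and v.ad_alt is not None:
            values["total_depth"] = total_depth(v.ad_ref, v.ad_alt)
        for name, j in col_idx.items():
            val = values.get(name)
            if val is not None:
                rows[i, j] = val
    return pd.DataFrame(rows, index=pd.Index(keys, name="variant"), columns=list(registry.names))
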