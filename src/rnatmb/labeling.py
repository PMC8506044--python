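"""Signal/noise training labels from the WES gold-standard callset.

An RNA-seq variant is labeled *signal* when the (already filtered) WES
callset of the same sample contains a variant at the same genomic
coordinate; everything else is *noise*.  Coordinate-only matching is the
default labeling rule; full-key matching (chrom, pos, ref, alt) is exposed
for the stricter intersection semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .vcf_io import MATCH_MODES, Callset, ContractError

logger = logging.getLogger(__name__)

SIGNAL = "signal"
NOISE = "noise"


@dataclass
class LabeledCallset:
    callset: Callset
    labels: np.ndarray  # dtype=object of {"signal","noise"}, one per variant
    match_mode: str

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.callset):
            raise ContractError("labels must align 1:1 with variants")

    @property
    def n_signal(self) -> int:
        return int(np.sum(self.labels == SIGNAL))

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))

    def binary(self) -> np.ndarray:
        """1 for signal, 0 for noise."""
        return (self.labels == SIGNAL).astype(int)


def label_by_wes(
    rnaseq: Callset,
    wes: Callset | Mapping[str, Callset],
    match_mode: str = "coordinate_only",
) -> LabeledCallset:
    """Label each RNA-seq variant signal/noise by WES cross-reference.

    For a pooled (merged) RNA-seq callset, pass a mapping of sample id to WES
    callset: each variant is matched only against the WES callset of its
    origin sample, never across samples.
    """
    if match_mode not in MATCH_MODES:
        raise ContractError(f"unknown match_mode {match_mode!r}; expected {MATCH_MODES}")

    def ref_keys(callset: Callset) -> set:
        return callset.keys() if match_mode == "full_key" else callset.coords()

    if isinstance(wes, Callset):
        per_sample = {v.sample_id for v in rnaseq.variants}
        lookup = {sid: ref_keys(wes) for sid in per_sample} if per_sample else {}
        default = ref_keys(wes)
        total_wes = len(wes)
    else:
        missing = {v.sample_id for v in rnaseq.variants} - set(wes)
        if missing:
            raise ContractError(
                f"no WES callset for origin samples: {sorted(missing)}"
            )
        lookup = {sid: ref_keys(c) for sid, c in wes.items()}
        default = set()
        total_wes = sum(len(c) for c in wes.values())

    if total_wes == 0 and len(rnaseq) > 0:
        logger.warning(
            "WES reference is empty; labeling all %d RNA-seq variants as noise",
            len(rnaseq),
        )

    labels = np.empty(len(rnaseq), dtype=object)
    for i, v in enumerate(rnaseq.variants):
        ref = lookup.get(v.sample_id, default)
        probe = v.key if match_mode == "full_key" else v.coord
        labels[i] = SIGNAL if probe in ref else NOISE
    return LabeledCallset(callset=rnaseq, labels=labels, match_mode=match_mode)
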