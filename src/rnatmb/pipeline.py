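"""End-to-end orchestration of the three analysis modes.

Ties the stages together the way a cohort study runs them:

1. pair each tumor RNA-seq callset with its WES callset;
2. derive the WES gold standard by the applicable rule filter;
3. (ml mode) merge the training samples' unfiltered RNA-seq callsets, label
   each variant signal/noise by per-sample WES coordinate match, build the
   feature matrix, tune and train the boosted-tree classifier;
4. produce per-sample RNA-seq TMB estimates under a mode:
   ``isec`` (upper bound: variants shared with WES by full key),
   ``rule`` (deterministic filter recipe), or
   ``ml`` (classifier-filtered);
5. score concordance of RNA-seq TMB against WES TMB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classifier import (
    ClassifierModel,
    SearchConfig,
    apply_ml_filter,
    train_noise_classifier,
)
from .concordance import ConcordanceReport, build_concordance_report
from .features import FeatureRegistry, build_feature_matrix, default_registry
from .filters import FilterConfig, filter_rnaseq_tumor_only, rule_filter
from .labeling import LabeledCallset, label_by_wes
from .simulate import SimulatedCohort
from .tmb import TMBEstimate, compute_tmb
from .vcf_io import Callset, ContractError, intersect_callsets, merge_callsets, read_callset

logger = logging.getLogger(__name__)

ANALYSIS_MODES = ("isec", "rule", "ml")


def load_cohort_callsets(
    cohort: SimulatedCohort, sample_ids: Sequence[str] | None = None
) -> tuple[dict[str, Callset], dict[str, Callset]]:
    """Re-ingest a simulated cohort's VCFs (RNA-seq, WES) per sample."""
    ids = list(sample_ids) if sample_ids is not None else cohort.sample_ids
    rna = {s: read_callset(cohort.rnaseq_paths[s], "rnaseq_tumor_only") for s in ids}
    wes = {s: read_callset(cohort.wes_paths[s], cohort.wes_source) for s in ids}
    return rna, wes


def wes_gold_standard(
    wes: Mapping[str, Callset], filter_config: FilterConfig | None = None
) -> dict[str, Callset]:
    """Filter each WES callset by the recipe matching its source tag."""
    return {sid: rule_filter(c, filter_config) for sid, c in wes.items()}


def train_from_cohort(
    rna: Mapping[str, Callset],
    wes_filtered: Mapping[str, Callset],
    train_ids: Sequence[str],
    seed: int = 0,
    search: SearchConfig | None = None,
    registry: FeatureRegistry | None = None,
    match_mode: str = "coordinate_only",
) -> tuple[ClassifierModel, LabeledCallset]:
    """Merge training RNA-seq callsets, label against per-sample WES, train."""
    missing = [s for s in train_ids if s not in rna]
    if missing:
        raise ContractError(f"no RNA-seq callset for training samples: {missing}")
    merged = merge_callsets([rna[s] for s in train_ids])
    labeled = label_by_wes(
        merged, {s: wes_filtered[s] for s in train_ids}, match_mode
    )
    registry = registry or default_registry()
    features = build_feature_matrix(merged, registry)
    model = train_noise_classifier(
        features, labeled.labels, search=search, seed=seed, registry=registry
    )
    return model, labeled


def rnaseq_tmb_by_mode(
    rna: Mapping[str, Callset],
    cohort: SimulatedCohort,
    mode: str,
    wes_filtered: Mapping[str, Callset] | None = None,
    filter_config: FilterConfig | None = None,
    model: ClassifierModel | None = None,
    cutoff: float = 0.5,
) -> dict[str, TMBEstimate]:
    """Per-sample RNA-seq TMB estimates under isec / rule / ml filtering."""
    if mode not in ANALYSIS_MODES:
        raise ContractError(f"unknown analysis mode {mode!r}; expected {ANALYSIS_MODES}")
    out: dict[str, TMBEstimate] = {}
    for sid, callset in rna.items():
        if mode == "isec":
            if wes_filtered is None or sid not in wes_filtered:
                raise ContractError(f"isec mode needs the WES callset for {sid}")
            filtered = intersect_callsets(callset, wes_filtered[sid], "full_key")
        elif mode == "rule":
            filtered = filter_rnaseq_tumor_only(callset, filter_config)
        else:
            if model is None:
                raise ContractError("ml mode needs a trained model")
            filtered = apply_ml_filter(callset, model, cutoff)
        out[sid] = compute_tmb(filtered, cohort.regions, mode)
    return out


def wes_tmb(
    wes_filtered: Mapping[str, Callset], cohort: SimulatedCohort
) -> dict[str, TMBEstimate]:
    return {
        sid: compute_tmb(c, cohort.regions, cohort.wes_source)
        for sid, c in wes_filtered.items()
    }


@dataclass
class CohortEvaluation:
    mode: str
    report: ConcordanceReport
    rnaseq_tmb: dict[str, TMBEstimate]
    wes_tmb: dict[str, TMBEstimate]
    model: ClassifierModel | None = None

    def correlation_with(self, reference: Mapping[str, float]) -> float:
        """Pearson r of the mode's RNA-seq TMB against an external per-sample
        reference (e.g. simulator truth)."""
        ids = sorted(set(self.rnaseq_tmb) & set(reference))
        x = [self.rnaseq_tmb[s].tmb for s in ids]
        y = [reference[s] for s in ids]
        from .concordance import correlation

        return correlation(x, y, "pearson")[0]


def split_samples(
    sample_ids: Sequence[str], train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Deterministic random train/test split of cohort sample ids."""
    if not (0 < train_fraction < 1):
        raise ContractError("train_fraction must be in (0,1)")
    ids = list(sample_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = max(1, int(round(train_fraction * len(ids))))
    n_train = min(n_train, len(ids) - 1)
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def evaluate_cohort(
    cohort: SimulatedCohort,
    mode: str,
    seed: int = 0,
    filter_config: FilterConfig | None = None,
    search: SearchConfig | None = None,
    cutoff: float = 0.5,
    train_fraction: float = 0.5,
    thresholds: Sequence[float] = (6, 10, 20),
) -> CohortEvaluation:
    """Run one analysis mode end to end on a simulated cohort.

    In ml mode the cohort is split into training and held-out samples; the
    concordance report covers the held-out samples only (train on one subset,
    estimate TMB on the other).  isec and rule modes use all samples.
    """
    rna, wes = load_cohort_callsets(cohort)
    gold = wes_gold_standard(wes, filter_config)
    model = None
    if mode == "ml":
        train_ids, test_ids = split_samples(cohort.sample_ids, train_fraction, seed)
        model, _ = train_from_cohort(
            rna, gold, train_ids, seed=seed, search=search
        )
        eval_ids = test_ids
    else:
        eval_ids = list(cohort.sample_ids)
    rna_eval = {s: rna[s] for s in eval_ids}
    gold_eval = {s: gold[s] for s in eval_ids}
    rna_tmb = rnaseq_tmb_by_mode(
        rna_eval, cohort, mode,
        wes_filtered=gold_eval, filter_config=filter_config,
        model=model, cutoff=cutoff,
    )
    wes_estimates = wes_tmb(gold_eval, cohort)
    report = build_concordance_report(rna_tmb, wes_estimates, thresholds, mode)
    return CohortEvaluation(
        mode=mode,
        report=report,
        rnaseq_tmb=rna_tmb,
        wes_tmb=wes_estimates,
        model=model,
    )
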