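"""Concordance between RNA-seq-derived and WES-derived TMB across a cohort.

WES-TMB is the gold standard: per-threshold high/low labels are always
derived from the WES values, and the raw RNA-seq TMB values are the scores.
ROC AUC uses the rank (Mann-Whitney) formulation: the probability that a
random positive outranks a random negative, ties counted 1/2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .tmb import CLINICAL_THRESHOLDS, TMBEstimate, classify_tmb
from .vcf_io import ContractError


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Product-moment or rank correlation with a two-sided p-value.

    Spearman uses mid-ranks for ties.  A constant vector has no defined
    correlation: returns (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method not in ("pearson", "spearman"):
        raise ContractError(f"unknown correlation method {method!r}")
    if len(x) != len(y) or len(x) < 3:
        raise ContractError("correlation needs two aligned vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ContractError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    if method == "pearson":
        res = scipy.stats.pearsonr(x, y)
    else:
        res = scipy.stats.spearmanr(x, y)
    return (float(res.statistic), float(res.pvalue))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via mid-ranks: P(score_pos > score_neg) + P(equal)/2.

    Returns nan when either class is absent (not applicable).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(scores) != len(y):
        raise ContractError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class ConcordanceReport:
    pairs: pd.DataFrame  # columns: sample_id, rnaseq_tmb, wes_tmb, mode
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    auc_by_threshold: dict[float, float] = field(default_factory=dict)
    positives_by_threshold: dict[float, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        # not-applicable values (NaN) serialize as JSON null
        clean = lambda v: None if (isinstance(v, float) and np.isnan(v)) else v
        return {
            "pairs": self.pairs.to_dict(orient="records"),
            "pearson_r": clean(self.pearson_r),
            "pearson_p": clean(self.pearson_p),
            "spearman_rho": clean(self.spearman_rho),
            "spearman_p": clean(self.spearman_p),
            "auc_by_threshold": {
                str(k): clean(v) for k, v in self.auc_by_threshold.items()
            },
            "positives_by_threshold": {
                str(k): v for k, v in self.positives_by_threshold.items()
            },
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ConcordanceReport":
        data = json.loads(Path(path).read_text())
        restore = lambda v: float("nan") if v is None else v
        return cls(
            pairs=pd.DataFrame(
                data["pairs"], columns=["sample_id", "rnaseq_tmb", "wes_tmb", "mode"]
            ),
            pearson_r=restore(data["pearson_r"]),
            pearson_p=restore(data["pearson_p"]),
            spearman_rho=restore(data["spearman_rho"]),
            spearman_p=restore(data["spearman_p"]),
            auc_by_threshold={
                float(k): restore(v) for k, v in data["auc_by_threshold"].items()
            },
            positives_by_threshold={
                float(k): v for k, v in data["positives_by_threshold"].items()
            },
        )


def _tmb_values(estimates: Mapping[str, TMBEstimate | float]) -> dict[str, float]:
    return {
        sid: est.tmb if isinstance(est, TMBEstimate) else float(est)
        for sid, est in estimates.items()
    }


def build_concordance_report(
    rnaseq_tmbs: Mapping[str, TMBEstimate | float],
    wes_tmbs: Mapping[str, TMBEstimate | float],
    thresholds: Sequence[float] = CLINICAL_THRESHOLDS,
    mode: str = "rule",
) -> ConcordanceReport:
    """Correlations plus per-threshold ROC AUC of RNA-seq TMB against
    WES-defined high/low classes, samples aligned by id."""
    rna = _tmb_values(rnaseq_tmbs)
    wes = _tmb_values(wes_tmbs)
    if set(rna) != set(wes):
        only_rna = sorted(set(rna) - set(wes))
        only_wes = sorted(set(wes) - set(rna))
        raise ContractError(
            f"sample id mismatch: only in RNA-seq {only_rna}; only in WES {only_wes}"
        )
    ids = sorted(rna)
    x = np.array([rna[s] for s in ids])
    y = np.array([wes[s] for s in ids])
    pearson = correlation(x, y, "pearson")
    spearman = correlation(x, y, "spearman")
    aucs: dict[float, float] = {}
    positives: dict[float, int] = {}
    for thr in thresholds:
        labels = np.array([1 if classify_tmb(v, thr) == "high" else 0 for v in y])
        positives[float(thr)] = int(labels.sum())
        aucs[float(thr)] = roc_auc(x, labels)
    pairs = pd.DataFrame(
        {"sample_id": ids, "rnaseq_tmb": x, "wes_tmb": y, "mode": mode}
    )
    return ConcordanceReport(
        pairs=pairs,
        pearson_r=pearson[0],
        pearson_p=pearson[1],
        spearman_rho=spearman[0],
        spearman_p=spearman[1],
        auc_by_threshold=aucs,
        positives_by_threshold=positives,
    )
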