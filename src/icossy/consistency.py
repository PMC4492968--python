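"""10-fold cross-validated MIS frequency ranking.

A single full-data ranking can be swayed by a handful of samples.  To find
the subnetworks that are *consistently* highly ranked, the samples are
randomly divided into ``folds`` stratified sets; in each fold one set is
held out and the ranking runs on the remaining samples.  Each MIS is then
scored by its frequency — the number of folds in which it appears in the
fold's top-K list — and frequency ties are broken by mean entropy over the
folds (then mis_id).  Normalization happens once before CV: the fuzzy rank
transform is per-sample, so no cross-sample statistic leaks from held-out
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import ChipMap, ExpressionMatrix, PhenotypeLabels
from .network import MIS
from .scoring import rank_mis

logger = logging.getLogger("icossy")

__all__ = ["CVResult", "make_folds", "cv_rank"]


@dataclass
class CVResult:
    folds: int
    per_fold_top: list[list[str]]
    frequency: dict[str, int]
    mean_entropy: dict[str, float]
    final_ranking: list[str]


def make_folds(labels: PhenotypeLabels, folds: int = 10, seed: int = 0) -> list[list[str]]:
    """Partition samples into stratified disjoint subsets, deterministically.

    Per-fold class counts differ from exact proportionality by at most one.
    If a class has fewer samples than requested folds, the fold count is
    reduced to the smallest class size (logged).
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    counts = labels.class_counts()
    min_count = min(counts.values())
    if min_count < 2:
        raise ValueError(f"each class needs >= 2 samples, got {counts}")
    if folds > min_count:
        logger.warning("reducing folds from %d to %d (smallest class size)", folds, min_count)
        folds = min_count
    y = np.asarray(labels.labels())
    samples = np.asarray(labels.sample_ids)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    return [[str(s) for s in samples[test_idx]] for _, test_idx in skf.split(samples, y)]


def cv_rank(
    all_mis: list[MIS],
    m: ExpressionMatrix,
    chip: ChipMap,
    labels: PhenotypeLabels,
    K: int = 10,
    folds: int = 10,
    seed: int = 0,
    stat: str = "welch_p",
) -> CVResult:
    """Rank MISs by cross-validated top-K frequency.

    In each fold the held-out set is excluded and the regular ranking runs on
    the retained samples; the first K mis_ids form that fold's top list.  The
    final ranking sorts by (frequency desc, mean entropy asc, mis_id); its
    top K is the model output.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    fold_sets = make_folds(labels, folds=folds, seed=seed)
    n_folds = len(fold_sets)
    per_fold_top: list[list[str]] = []
    entropy_acc: dict[str, list[float]] = {}
    for i, held_out in enumerate(fold_sets):
        held = set(held_out)
        train_ids = [s for s in labels.sample_ids if s not in held]
        sub_labels = labels.subset(train_ids)
        if len(set(sub_labels.labels())) < 2:  # unreachable with stratified folds
            logger.warning("fold %d lost a class; regenerating folds", i)
            return cv_rank(all_mis, m, chip, labels, K, folds, seed + 7919, stat)
        sub_m = m.subset_samples(train_ids)
        scores = rank_mis(all_mis, sub_m, chip, sub_labels, stat=stat, seed=seed + i)
        per_fold_top.append([s.mis_id for s in scores[:K]])
        for s in scores:
            entropy_acc.setdefault(s.mis_id, []).append(s.entropy)
    frequency = {mid: 0 for mid in entropy_acc}
    for top in per_fold_top:
        for mid in top:
            frequency[mid] += 1
    mean_entropy = {mid: float(np.mean(v)) for mid, v in entropy_acc.items()}
    final = sorted(frequency, key=lambda mid: (-frequency[mid], mean_entropy[mid], mid))
    return CVResult(n_folds, per_fold_top, frequency, mean_entropy, final)
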