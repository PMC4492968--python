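"""Entropy-based MIS scoring.

Each MIS is represented by its (up to) five most differentially expressed
probesets — by default the smallest two-sided Welch t-test p-values computed
on normalized expressions, with a robust IQR-based t variant available
behind a flag.  Samples are embedded as vectors of the representatives'
normalized expressions and partitioned into two clusters; the MIS score is
the cluster-size-weighted Shannon entropy (in bits) of the phenotype labels
within clusters.  A score of 0 means the representative expressions separate
the two phenotypes perfectly; 1 bit means the clusters are uninformative.
MISs are ranked ascending by entropy: the lower the score, the higher the
rank.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .io import ChipMap, ExpressionMatrix, PhenotypeLabels
from .network import MIS

logger = logging.getLogger("icossy")

__all__ = [
    "DEStat",
    "MISScore",
    "NoMappedProbesets",
    "welch_t",
    "iqr_t",
    "select_representatives",
    "entropy_score",
    "rank_mis",
]

#: normal-consistency constant: IQR of a normal distribution is 1.349 sigma
IQR_TO_SD = 1.349


class NoMappedProbesets(ValueError):
    """No probeset maps to any gene of the MIS."""


@dataclass(frozen=True)
class DEStat:
    """Differential-expression statistic for one probeset (class1 - class2)."""

    probeset_id: str
    t_value: float
    df: float
    p_value: float
    fold_difference: float
    gene: str = ""


@dataclass
class MISScore:
    mis_id: str
    genes: frozenset
    representatives: list
    entropy: float
    cluster_assignment: dict
    cv_frequency: int | None = None

    @property
    def mean_abs_t(self) -> float:
        finite = [abs(r.t_value) for r in self.representatives if math.isfinite(r.t_value)]
        return float(np.mean(finite)) if finite else float("inf")


def _degenerate(x: np.ndarray, y: np.ndarray, probeset_id: str, gene: str) -> DEStat:
    mx, my = float(np.mean(x)), float(np.mean(y))
    df = float(len(x) + len(y) - 2)
    if np.isclose(mx, my):
        return DEStat(probeset_id, 0.0, df, 1.0, mx - my, gene)
    logger.warning("probeset %s: zero variance in both groups with unequal means", probeset_id)
    t = math.inf if mx > my else -math.inf
    return DEStat(probeset_id, t, df, 0.0, mx - my, gene)


def _welch_from_scales(
    mx: float, my: float, vx: float, vy: float, nx_: int, ny: int
) -> tuple[float, float, float]:
    """(t, df, p) from group means and variance estimates (Welch-Satterthwaite)."""
    sx, sy = vx / nx_, vy / ny
    t = (mx - my) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (
        (sx**2 / (nx_ - 1) if sx > 0 else 0.0) + (sy**2 / (ny - 1) if sy > 0 else 0.0)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def welch_t(x, y, probeset_id: str = "", gene: str = "") -> DEStat:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean(x) - mean(y)) / sqrt(s2x/nx + s2y/ny) with sample variances and
    Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least two observations per group")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        return _degenerate(x, y, probeset_id, gene)
    t, df, p = _welch_from_scales(np.mean(x), np.mean(y), vx, vy, x.size, y.size)
    return DEStat(probeset_id, t, df, p, float(np.mean(x) - np.mean(y)), gene)


def iqr_t(x, y, probeset_id: str = "", gene: str = "") -> DEStat:
    """Robust Welch-style t with variances replaced by (IQR/1.349)^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("iqr_t requires at least two observations per group")
    s2x = (stats.iqr(x) / IQR_TO_SD) ** 2
    s2y = (stats.iqr(y) / IQR_TO_SD) ** 2
    if s2x == 0 and s2y == 0:
        return _degenerate(x, y, probeset_id, gene)
    t, df, p = _welch_from_scales(np.mean(x), np.mean(y), s2x, s2y, x.size, y.size)
    return DEStat(probeset_id, t, df, p, float(np.mean(x) - np.mean(y)), gene)


def compute_de_stats(
    m: ExpressionMatrix,
    chip: ChipMap,
    labels: PhenotypeLabels,
    stat: str = "welch_p",
    probesets=None,
) -> list[DEStat]:
    """Per-probeset differential-expression statistics on normalized values."""
    if stat not in {"welch_p", "iqr_t"}:
        raise ValueError(f"unknown statistic {stat!r}")
    fn = welch_t if stat == "welch_p" else iqr_t
    cls1, cls2 = labels.class_names
    idx1 = [m.sample_ids.index(s) for s in labels.samples_of(cls1)]
    idx2 = [m.sample_ids.index(s) for s in labels.samples_of(cls2)]
    values = m.values
    row_pos = {r: i for i, r in enumerate(m.row_ids)}
    out = []
    for probe in probesets if probesets is not None else m.row_ids:
        i = row_pos.get(probe)
        if i is None:
            continue
        gene = chip.probe_to_gene.get(probe, "")
        out.append(fn(values[i, idx1], values[i, idx2], probeset_id=probe, gene=gene))
    return out


def _rep_sort_key(stat: str):
    if stat == "welch_p":
        return lambda d: (d.p_value, -abs(d.t_value), d.probeset_id)
    return lambda d: (-abs(d.t_value), d.p_value, d.probeset_id)


def select_representatives(
    mis: MIS,
    m: ExpressionMatrix,
    chip: ChipMap,
    labels: PhenotypeLabels,
    stat: str = "welch_p",
    n_representatives: int = 5,
) -> list[DEStat]:
    """The five most differentially expressed probesets mapping to MIS genes.

    Candidates are ranked by ascending p-value (``welch_p``) or descending
    |t| (``iqr_t``); ties break by the other statistic, then probeset id.
    """
    gene_to_probes = chip.gene_to_probes
    in_matrix = set(m.row_ids)
    candidates = sorted(
        p for gene in mis.genes for p in gene_to_probes.get(gene, ()) if p in in_matrix
    )
    if not candidates:
        raise NoMappedProbesets(f"{mis.mis_id}: no probeset maps to its genes")
    de = compute_de_stats(m, chip, labels, stat=stat, probesets=candidates)
    de.sort(key=_rep_sort_key(stat))
    return de[:n_representatives]


def _cluster_entropy_bits(cluster_labels: np.ndarray, class_labels: np.ndarray) -> float:
    n = class_labels.size
    total = 0.0
    for c in np.unique(cluster_labels):
        mask = cluster_labels == c
        frac = mask.sum() / n
        _, counts = np.unique(class_labels[mask], return_counts=True)
        p = counts / counts.sum()
        h = float(-(p * np.log2(p)).sum())
        total += frac * h
    return total


def entropy_score(
    reps: list[DEStat],
    m: ExpressionMatrix,
    labels: PhenotypeLabels,
    seed: int = 0,
) -> tuple[float, dict]:
    """Weighted Shannon entropy (bits) of phenotype labels within 2 sample
    clusters formed on the representatives' normalized expressions.

    Clustering is 2-means with seeded k-means++ initialization and 10
    restarts; a degenerate single-cluster outcome is retried with shifted
    seeds and finally falls back to a midpoint split on the first
    representative.
    """
    if not reps:
        raise ValueError("entropy_score needs at least one representative")
    if len(labels.sample_ids) < 4:
        raise ValueError("entropy_score needs at least four samples")
    X = np.column_stack(
        [m.data.loc[r.probeset_id, labels.sample_ids].to_numpy(dtype=float) for r in reps]
    )
    y = np.asarray(labels.labels())
    assignment = None
    for attempt in range(3):
        km = KMeans(n_clusters=2, n_init=10, random_state=(seed + 1000 * attempt) % 2**31)
        fitted = km.fit_predict(X)
        if np.unique(fitted).size == 2:
            assignment = fitted
            break
    if assignment is None:
        first = X[:, 0]
        cut = (first.min() + first.max()) / 2.0
        assignment = (first > cut).astype(int)
        if np.unique(assignment).size < 2:
            logger.warning("constant representative expressions; single-cluster entropy")
    h = _cluster_entropy_bits(assignment, y)
    return h, dict(zip(labels.sample_ids, (int(c) for c in assignment)))


def _mis_seed(seed: int, mis_id: str) -> int:
    return (seed + zlib.crc32(mis_id.encode())) % 2**31


def rank_mis(
    all_mis: list[MIS],
    m: ExpressionMatrix,
    chip: ChipMap,
    labels: PhenotypeLabels,
    stat: str = "welch_p",
    seed: int = 0,
) -> list[MISScore]:
    """Score every MIS and sort ascending by entropy.

    Ties break by larger mean |t| of the representatives, then mis_id.
    MISs with no mapped probeset are skipped with a logged reason.
    """
    scores: list[MISScore] = []
    for mis in sorted(all_mis, key=lambda x: x.mis_id):
        try:
            reps = select_representatives(mis, m, chip, labels, stat=stat)
        except NoMappedProbesets as exc:
            logger.info("skipping %s: %s", mis.mis_id, exc)
            continue
        h, assignment = entropy_score(reps, m, labels, seed=_mis_seed(seed, mis.mis_id))
        scores.append(MISScore(mis.mis_id, mis.genes, reps, h, assignment))
    if not scores:
        raise ValueError("no MIS could be scored: no probesets map to any MIS gene")
    scores.sort(key=lambda s: (s.entropy, -s.mean_abs_t, s.mis_id))
    return scores
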