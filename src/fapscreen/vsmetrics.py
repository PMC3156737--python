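"""Evaluation metrics for ranked virtual-screening output.

Given a ranking of actives and decoys by similarity score, this module
computes the ROC AUC, early-enrichment metrics (enrichment factor EF,
relative enrichment factor REF, ROC enrichment ROCE), the arithmetically
weighted awROCE which down-weights actives from large chemotype clusters,
chemotype discovery curves, and BEDROC.

Conventions (documented because the respective printed formulas leave them
open): AUC gives half credit for score ties between an active and a decoy,
which makes it exactly the Mann-Whitney U estimator (a strict-counting mode
is available); the top fraction of the database is N_sel = ceil(x% * N); the
FPR threshold for ROCE is the first rank at which the FPR reaches x%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class Ranking:
    """A scored screening run, sorted by non-increasing score.

    Construct via :meth:`from_scores`, which sorts stably (ties keep input
    order).  Metric computation requires at least one active and one decoy.
    """

    ids: List[str]
    scores: np.ndarray
    is_active: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.is_active = np.asarray(self.is_active, dtype=bool)
        n = len(self.ids)
        if self.scores.shape != (n,) or self.is_active.shape != (n,):
            raise ValueError("ids, scores and is_active must be equally long")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    @classmethod
    def from_scores(
        cls, ids: Sequence[str], scores: Sequence[float], is_active: Sequence[bool]
    ) -> "Ranking":
        scores = np.asarray(scores, dtype=float)
        order = np.argsort(-scores, kind="stable")
        return cls(
            ids=[ids[k] for k in order],
            scores=scores[order],
            is_active=np.asarray(is_active, dtype=bool)[order],
        )

    @property
    def n_total(self) -> int:
        return len(self.ids)

    @property
    def n_actives(self) -> int:
        return int(self.is_active.sum())

    @property
    def n_decoys(self) -> int:
        return self.n_total - self.n_actives

    def _require_both_classes(self) -> None:
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("metrics need at least one active and one decoy")


@dataclass
class ChemotypeClustering:
    """Assignment of every active to a scaffold cluster."""

    cluster_of: Dict[str, str]

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_of.values()))

    def sizes(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for c in self.cluster_of.values():
            out[c] = out.get(c, 0) + 1
        return out


def auc(ranking: Ranking, ties: str = "half") -> float:
    """Area under the ROC curve from decoys-above-each-active counts.

    AUC = 1 - (1 / (N_actives * N_decoys)) * sum_i d_i, where d_i is the
    number of decoys scoring above the i-th active.  With ``ties="half"``
    (default) a decoy tied with an active contributes 0.5, which makes the
    value identical to the Mann-Whitney U estimator; ``ties="strict"`` counts
    only strictly higher-scoring decoys.
    """
    ranking._require_both_classes()
    if ties not in ("half", "strict"):
        raise ValueError("ties must be 'half' or 'strict'")
    active_scores = ranking.scores[ranking.is_active]
    decoy_sorted = np.sort(ranking.scores[~ranking.is_active])
    n_d = decoy_sorted.size
    # decoys strictly above each active / tied with it, via binary search
    above = n_d - np.searchsorted(decoy_sorted, active_scores, side="right")
    if ties == "half":
        tied = (
            np.searchsorted(decoy_sorted, active_scores, side="right")
            - np.searchsorted(decoy_sorted, active_scores, side="left")
        )
        d_sum = float(above.sum()) + 0.5 * float(tied.sum())
    else:
        d_sum = float(above.sum())
    return 1.0 - d_sum / (ranking.n_actives * n_d)


def _n_selected(ranking: Ranking, fraction_pct: float) -> int:
    if not 0 < fraction_pct <= 100:
        raise ValueError("fraction must be in (0, 100]")
    return int(math.ceil(fraction_pct / 100.0 * ranking.n_total))


def enrichment_factor(ranking: Ranking, fraction_pct: float) -> float:
    """EF at x%: active rate in the top ceil(x% * N) over the global active rate."""
    ranking._require_both_classes()
    n_sel = _n_selected(ranking, fraction_pct)
    tp = int(ranking.is_active[:n_sel].sum())
    return (tp / n_sel) / (ranking.n_actives / ranking.n_total)


def relative_enrichment_factor(ranking: Ranking, fraction_pct: float) -> float:
    """REF at x%, in [0, 100]: 100 * TP / min(N_sel, N_actives).

    Normalizes by the best achievable retrieval in the selection, removing
    the dependence on the number of actives; a perfect ranking scores 100 at
    every fraction.
    """
    ranking._require_both_classes()
    n_sel = _n_selected(ranking, fraction_pct)
    tp = int(ranking.is_active[:n_sel].sum())
    return 100.0 * tp / min(n_sel, ranking.n_actives)


def _roc_cutoff_index(ranking: Ranking, fpr_pct: float) -> int:
    """Index (exclusive) of the first rank at which the FPR reaches x%."""
    if not 0 < fpr_pct <= 100:
        raise ValueError("fpr fraction must be in (0, 100]")
    if ranking.n_decoys < 1:
        raise ValueError("no decoys: FPR threshold unreachable")
    decoys_seen = np.cumsum(~ranking.is_active)
    fpr = decoys_seen / ranking.n_decoys
    hits = np.nonzero(fpr >= fpr_pct / 100.0)[0]
    if hits.size == 0:
        raise ValueError(f"FPR never reaches {fpr_pct}%")
    return int(hits[0]) + 1


def roc_enrichment(ranking: Ranking, fpr_pct: float) -> float:
    """ROCE at x% FPR: TPR at the first rank where FPR >= x%, divided by x/100."""
    ranking._require_both_classes()
    cut = _roc_cutoff_index(ranking, fpr_pct)
    tpr = int(ranking.is_active[:cut].sum()) / ranking.n_actives
    return tpr / (fpr_pct / 100.0)


def aw_roc_enrichment(
    ranking: Ranking, clustering: ChemotypeClustering, fpr_pct: float
) -> float:
    """Arithmetically weighted ROC enrichment.

    Each retrieved active contributes 1/N_j (N_j = size of its chemotype
    cluster), the weighted hits are averaged over the number of clusters, and
    the resulting weighted TPR is divided by x/100.  With singleton clusters
    this reduces exactly to :func:`roc_enrichment`.
    """
    ranking._require_both_classes()
    sizes = clustering.sizes()
    for idx in np.nonzero(ranking.is_active)[0]:
        if ranking.ids[idx] not in clustering.cluster_of:
            raise ValueError(f"active {ranking.ids[idx]!r} has no chemotype cluster")
    cut = _roc_cutoff_index(ranking, fpr_pct)
    weighted_hits = 0.0
    for idx in range(cut):
        if ranking.is_active[idx]:
            cluster = clustering.cluster_of[ranking.ids[idx]]
            weighted_hits += 1.0 / sizes[cluster]
    weighted_tpr = weighted_hits / clustering.n_clusters
    return weighted_tpr / (fpr_pct / 100.0)


def chemotype_discovery_curve(
    ranking: Ranking, clustering: ChemotypeClustering
) -> Tuple[np.ndarray, np.ndarray]:
    """Fraction of chemotype clusters discovered as a function of database fraction.

    A chemotype counts as discovered once any of its actives has appeared in
    the ranking.  Returns (database_fraction, cluster_fraction) step-curve
    values at every rank; the curve is non-decreasing and ends at 1 when all
    clusters were seen.
    """
    ranking._require_both_classes()
    k = clustering.n_clusters
    seen: set = set()
    discovered = np.empty(ranking.n_total)
    for idx in range(ranking.n_total):
        if ranking.is_active[idx]:
            cid = clustering.cluster_of.get(ranking.ids[idx])
            if cid is None:
                raise ValueError(f"active {ranking.ids[idx]!r} has no chemotype cluster")
            seen.add(cid)
        discovered[idx] = len(seen) / k
    db_fraction = np.arange(1, ranking.n_total + 1) / ranking.n_total
    return db_fraction, discovered


def bedroc(ranking: Ranking, alpha: float) -> float:
    """Boltzmann-enhanced discrimination of ROC (Truchon & Bayly).

    Exponentially weights early ranks with decay parameter ``alpha`` and maps
    the resulting RIE onto [0, 1].
    """
    ranking._require_both_classes()
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n, n_act = ranking.n_total, ranking.n_actives
    r_a = n_act / n
    ranks = np.nonzero(ranking.is_active)[0] + 1  # 1-based
    s = float(np.exp(-alpha * ranks / n).sum())
    # RIE: observed sum over its uniform-rank expectation (n_act/N) * sum_r e^(-alpha r/N)
    rie = s / ((n_act / n) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / n) - 1.0))
    factor = r_a * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * r_a)
    )
    constant = 1.0 / (1.0 - math.exp(alpha * (1.0 - r_a)))
    return rie * factor + constant


DEFAULT_FRACTIONS = (1.0, 5.0, 10.0)
DEFAULT_ALPHAS = (20.0, 8.0, 5.0)


def evaluate(
    ranking: Ranking,
    clustering: Optional[ChemotypeClustering] = None,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> Dict[str, float]:
    """One flat report of all metrics at the requested fractions/alphas."""
    report: Dict[str, float] = {"auc": auc(ranking)}
    for x in fractions:
        report[f"ef_{x:g}%"] = enrichment_factor(ranking, x)
        report[f"ref_{x:g}%"] = relative_enrichment_factor(ranking, x)
        report[f"roce_{x:g}%"] = roc_enrichment(ranking, x)
        if clustering is not None:
            report[f"awroce_{x:g}%"] = aw_roc_enrichment(ranking, clustering, x)
    for a in alphas:
        report[f"bedroc_a{a:g}"] = bedroc(ranking, a)
    return report


def report_frame(report: Mapping[str, float]) -> pd.DataFrame:
    """Metrics report as a two-column DataFrame (metric, value) for TSV export."""
    return pd.DataFrame({"metric": list(report.keys()), "value": list(report.values())})


# -- delimited-text I/O ------------------------------------------------------


def read_ranking(
    ranking_path: str, activity_path: str, delimiter: str = "\t"
) -> Ranking:
    """Join a ranking table (rank, name, score) with an activity table (id, 0/1)."""
    rank_df = pd.read_csv(ranking_path, sep=delimiter, comment="#")
    act_df = pd.read_csv(activity_path, sep=delimiter, comment="#")
    act_df.columns = [c.strip() for c in act_df.columns]
    id_col, active_col = act_df.columns[0], act_df.columns[1]
    activity = dict(zip(act_df[id_col].astype(str), act_df[active_col].astype(int)))
    name_col = "name" if "name" in rank_df.columns else rank_df.columns[1]
    score_col = "score" if "score" in rank_df.columns else rank_df.columns[2]
    names = rank_df[name_col].astype(str).tolist()
    missing = [n for n in names if n not in activity]
    if missing:
        raise ValueError(f"no activity entry for {missing[0]!r}")
    return Ranking.from_scores(
        names,
        rank_df[score_col].to_numpy(dtype=float),
        [bool(activity[n]) for n in names],
    )


def read_clusters(path: str, delimiter: str = "\t") -> ChemotypeClustering:
    """Read an (id, cluster label) table."""
    df = pd.read_csv(path, sep=delimiter, comment="#")
    return ChemotypeClustering(
        cluster_of=dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    )
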