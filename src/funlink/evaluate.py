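"""ROC/AUC characterization of a ranking and PPV-based candidate selection.

The scored reference genes act as positives and every other scored gene as a
negative.  AUC is the probability that a random positive outranks a random
negative (midranks for ties), computed by the rank statistic.  Candidates
are selected by positive predictive value: among genes scoring at or above a
threshold t, PPV(t) is the fraction that are reference genes, and the chosen
threshold is the lowest score with PPV strictly above the cutoff (0.5 by
default), i.e. the most permissive cut at which a selected gene is more
likely than not to be trait-associated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .netcore import IntegratedNetwork
from .prioritize import PrioritizationResult, ReferenceGeneSet, dag_score

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    """ROC/AUC, the PPV curve, and the PPV-selected candidate list."""

    auc: Optional[float] = None
    random_level: Optional[bool] = None  # AUC <= 0.5 means a random-level ranking
    roc_points: List[Tuple[float, float]] = field(default_factory=list)
    ppv_curve: pd.DataFrame = field(default_factory=pd.DataFrame)
    selected_threshold: Optional[float] = None
    candidates: List[str] = field(default_factory=list)


def _scores_and_labels(
    result: PrioritizationResult,
    refs: ReferenceGeneSet,
    loo: bool,
    net: Optional[IntegratedNetwork],
) -> Tuple[np.ndarray, np.ndarray, pd.Series]:
    scores = result.scores()
    labels = scores.index.to_series().isin(refs.genes).to_numpy()
    values = scores.to_numpy(dtype=float).copy()
    if loo and net is not None:
        # Literal leave-one-out: rescore each reference gene with itself
        # withdrawn from the reference set.  Because the DAG sum already
        # excludes the i = j term, this reproduces the same value; kept as
        # an explicit guard against self-association inflation.
        for pos in np.flatnonzero(labels):
            gene = scores.index[pos]
            loo_refs = ReferenceGeneSet(refs.trait_label, refs.genes - {gene})
            values[pos] = dag_score(net, loo_refs, gene)[0]
    if not labels.any():
        raise ValueError("no reference gene among the scored genes")
    if labels.all():
        raise ValueError("no non-reference gene among the scored genes")
    return values, labels, scores


def roc_auc(
    result: PrioritizationResult,
    refs: ReferenceGeneSet,
    loo: bool = True,
    net: Optional[IntegratedNetwork] = None,
    into: Optional[EvaluationResult] = None,
) -> EvaluationResult:
    """Rank-statistic AUC with midranks for ties, plus the ROC polyline.

    With ``loo`` and a network, each reference gene's score is recomputed
    with itself removed from the reference set before evaluation.
    """
    values, labels, _ = _scores_and_labels(result, refs, loo, net)
    ev = into or EvaluationResult()
    ev.auc = float(roc_auc_score(labels, values))
    ev.random_level = ev.auc <= 0.5
    fpr, tpr, _thr = roc_curve(labels, values, drop_intermediate=False)
    ev.roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    logger.info(
        "roc_auc: AUC = %.4f over %d positives / %d negatives%s",
        ev.auc,
        int(labels.sum()),
        int((~labels).sum()),
        " (random-level)" if ev.random_level else "",
    )
    return ev


def ppv_curve(
    result: PrioritizationResult,
    refs: ReferenceGeneSet,
    loo: bool = False,
    net: Optional[IntegratedNetwork] = None,
    into: Optional[EvaluationResult] = None,
) -> EvaluationResult:
    """PPV at every distinct score threshold, in descending threshold order.

    PPV(t) = |reference genes scoring >= t| / |genes scoring >= t|; rows for
    empty selections are never emitted (0/0 is undefined).
    """
    values, labels, _ = _scores_and_labels(result, refs, loo, net)
    order = np.argsort(-values, kind="mergesort")
    sorted_vals = values[order]
    cum_ref = np.cumsum(labels[order])
    rows = []
    # last index of each run of equal scores = cumulative counts at >= t
    distinct = np.flatnonzero(np.r_[sorted_vals[1:] != sorted_vals[:-1], True])
    for idx in distinct:
        n_sel = int(idx + 1)
        n_ref = int(cum_ref[idx])
        rows.append(
            {
                "threshold": float(sorted_vals[idx]),
                "n_selected": n_sel,
                "n_ref_selected": n_ref,
                "ppv": n_ref / n_sel,
            }
        )
    ev = into or EvaluationResult()
    ev.ppv_curve = pd.DataFrame(rows, columns=["threshold", "n_selected", "n_ref_selected", "ppv"])
    return ev


def select_candidates(
    result: PrioritizationResult,
    refs: ReferenceGeneSet,
    min_ppv: float = 0.5,
    loo: bool = False,
    net: Optional[IntegratedNetwork] = None,
    into: Optional[EvaluationResult] = None,
) -> EvaluationResult:
    """Select non-reference candidates at the lowest threshold with PPV > min_ppv.

    The lowest qualifying threshold maximizes the candidate yield while
    keeping the selection more likely right than wrong.  If no threshold
    qualifies, no candidates are returned.
    """
    ev = ppv_curve(result, refs, loo=loo, net=net, into=into)
    qualifying = ev.ppv_curve[ev.ppv_curve["ppv"] > min_ppv]
    if qualifying.empty:
        ev.selected_threshold = None
        ev.candidates = []
        logger.info("select_candidates: no threshold reaches PPV > %g", min_ppv)
        return ev
    t = float(qualifying["threshold"].min())
    ev.selected_threshold = t
    values, labels, scores = _scores_and_labels(result, refs, loo, net)
    mask = (values >= t) & ~labels
    ev.candidates = sorted(scores.index[mask])
    logger.info(
        "select_candidates: threshold %g selects %d candidate(s) at PPV > %g",
        t,
        len(ev.candidates),
        min_ppv,
    )
    return ev


def evaluate(
    result: PrioritizationResult,
    refs: ReferenceGeneSet,
    min_ppv: float = 0.5,
    loo: bool = True,
    net: Optional[IntegratedNetwork] = None,
) -> EvaluationResult:
    """Full evaluation: ROC/AUC, PPV curve, and candidate selection."""
    ev = roc_auc(result, refs, loo=loo, net=net)
    select_candidates(result, refs, min_ppv=min_ppv, loo=loo, net=net, into=ev)
    return ev


def subsample_negatives(
    result: PrioritizationResult,
    refs: ReferenceGeneSet,
    n_negatives: int,
    seed: int,
) -> PrioritizationResult:
    """Seeded random subsampling of the negative universe for very large
    networks; all reference genes are kept."""
    table = result.table
    is_ref = table["gene"].isin(refs.genes)
    neg = table[~is_ref]
    if n_negatives >= len(neg):
        return result
    rng = np.random.default_rng(seed)
    picked = rng.choice(neg.index.to_numpy(), size=n_negatives, replace=False)
    sub = pd.concat([table[is_ref], table.loc[np.sort(picked)]])
    sub = sub.sort_values(["dag", "gene"], ascending=[False, True], kind="mergesort")
    sub["rank"] = range(1, len(sub) + 1)
    return PrioritizationResult(
        trait_label=result.trait_label, scope=result.scope, table=sub.reset_index(drop=True)
    )
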