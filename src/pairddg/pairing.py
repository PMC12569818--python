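"""Anchor-query pairwise construction and ensemble ddG recovery.

Instead of regressing ddG directly, each *query* record (unknown label) is
paired with every eligible *anchor* record (known label) from the same
UniProt group.  The pair carries

* a feature ``X_query - X_anchor`` (difference of the assembled inputs), and
* a training target dddG = ddG_query - ddG_anchor.

A regressor trained on such pairs predicts dddG; the query's ddG is then
recovered as the ensemble average over its N anchors,

    ddG_query = (1/N) * sum_i (dddG_pred_i + ddG_anchor_i),

which is exact whenever the dddG predictions are exact, for any anchor set.
Pairing within a protein group cancels any group-level offset in the labels,
which is what lets anchors rescue accuracy under distribution shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .featurize import FeatureMatrix
from .records import Dataset, MutationRecord

__all__ = [
    "AnchorQueryPair",
    "RecoveredPrediction",
    "build_pairs",
    "build_training_pairs",
    "pair_feature_matrix",
    "recover_query_ddg",
    "recover_all",
]


@dataclass
class AnchorQueryPair:
    """One (query, anchor) comparison.

    ``target_dddg`` is present at train time and for labelled evaluation
    pairs; it is None when the query label is unknown.
    """

    query_id: str
    anchor_id: str
    pair_feature: np.ndarray
    group: str
    target_dddg: float | None = None
    anchor_ddg: float | None = None


@dataclass
class RecoveredPrediction:
    """Ensemble-averaged ddG for one query with per-anchor diagnostics."""

    query_id: str
    ddg_pred: float
    n_anchors: int
    per_anchor_values: np.ndarray

    @property
    def anchor_sd(self) -> float:
        """Dispersion of the per-anchor recovered values (0 for an oracle)."""
        return float(np.std(self.per_anchor_values))


def build_pairs(
    queries: Sequence[MutationRecord],
    anchors: Sequence[MutationRecord],
    features: FeatureMatrix,
    same_group_only: bool = True,
    with_targets: bool = True,
    allow_self_pairs: bool = False,
) -> tuple[list[AnchorQueryPair], list[str]]:
    """Pair every query with all of its eligible anchors.

    Eligibility defaults to same-UniProt-group membership.  Queries with no
    eligible anchor are not an error: they are returned in the second
    element (the "uncovered" list) so the caller can report coverage.
    """
    pairs: list[AnchorQueryPair] = []
    uncovered: list[str] = []
    for q in queries:
        n_before = len(pairs)
        xq = features.row(q.record_id)
        for a in anchors:
            if a.record_id == q.record_id and not allow_self_pairs:
                continue
            if same_group_only and a.uniprot_id != q.uniprot_id:
                continue
            pairs.append(
                AnchorQueryPair(
                    query_id=q.record_id,
                    anchor_id=a.record_id,
                    pair_feature=xq - features.row(a.record_id),
                    group=q.uniprot_id,
                    target_dddg=(q.ddg - a.ddg) if with_targets else None,
                    anchor_ddg=a.ddg,
                )
            )
        if len(pairs) == n_before and not (
            allow_self_pairs and any(a.record_id == q.record_id for a in anchors)
        ):
            uncovered.append(q.record_id)
    return pairs, uncovered


def build_training_pairs(
    train_records: Sequence[MutationRecord] | Dataset,
    features: FeatureMatrix,
    within_group_only: bool = True,
    max_pairs_per_group: int | None = None,
    seed: int = 0,
) -> list[AnchorQueryPair]:
    """All ordered labelled pairs (i, j), i != j, for training.

    Within each UniProt group by default (k records yield k(k-1) ordered
    pairs), or globally when ``within_group_only`` is off.  Ordered pairs
    keep the antisymmetric structure (target of (i,j) is the negative of
    (j,i)) learnable.  ``max_pairs_per_group`` caps each group (or the
    global pool) by a seeded uniform subsample to bound the O(k^2) blow-up.
    """
    records = list(train_records)
    if within_group_only:
        groups: dict[str, list[MutationRecord]] = {}
        for r in records:
            groups.setdefault(r.uniprot_id, []).append(r)
        pools = [groups[g] for g in sorted(groups)]
    else:
        pools = [records]

    rng = np.random.default_rng(seed)
    pairs: list[AnchorQueryPair] = []
    for pool in pools:
        idx_pairs = [(i, j) for i in range(len(pool)) for j in range(len(pool)) if i != j]
        if max_pairs_per_group is not None and len(idx_pairs) > max_pairs_per_group:
            chosen = rng.choice(len(idx_pairs), size=max_pairs_per_group, replace=False)
            idx_pairs = [idx_pairs[c] for c in sorted(chosen)]
        for i, j in idx_pairs:
            q, a = pool[i], pool[j]
            pairs.append(
                AnchorQueryPair(
                    query_id=q.record_id,
                    anchor_id=a.record_id,
                    pair_feature=features.row(q.record_id) - features.row(a.record_id),
                    group=q.uniprot_id if within_group_only else "*",
                    target_dddg=q.ddg - a.ddg,
                    anchor_ddg=a.ddg,
                )
            )
    return pairs


def pair_feature_matrix(pairs: Sequence[AnchorQueryPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair features (X) and dddG targets (y) for model fitting."""
    if not pairs:
        raise ValueError("no pairs given")
    X = np.stack([p.pair_feature for p in pairs])
    y = np.array([np.nan if p.target_dddg is None else p.target_dddg for p in pairs])
    return X, y


def recover_query_ddg(
    query_id: str,
    pred_dddg: Sequence[float],
    anchor_ddg: Sequence[float],
) -> RecoveredPrediction:
    """Ensemble recovery: mean over anchors of (predicted dddG + anchor ddG)."""
    pred = np.asarray(pred_dddg, dtype=float)
    anc = np.asarray(anchor_ddg, dtype=float)
    if pred.shape != anc.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {anc.shape}")
    if pred.size == 0:
        raise ValueError(f"query {query_id!r} has no anchors (uncovered)")
    per_anchor = pred + anc
    return RecoveredPrediction(
        query_id=query_id,
        ddg_pred=float(per_anchor.mean()),
        n_anchors=int(per_anchor.size),
        per_anchor_values=per_anchor,
    )


def recover_all(
    pairs: Sequence[AnchorQueryPair],
    pred_dddg: Sequence[float],
) -> dict[str, RecoveredPrediction]:
    """Group per-pair dddG predictions by query and recover each query ddG.

    ``pred_dddg`` must be aligned with ``pairs``; every pair needs its
    ``anchor_ddg``.
    """
    pred = np.asarray(pred_dddg, dtype=float)
    if pred.shape[0] != len(pairs):
        raise ValueError("predictions not aligned with pairs")
    by_query: dict[str, tuple[list[float], list[float]]] = {}
    for p, yhat in zip(pairs, pred):
        if p.anchor_ddg is None:
            raise ValueError(f"pair ({p.query_id}, {p.anchor_id}) lacks anchor_ddg")
        preds, ancs = by_query.setdefault(p.query_id, ([], []))
        preds.append(float(yhat))
        ancs.append(p.anchor_ddg)
    return {
        q: recover_query_ddg(q, preds, ancs)
        for q, (preds, ancs) in by_query.items()
    }
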