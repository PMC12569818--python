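"""Benchmark experiment objects: a model built from a dataset, fit -> results.

:class:`DdgBenchmark` is the package's front door, in the mould of a
statsmodels model: construct it from a :class:`~pairddg.records.Dataset`
(or a dataframe) together with the experimental condition — feature mode,
partitioning strategy, anchor ratio, paired or unpaired use of anchors,
regressor — then call :meth:`~DdgBenchmark.fit` with a seed.  One fit runs
the full pipeline (featurize -> split -> select anchors -> [pair] -> train
-> predict -> recover) and returns a :class:`DdgBenchmarkResults` carrying
per-query predictions, the metric quartet, classification at the resistance
threshold, and a text ``summary()``.  :meth:`~DdgBenchmark.fit_repeated`
wraps the 30-repeat mean +/- SD protocol.

The two anchor regimes mirror the two ways reference data can be used:

* ``paired=False`` (the baseline): anchors are simply merged into the
  training set and the regressor maps features to ddG directly;
* ``paired=True``: the regressor is trained on within-group ordered pairs
  (target dddG) and each query is predicted through all of its same-group
  anchors, ensemble-averaged back to ddG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .featurize import (
    EmbeddingProvider,
    FeatureMatrix,
    SyntheticEmbeddingProvider,
    featurize_dataset,
)
from .models_eval import (
    AggregatedMetrics,
    ClassificationReport,
    MetricReport,
    RegressorSpec,
    classify_resistance,
    compute_metrics,
    repeat_harness,
    train_model,
)
from .pairing import build_pairs, build_training_pairs, pair_feature_matrix, recover_all
from .partition import select_anchor_subset, split_by_uniprot, split_random
from .records import Dataset

__all__ = ["DdgBenchmark", "DdgBenchmarkResults"]


class DdgBenchmark:
    """One benchmark condition on one dataset.

    Parameters
    ----------
    dataset:
        The mutation records to benchmark on.
    regressor:
        Registry spec of the model to train (default random forest).
    feature_mode:
        ``"difference"`` (2304 features at the default embedding width) or
        ``"concatenation"`` (3584).
    strategy:
        ``"random"`` record-level 8:1:1 split or ``"uniprot"``
        group-disjoint split.
    anchor_ratio:
        Fraction of the test set revealed as labelled anchors (0 to 0.9).
    paired:
        Use anchors through pairwise dddG learning (True) or by merging
        them into the training set (False).  Ignored at ratio 0.
    """

    def __init__(
        self,
        dataset: Dataset,
        regressor: RegressorSpec | str = "rf",
        feature_mode: Literal["difference", "concatenation"] = "difference",
        strategy: Literal["random", "uniprot"] = "uniprot",
        anchor_ratio: float = 0.0,
        paired: bool = False,
        provider: EmbeddingProvider | None = None,
        fingerprint_backend: str = "cheminformatics",
        pair_within_group: bool = True,
        include_anchor_pairs: bool = True,
        antisymmetric_inference: bool = True,
        max_pairs_per_group: int | None = None,
        features: FeatureMatrix | None = None,
    ) -> None:
        if not (0.0 <= anchor_ratio <= 0.9):
            raise ValueError(f"anchor_ratio must be in [0, 0.9], got {anchor_ratio}")
        if paired and anchor_ratio == 0.0:
            raise ValueError("paired prediction needs anchor_ratio > 0")
        self.dataset = dataset
        self.regressor = (
            RegressorSpec(regressor) if isinstance(regressor, str) else regressor
        )
        self.feature_mode = feature_mode
        self.strategy = strategy
        self.anchor_ratio = anchor_ratio
        self.paired = paired
        self.provider = provider or SyntheticEmbeddingProvider()
        self.fingerprint_backend = fingerprint_backend
        self.pair_within_group = pair_within_group
        self.include_anchor_pairs = include_anchor_pairs
        self.antisymmetric_inference = antisymmetric_inference
        self.max_pairs_per_group = max_pairs_per_group
        self._features = features

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "DdgBenchmark":
        """Build from a dataframe in the canonical column schema."""
        from .records import MutationRecord

        records = []
        for _, row in frame.iterrows():
            records.append(
                MutationRecord(
                    record_id=str(row["record_id"]),
                    uniprot_id=str(row["uniprot_id"]),
                    wild_seq=str(row["wild_seq"]),
                    mutation_spec=(str(row["mutation_spec"]) or None)
                    if "mutation_spec" in row and pd.notna(row["mutation_spec"])
                    else None,
                    mutant_seq=(str(row["mutant_seq"]) or None)
                    if "mutant_seq" in row and pd.notna(row["mutant_seq"])
                    else None,
                    smiles=str(row["smiles"]),
                    ddg=float(row["ddg"]),
                    distance=float(row["distance"])
                    if "distance" in row and pd.notna(row["distance"])
                    else None,
                )
            )
        return cls(Dataset(records, provenance="from_dataframe"), **kwargs)

    # -- pipeline pieces ---------------------------------------------------

    def features(self) -> FeatureMatrix:
        """Featurize once and cache; featurization is deterministic."""
        if self._features is None:
            self._features = featurize_dataset(
                self.dataset,
                provider=self.provider,
                mode=self.feature_mode,
                fingerprint_backend=self.fingerprint_backend,
            )
        return self._features

    def _split(self, seed: int):
        if self.strategy == "random":
            return split_random(self.dataset.record_ids, seed)
        return split_by_uniprot(self.dataset, seed)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0) -> "DdgBenchmarkResults":
        """Run the full pipeline once with this seed."""
        feats = self.features()
        split = self._split(seed)
        test = self.dataset.subset(split.test_ids)
        selection = select_anchor_subset(test, self.anchor_ratio, seed=seed)
        anchors = self.dataset.subset(selection.anchor_ids)
        queries = self.dataset.subset(selection.query_ids)
        train = self.dataset.subset(split.train_ids)
        spec = RegressorSpec(self.regressor.name, self.regressor.hyperparams, seed)

        if self.paired:
            preds, uncovered, model = self._fit_paired(
                spec, feats, train, anchors, queries, seed
            )
        else:
            preds, uncovered, model = self._fit_direct(
                spec, feats, train, anchors, queries
            )

        y_true = np.array([q.ddg for q in queries if q.record_id in preds])
        y_pred = np.array([preds[q.record_id] for q in queries if q.record_id in preds])
        metrics = compute_metrics(y_true, y_pred) if y_true.size >= 2 else None
        return DdgBenchmarkResults(
            benchmark=self,
            seed=seed,
            split=split,
            anchor_ids=list(selection.anchor_ids),
            query_ids=list(selection.query_ids),
            predictions=pd.DataFrame(
                {
                    "record_id": [q.record_id for q in queries if q.record_id in preds],
                    "ddg_true": y_true,
                    "ddg_pred": y_pred,
                }
            ),
            uncovered=uncovered,
            metrics=metrics,
            model=model,
        )

    def _fit_direct(self, spec, feats, train, anchors, queries):
        train_records = list(train) + list(anchors)
        X = feats.rows([r.record_id for r in train_records])
        y = np.array([r.ddg for r in train_records])
        model = train_model(spec, X, y)
        Xq = feats.rows([q.record_id for q in queries])
        yhat = model.predict(Xq)
        preds = {q.record_id: float(v) for q, v in zip(queries, yhat)}
        return preds, [], model

    def _fit_paired(self, spec, feats, train, anchors, queries, seed):
        train_pairs = build_training_pairs(
            train,
            feats,
            within_group_only=self.pair_within_group,
            max_pairs_per_group=self.max_pairs_per_group,
            seed=seed,
        )
        if self.include_anchor_pairs and len(anchors) >= 2:
            train_pairs += build_training_pairs(
                anchors,
                feats,
                within_group_only=True,
                max_pairs_per_group=self.max_pairs_per_group,
                seed=seed,
            )
        X, y = pair_feature_matrix(train_pairs)
        model = train_model(spec, X, y)

        query_pairs, uncovered = build_pairs(
            list(queries), list(anchors), feats,
            same_group_only=True, with_targets=False,
        )
        if not query_pairs:
            return {}, uncovered, model
        Xp = np.stack([p.pair_feature for p in query_pairs])
        dddg_hat = model.predict(Xp)
        if self.antisymmetric_inference:
            # dddG is antisymmetric by construction; -Xp is exactly the
            # reversed (anchor, query) pair, so averaging the two directions
            # cancels the regressor's symmetric error component
            dddg_hat = (dddg_hat - model.predict(-Xp)) / 2.0
        recovered = recover_all(query_pairs, dddg_hat)
        preds = {q: r.ddg_pred for q, r in recovered.items()}
        return preds, uncovered, model

    def fit_repeated(self, n_repeats: int = 30, base_seed: int = 0) -> AggregatedMetrics:
        """Mean +/- SD of the metric quartet over seeds base_seed + i."""

        def run(seed: int) -> MetricReport:
            res = self.fit(seed)
            if res.metrics is None:
                raise RuntimeError("too few covered queries for metrics")
            return res.metrics

        return repeat_harness(run, n_repeats=n_repeats, base_seed=base_seed)


@dataclass
class DdgBenchmarkResults:
    """Outcome of one benchmark fit."""

    benchmark: DdgBenchmark
    seed: int
    split: object
    anchor_ids: list[str]
    query_ids: list[str]
    predictions: pd.DataFrame
    uncovered: list[str]
    metrics: MetricReport | None
    model: object = field(repr=False, default=None)

    def classification(self, threshold: float = 1.36) -> ClassificationReport:
        """Resistant/susceptible evaluation of the query predictions."""
        return classify_resistance(
            self.predictions["ddg_true"].to_numpy(),
            self.predictions["ddg_pred"].to_numpy(),
            threshold=threshold,
        )

    def plot_predictions(self, ax=None, threshold: float = 1.36):
        """Scatter of predicted vs. true query ddG with the parity line and
        the resistant/susceptible threshold marked on both axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        t = self.predictions["ddg_true"]
        p = self.predictions["ddg_pred"]
        ax.scatter(t, p, s=18, alpha=0.7, edgecolor="none")
        lo = min(t.min(), p.min()) - 0.5
        hi = max(t.max(), p.max()) + 0.5
        ax.plot([lo, hi], [lo, hi], lw=0.8, color="0.4", zorder=0)
        ax.axvline(threshold, lw=0.6, ls="--", color="0.6")
        ax.axhline(threshold, lw=0.6, ls="--", color="0.6")
        ax.set_xlabel(r"experimental $\Delta\Delta G$ (kcal/mol)")
        ax.set_ylabel(r"predicted $\Delta\Delta G$ (kcal/mol)")
        if self.metrics is not None:
            ax.set_title(
                f"{self.benchmark.regressor.name}, {self.benchmark.strategy}: "
                f"r = {self.metrics.pearson:.2f}", fontsize=10,
            )
        return ax

    def summary(self) -> str:
        b = self.benchmark
        lines = [
            "ddG benchmark results",
            "=" * 44,
            f"regressor:     {b.regressor.label()}",
            f"feature mode:  {b.feature_mode}",
            f"strategy:      {b.strategy}",
            f"anchor ratio:  {b.anchor_ratio:.2f} "
            f"({'paired' if b.paired else 'unpaired'})",
            f"seed:          {self.seed}",
            f"train/val/test sizes: {self.split.sizes()}",
            f"queries predicted: {len(self.predictions)} "
            f"(uncovered: {len(self.uncovered)})",
        ]
        if self.metrics is not None:
            m = self.metrics
            lines += [
                "-" * 44,
                f"MAE      {m.mae:8.4f} kcal/mol",
                f"RMSE     {m.rmse:8.4f} kcal/mol",
                f"Pearson  {m.pearson:8.4f}",
                f"Spearman {m.spearman:8.4f}",
            ]
        else:
            lines.append("metrics: undefined (too few covered queries)")
        return "\n".join(lines)
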