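"""Dataset partitioning protocols and train/test leakage diagnostics.

Three ways of holding data out, in increasing order of realism for a
"new protein" deployment scenario:

* **random** 8:1:1 split of records — the conventional benchmark setting,
  in which near-duplicate records of the same protein land on both sides
  of the split and inflate apparent accuracy;
* **uniprot** split — all records sharing a UniProt accession are kept in
  one subset, so the test proteins are genuinely unseen;
* **anchor/query** division of an existing test set — a fraction of test
  records (the anchors, with known labels) is carved out to serve as
  reference points for the remaining queries.

The leakage report quantifies why the random split is optimistic: for every
test record it finds the most similar training record, by protein percent
identity (edit distance) and by ligand Tanimoto similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .featurize import ligand_fingerprint, tanimoto
from .records import Dataset

__all__ = [
    "SplitAssignment",
    "AnchorSelection",
    "split_random",
    "split_by_uniprot",
    "select_anchor_subset",
    "leakage_report",
    "sequence_identity",
    "edit_distance",
]

Subset = Literal["train", "val", "test"]
RATIOS = (0.8, 0.1, 0.1)


@dataclass
class SplitAssignment:
    """Deterministic record -> {train, val, test} mapping."""

    assignment: dict[str, Subset]
    strategy: Literal["random", "uniprot"]
    seed: int
    ratios: tuple[float, float, float] = RATIOS

    def ids(self, subset: Subset) -> list[str]:
        return [rid for rid, s in self.assignment.items() if s == subset]

    @property
    def train_ids(self) -> list[str]:
        return self.ids("train")

    @property
    def val_ids(self) -> list[str]:
        return self.ids("val")

    @property
    def test_ids(self) -> list[str]:
        return self.ids("test")

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train_ids), len(self.val_ids), len(self.test_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"record_id": list(self.assignment), "subset": list(self.assignment.values())}
        )

    def check_partition(self, ids: list[str]) -> None:
        """Assert the assignment is an exhaustive partition of ``ids``."""
        if set(self.assignment) != set(ids) or len(self.assignment) != len(ids):
            raise ValueError("assignment is not an exhaustive partition of ids")


def _split_sizes(n: int) -> tuple[int, int, int]:
    # 8:1:1 with floor/remainder rounding: reproduces 3343/418/418 at n=4179.
    n_train = int(np.floor(0.8 * n))
    m = n - n_train
    n_val = m // 2
    n_test = m - n_val
    return n_train, n_val, n_test


def split_random(ids: list[str], seed: int) -> SplitAssignment:
    """Record-level 8:1:1 split by seeded uniform shuffle.

    Sizes follow train = floor(0.8 n), then the remainder is halved with
    the odd record going to test.
    """
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    n_train, n_val, n_test = _split_sizes(n)
    order = np.random.default_rng(seed).permutation(n)
    assignment: dict[str, Subset] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            subset: Subset = "train"
        elif rank < n_train + n_val:
            subset = "val"
        else:
            subset = "test"
        assignment[ids[idx]] = subset
    # preserve input order for stable serialization
    assignment = {rid: assignment[rid] for rid in ids}
    out = SplitAssignment(assignment=assignment, strategy="random", seed=seed)
    out.check_partition(ids)
    return out


def split_by_uniprot(ds: Dataset, seed: int, test_first: bool = False) -> SplitAssignment:
    """Group-disjoint split: every UniProt accession lands in one subset.

    Group ids are shuffled with the seed; the first floor(0.8 G) groups go
    to train and the remaining groups are dealt alternately to val and test
    (val first, or test first when ``test_first``).  Balancing operates on
    group counts, not record counts, so subset record fractions are only
    approximately 8:1:1.
    """
    group_ids = ds.uniprot_ids
    n_groups = len(group_ids)
    if n_groups < 3:
        raise ValueError(f"need at least 3 distinct uniprot_ids, got {n_groups}")
    order = np.random.default_rng(seed).permutation(n_groups)
    shuffled = [group_ids[i] for i in order]
    n_train_groups = int(np.floor(0.8 * n_groups))
    holdout = shuffled[n_train_groups:]
    first, second = ("test", "val") if test_first else ("val", "test")
    group_subset: dict[str, Subset] = {g: "train" for g in shuffled[:n_train_groups]}
    for i, g in enumerate(holdout):
        group_subset[g] = first if i % 2 == 0 else second
    if "test" not in group_subset.values():
        raise ValueError(
            "uniprot split produced an empty test set; use at least 4 groups "
            "or pass test_first=True to assign the single holdout group to test"
        )
    assignment = {r.record_id: group_subset[r.uniprot_id] for r in ds}
    out = SplitAssignment(assignment=assignment, strategy="uniprot", seed=seed)
    out.check_partition(ds.record_ids)
    return out


@dataclass
class AnchorSelection:
    """Division of a test set into labelled anchors and unlabelled queries."""

    anchor_ids: list[str]
    query_ids: list[str]
    ratio: float
    seed: int
    stratified: bool = True


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_anchor_subset(
    test_records: Dataset | list,
    ratio: float,
    seed: int,
    stratified: bool = True,
) -> AnchorSelection:
    """Sample anchors from a test set at a given ratio.

    Stratified sampling (the default) draws round(ratio * n_g) anchors from
    each UniProt group g, guaranteeing that anchors exist within every group
    large enough for the ratio — a prerequisite for within-group pairing.
    Pooled sampling ignores groups.
    """
    if not (0.0 <= ratio <= 0.9):
        raise ValueError(f"anchor ratio must be in [0, 0.9], got {ratio}")
    records = list(test_records)
    rng = np.random.default_rng(seed)
    anchors: list[str] = []
    if ratio > 0:
        if stratified:
            groups: dict[str, list[str]] = {}
            for r in records:
                groups.setdefault(r.uniprot_id, []).append(r.record_id)
            for g in sorted(groups):
                members = groups[g]
                k = _round_half_up(ratio * len(members))
                picked = rng.choice(len(members), size=k, replace=False)
                anchors.extend(members[i] for i in sorted(picked))
        else:
            ids = [r.record_id for r in records]
            k = _round_half_up(ratio * len(ids))
            picked = rng.choice(len(ids), size=k, replace=False)
            anchors.extend(ids[i] for i in sorted(picked))
    anchor_set = set(anchors)
    queries = [r.record_id for r in records if r.record_id not in anchor_set]
    return AnchorSelection(
        anchor_ids=anchors, query_ids=queries, ratio=ratio, seed=seed,
        stratified=stratified,
    )


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance by banded-free dynamic programming."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    bn = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a.encode("latin-1"), start=1):
        cur = np.empty_like(prev)
        cur[0] = i
        sub = prev[:-1] + (bn != ca)
        np.minimum(sub, prev[1:] + 1, out=cur[1:])
        # insertions need a sequential pass
        for j in range(1, len(cur)):
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev = cur
    return int(prev[-1])


def sequence_identity(a: str, b: str) -> float:
    """Percent identity = 100 * (1 - edit_distance / max(len))."""
    if not a and not b:
        return 100.0
    return 100.0 * (1.0 - edit_distance(a, b) / max(len(a), len(b)))


def leakage_report(
    train: Dataset,
    test: Dataset,
    fingerprint_backend: str = "cheminformatics",
) -> "LeakageReport":
    """Per-test-record maximum similarity to the training set.

    For each test record: the highest protein percent identity (normalized
    edit distance on mutant sequences, falling back to wild) and the highest
    ligand Tanimoto similarity (on fingerprints) against any training
    record.  A random record split typically shows 100 % on both axes for
    most test records; a group-disjoint split does not.
    """
    if len(train) == 0 or len(test) == 0:
        raise ValueError("train and test must both be non-empty")

    from .featurize import mutant_sequence

    train_seqs = [mutant_sequence(r) for r in train]
    seq_id_cache: dict[tuple[str, str], float] = {}

    def max_identity(seq: str) -> float:
        best = 0.0
        for ts in train_seqs:
            key = (seq, ts)
            if key not in seq_id_cache:
                seq_id_cache[key] = sequence_identity(seq, ts)
            best = max(best, seq_id_cache[key])
            if best == 100.0:
                break
        return best

    fp_cache: dict[str, np.ndarray] = {}

    def fp(smiles: str) -> np.ndarray:
        if smiles not in fp_cache:
            fp_cache[smiles] = ligand_fingerprint(smiles, backend=fingerprint_backend)
        return fp_cache[smiles]

    train_fps = [fp(r.smiles) for r in train]
    rows = []
    for r in test:
        seq = mutant_sequence(r)
        qfp = fp(r.smiles)
        max_tan = max(tanimoto(qfp, tfp) for tfp in train_fps)
        rows.append(
            {
                "record_id": r.record_id,
                "max_seq_identity_pct": max_identity(seq),
                "max_smiles_tanimoto_pct": 100.0 * max_tan,
            }
        )
    table = pd.DataFrame(rows)
    return LeakageReport(per_record=table)


@dataclass
class LeakageReport:
    per_record: pd.DataFrame

    def summary(self) -> dict:
        out = {}
        for col in ("max_seq_identity_pct", "max_smiles_tanimoto_pct"):
            v = self.per_record[col]
            out[col] = {
                "min": float(v.min()),
                "median": float(v.median()),
                "max": float(v.max()),
            }
        out["n_test"] = int(len(self.per_record))
        return out
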