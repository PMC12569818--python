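"""Featurization: protein embeddings, ligand fingerprints, input assembly.

The model input for one record is built in three steps:

1. embed the wild-type and mutant sequences into fixed-length vectors
   (1280-d by default, the size of a protein-language-model hidden state);
2. combine the two embeddings either by subtraction, ``R_mut - R_wt``
   (the *difference* mode, which isolates the mutation's effect), or by
   concatenation ``[R_mut | R_wt]``;
3. append a 1024-bit circular ligand fingerprint (ECFP4: Morgan radius 2).

Resulting input lengths are 1280 + 1024 = 2304 in difference mode and
2*1280 + 1024 = 3584 in concatenation mode.

Real language-model inference sits behind the :class:`EmbeddingProvider`
contract.  The default provider, :class:`SyntheticEmbeddingProvider`, draws a
deterministic standard-normal vector from a hash of the sequence, so the
whole pipeline runs and tests without any model download; any provider must
be deterministic (same sequence, same vector, every run, every platform).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Protocol, runtime_checkable

import numpy as np

from .records import Dataset, MutationRecord, parse_mutation_spec

__all__ = [
    "DEFAULT_EMBED_DIM",
    "FINGERPRINT_BITS",
    "EmbeddingProvider",
    "SyntheticEmbeddingProvider",
    "AssembledInput",
    "apply_mutations",
    "synthetic_embed",
    "protein_feature_difference",
    "protein_feature_concat",
    "ligand_fingerprint",
    "tanimoto",
    "assemble_input",
    "featurize_record",
    "featurize_dataset",
    "feature_dim",
]

DEFAULT_EMBED_DIM = 1280
FINGERPRINT_BITS = 1024
FINGERPRINT_RADIUS = 2

FeatureMode = Literal["difference", "concatenation"]


def apply_mutations(wild_seq: str, spec: str) -> str:
    """Apply a substitution spec like ``"T315I"`` or ``"G719S+T790M"``.

    Positions are 1-based.  Only substitutions are supported, so the output
    length equals the input length.  The stated wild residue must match the
    sequence at each position (self-substitutions like ``"A1A"`` are allowed
    and are the identity).
    """
    muts = parse_mutation_spec(spec)
    seen: set[int] = set()
    chars = list(wild_seq)
    for m in muts:
        if m.position in seen:
            raise ValueError(f"duplicate position {m.position} in spec {spec!r}")
        seen.add(m.position)
        if not (1 <= m.position <= len(wild_seq)):
            raise ValueError(
                f"position {m.position} outside 1..{len(wild_seq)} in spec {spec!r}"
            )
        if chars[m.position - 1] != m.wild:
            raise ValueError(
                f"wild residue mismatch at position {m.position}: spec says "
                f"{m.wild}, sequence has {chars[m.position - 1]}"
            )
        chars[m.position - 1] = m.mutant
    return "".join(chars)


def mutant_sequence(record: MutationRecord) -> str:
    """The mutant sequence of a record, from ``mutant_seq`` or by applying
    ``mutation_spec`` to the wild type."""
    if record.mutant_seq is not None:
        return record.mutant_seq
    assert record.mutation_spec is not None
    return apply_mutations(record.wild_seq, record.mutation_spec)


def _stable_seed(*parts: str) -> int:
    """Platform-independent 63-bit seed from a SHA-256 of the parts."""
    h = hashlib.sha256("\x1f".join(parts).encode("utf-8")).digest()
    return int.from_bytes(h[:8], "big") >> 1


def synthetic_embed(seq: str, dim: int = DEFAULT_EMBED_DIM, salt: str = "") -> np.ndarray:
    """Deterministic stand-in embedding: i.i.d. N(0,1) seeded by (seq, salt).

    Bitwise reproducible across runs and platforms for the same inputs.
    Sequences differing anywhere (even one residue) hash to independent
    seeds, so their embeddings differ with probability 1.
    """
    if dim <= 0:
        raise ValueError(f"dim must be positive, got {dim}")
    if not seq:
        raise ValueError("sequence must be non-empty")
    rng = np.random.Generator(np.random.PCG64(_stable_seed("embed", seq, salt)))
    return rng.standard_normal(dim)


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract for sequence embedders: deterministic, fixed output length."""

    name: str
    dim: int

    def embed(self, seq: str) -> np.ndarray: ...


@dataclass
class SyntheticEmbeddingProvider:
    """Default provider wrapping :func:`synthetic_embed`, with a cache.

    The cache only avoids recomputation; it never changes results because
    the underlying function is a pure hash of the sequence.
    """

    dim: int = DEFAULT_EMBED_DIM
    salt: str = ""
    name: str = "synthetic"
    _cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def embed(self, seq: str) -> np.ndarray:
        vec = self._cache.get(seq)
        if vec is None:
            vec = synthetic_embed(seq, dim=self.dim, salt=self.salt)
            self._cache[seq] = vec
        return vec


def protein_feature_difference(r_mut: np.ndarray, r_wt: np.ndarray) -> np.ndarray:
    """Elementwise mutant-minus-wild embedding difference."""
    r_mut = np.asarray(r_mut, dtype=float)
    r_wt = np.asarray(r_wt, dtype=float)
    if r_mut.shape != r_wt.shape:
        raise ValueError(f"dimension mismatch: {r_mut.shape} vs {r_wt.shape}")
    return r_mut - r_wt


def protein_feature_concat(r_mut: np.ndarray, r_wt: np.ndarray) -> np.ndarray:
    """Concatenation [mutant | wild], length 2*dim."""
    r_mut = np.asarray(r_mut, dtype=float)
    r_wt = np.asarray(r_wt, dtype=float)
    if r_mut.shape != r_wt.shape:
        raise ValueError(f"dimension mismatch: {r_mut.shape} vs {r_wt.shape}")
    return np.concatenate([r_mut, r_wt])


def _fingerprint_rdkit(smiles: str, n_bits: int, radius: int) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def _fingerprint_hashed(smiles: str, n_bits: int) -> np.ndarray:
    # Test-only stand-in: hash every character k-mer (k = 1..4) of the
    # SMILES string into n_bits buckets.  Deterministic, no chemistry.
    arr = np.zeros(n_bits, dtype=np.uint8)
    for k in range(1, 5):
        for i in range(len(smiles) - k + 1):
            arr[_stable_seed("fp", smiles[i : i + k]) % n_bits] = 1
    return arr


def ligand_fingerprint(
    smiles: str,
    backend: Literal["cheminformatics", "hashed-fallback"] = "cheminformatics",
    n_bits: int = FINGERPRINT_BITS,
    radius: int = FINGERPRINT_RADIUS,
) -> np.ndarray:
    """1024-bit binary ligand fingerprint.

    The ``cheminformatics`` backend computes a Morgan/ECFP4 circular
    fingerprint (radius 2) via RDKit and raises on unparseable SMILES.  The
    ``hashed-fallback`` backend hashes SMILES character k-mers and exists so
    the pipeline runs without RDKit; it encodes no chemistry.
    """
    if not smiles:
        raise ValueError("SMILES must be non-empty")
    if backend == "cheminformatics":
        return _fingerprint_rdkit(smiles, n_bits, radius)
    if backend == "hashed-fallback":
        return _fingerprint_hashed(smiles, n_bits)
    raise ValueError(f"unknown fingerprint backend {backend!r}")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary fingerprints."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class AssembledInput:
    """Final model input: protein feature block followed by fingerprint."""

    values: np.ndarray
    mode: FeatureMode


def assemble_input(x_protein: np.ndarray, x_ligand: np.ndarray,
                   dim: int = DEFAULT_EMBED_DIM) -> AssembledInput:
    """Join the protein feature with the ligand fingerprint.

    The protein block must be ``dim`` long (difference mode) or ``2*dim``
    (concatenation mode); the assembled length is then ``dim + 1024`` or
    ``2*dim + 1024`` (2304 / 3584 at the default dim).
    """
    x_protein = np.asarray(x_protein, dtype=float)
    if x_protein.shape == (dim,):
        mode: FeatureMode = "difference"
    elif x_protein.shape == (2 * dim,):
        mode = "concatenation"
    else:
        raise ValueError(
            f"protein feature length {x_protein.shape} is neither {dim} "
            f"(difference) nor {2 * dim} (concatenation)"
        )
    values = np.concatenate([x_protein, np.asarray(x_ligand, dtype=float)])
    return AssembledInput(values=values, mode=mode)


def feature_dim(mode: FeatureMode, dim: int = DEFAULT_EMBED_DIM,
                n_bits: int = FINGERPRINT_BITS) -> int:
    """Length of the assembled input for a feature mode."""
    return (dim if mode == "difference" else 2 * dim) + n_bits


def featurize_record(
    record: MutationRecord,
    provider: EmbeddingProvider,
    mode: FeatureMode = "difference",
    fingerprint_backend: Literal["cheminformatics", "hashed-fallback"] = "cheminformatics",
) -> np.ndarray:
    """Assembled input vector for one record."""
    r_wt = provider.embed(record.wild_seq)
    r_mut = provider.embed(mutant_sequence(record))
    if mode == "difference":
        x_protein = protein_feature_difference(r_mut, r_wt)
    elif mode == "concatenation":
        x_protein = protein_feature_concat(r_mut, r_wt)
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    fp = ligand_fingerprint(record.smiles, backend=fingerprint_backend)
    return assemble_input(x_protein, fp, dim=provider.dim).values


def featurize_dataset(
    ds: Dataset,
    provider: EmbeddingProvider | None = None,
    mode: FeatureMode = "difference",
    fingerprint_backend: Literal["cheminformatics", "hashed-fallback"] = "cheminformatics",
) -> "FeatureMatrix":
    """Feature matrix for a dataset, rows aligned with record order."""
    if provider is None:
        provider = SyntheticEmbeddingProvider()
    X = np.stack(
        [featurize_record(r, provider, mode, fingerprint_backend) for r in ds]
    )
    return FeatureMatrix(
        X=X,
        record_ids=ds.record_ids,
        mode=mode,
        provider_name=provider.name,
        embed_dim=provider.dim,
        fingerprint_backend=fingerprint_backend,
    )


@dataclass
class FeatureMatrix:
    """Dense feature matrix plus the metadata needed to reproduce it."""

    X: np.ndarray
    record_ids: list[str]
    mode: FeatureMode
    provider_name: str
    embed_dim: int
    fingerprint_backend: str

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.record_ids):
            raise ValueError("row count does not match record_ids")
        self._index = {rid: i for i, rid in enumerate(self.record_ids)}

    def row(self, record_id: str) -> np.ndarray:
        return self.X[self._index[record_id]]

    def rows(self, record_ids: list[str]) -> np.ndarray:
        return self.X[[self._index[r] for r in record_ids]]

    @property
    def metadata(self) -> dict:
        return {
            "provider": self.provider_name,
            "dim": self.embed_dim,
            "mode": self.mode,
            "fingerprint_backend": self.fingerprint_backend,
            "fingerprint_radius": FINGERPRINT_RADIUS,
            "n_bits": FINGERPRINT_BITS,
            "n_records": len(self.record_ids),
            "n_features": int(self.X.shape[1]),
        }
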