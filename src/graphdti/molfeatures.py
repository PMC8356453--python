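"""Molecular similarity primitives and feature encoders.

Tanimoto coefficients over fingerprint bit sets and Needleman-Wunsch global
percent identity drive the negative-set construction and expression
augmentation rules. Encoders produce the fixed-width feature blocks: 300-dim
drug and protein vectors and 512-dim binding-site vectors. Pretrained
Mol2vec / ProtVec / autoencoder vectors are accepted as precomputed input;
deterministic hashing stand-ins let the full pipeline run without any
pretrained asset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

DRUG_DIM = 300
PROTEIN_DIM = 300
SITE_DIM = 512

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class SimilarityError(ValueError):
    """Undefined similarity (e.g., two empty fingerprints)."""


class DimensionError(ValueError):
    """Precomputed vector of the wrong length."""


@dataclass
class Fingerprint:
    drug_id: str
    bits: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        self.bits = frozenset(int(b) for b in self.bits)
        if any(b < 0 for b in self.bits):
            raise ValueError("fingerprint bit indices must be nonnegative")

    @property
    def degenerate(self) -> bool:
        return len(self.bits) == 0


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B| over on-bit sets; in [0, 1]."""
    if a.degenerate and b.degenerate:
        raise SimilarityError(
            f"Tanimoto undefined for two empty fingerprints ({a.drug_id}, {b.drug_id})"
        )
    union = a.bits | b.bits
    return len(a.bits & b.bits) / len(union)


@dataclass
class ProteinSequence:
    protein_id: str
    residues: str

    def __post_init__(self):
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"empty sequence for {self.protein_id}")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(f"illegal residues {sorted(bad)} in {self.protein_id}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0  # linear gap penalty per inserted column


@dataclass
class AlignmentResult:
    score: float
    aligned_length: int
    identical_positions: int

    @property
    def identity_percent(self) -> float:
        return 100.0 * self.identical_positions / self.aligned_length


def global_identity(
    a: ProteinSequence | str,
    b: ProteinSequence | str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> AlignmentResult:
    """Needleman-Wunsch global alignment and percent identity.

    Identity is counted over the full alignment length including gap columns.
    Traceback ties are resolved diagonal > up > left, so the reported
    alignment (and its identity) is deterministic even when several
    alignments share the optimal score.
    """
    sa = a.residues if isinstance(a, ProteinSequence) else ProteinSequence("a", a).residues
    sb = b.residues if isinstance(b, ProteinSequence) else ProteinSequence("b", b).residues
    n, m = len(sa), len(sb)

    F = np.empty((n + 1, m + 1))
    F[0, :] = scoring.gap * np.arange(m + 1)
    F[:, 0] = scoring.gap * np.arange(n + 1)
    for i in range(1, n + 1):
        ci = sa[i - 1]
        for j in range(1, m + 1):
            s = scoring.match if ci == sb[j - 1] else scoring.mismatch
            F[i, j] = max(F[i - 1, j - 1] + s, F[i - 1, j] + scoring.gap,
                          F[i, j - 1] + scoring.gap)

    i, j = n, m
    aligned = identical = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = scoring.match if sa[i - 1] == sb[j - 1] else scoring.mismatch
            if F[i, j] == F[i - 1, j - 1] + s:  # diagonal first
                identical += sa[i - 1] == sb[j - 1]
                aligned += 1
                i, j = i - 1, j - 1
                continue
        if i > 0 and F[i, j] == F[i - 1, j] + scoring.gap:  # then up
            aligned += 1
            i -= 1
            continue
        aligned += 1
        j -= 1
    return AlignmentResult(score=float(F[n, m]), aligned_length=aligned,
                           identical_positions=int(identical))


def _hash_vector(tokens, dim: int, salt: str) -> np.ndarray:
    v = np.zeros(dim)
    for tok in tokens:
        h = hashlib.blake2b(f"{tok}|{salt}".encode(), digest_size=8).digest()
        idx = int.from_bytes(h[:4], "big") % dim
        v[idx] += 1.0 if h[4] & 1 else -1.0
    norm = np.linalg.norm(v)
    if norm > 0:
        v /= norm
    return v


def _check_dim(vec: np.ndarray, dim: int, tag: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (dim,):
        raise DimensionError(f"{tag} vector must have length {dim}, got {vec.shape}")
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"{tag} vector contains non-finite entries")
    return vec


def encode_drug(drug: Fingerprint | np.ndarray) -> np.ndarray:
    """300-dim drug vector: precomputed passthrough or hashed fingerprint bits."""
    if isinstance(drug, Fingerprint):
        return _hash_vector((f"bit{b}" for b in sorted(drug.bits)), DRUG_DIM, "drug")
    return _check_dim(drug, DRUG_DIM, "drug")


def encode_protein(seq: ProteinSequence | np.ndarray) -> np.ndarray:
    """300-dim protein vector: precomputed passthrough or hashed overlapping 3-mers."""
    if isinstance(seq, ProteinSequence):
        if len(seq) < 3:
            raise ValueError(f"sequence {seq.protein_id} shorter than 3 residues")
        kmers = (seq.residues[i : i + 3] for i in range(len(seq) - 2))
        return _hash_vector(kmers, PROTEIN_DIM, "protein")
    return _check_dim(seq, PROTEIN_DIM, "protein")


def encode_site(site: np.ndarray) -> np.ndarray:
    """512-dim binding-site vector passthrough with validation."""
    return _check_dim(site, SITE_DIM, "site")


def random_site_vector(seed: int, site_id: str = "") -> np.ndarray:
    """Seeded stand-in for a binding-site autoencoder vector."""
    h = hashlib.blake2b(f"{site_id}|{seed}".encode(), digest_size=4).digest()
    rng = np.random.default_rng(int.from_bytes(h, "big"))
    v = rng.standard_normal(SITE_DIM)
    return v / np.linalg.norm(v)


def read_fasta(source) -> list[ProteinSequence]:
    from Bio import SeqIO

    handle = open(source) if not hasattr(source, "read") else source
    try:
        return [
            ProteinSequence(protein_id=rec.id, residues=str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if handle is not source:
            handle.close()


def read_fingerprints(source) -> list[Fingerprint]:
    """One drug per line: drug_id TAB comma-separated on-bit indices."""
    handle = open(source) if not hasattr(source, "read") else source
    try:
        fps = []
        for line in handle:
            line = line.strip()
            if not line:
                continue
            drug_id, _, rest = line.partition("\t")
            bits = frozenset(int(b) for b in rest.split(",") if b.strip())
            fps.append(Fingerprint(drug_id=drug_id, bits=bits))
        return fps
    finally:
        if handle is not source:
            handle.close()
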