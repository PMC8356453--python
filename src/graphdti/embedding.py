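"""Graph-as-document embedding of local network environments.

Each environment is turned into a multiset of Weisfeiler-Lehman subtree
tokens (the document) and hashed into a fixed-length vector. Initial node
labels encode the two node features carried by the environment — the
discretized differential-expression value and the distance-rank bucket — so
the token multiset is invariant under protein renaming that preserves
structure and labels. A corpus-trained backend is available as an
alternative to the deterministic hashing backend.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import TruncatedSVD

from .network import LocalEnvironment

# expression discretization edges (moderated Z-score): strong down, down,
# neutral, up, strong up
_EXPR_EDGES = (-2.0, -0.5, 0.5, 2.0)
PAD_LABEL = "PAD"


class EmbeddingStateError(RuntimeError):
    """Trained backend used before fitting a corpus."""


def _expr_bin(z: float) -> int:
    for i, edge in enumerate(_EXPR_EDGES):
        if z <= edge if i < 2 else z < edge:
            return i
    return len(_EXPR_EDGES)


def _rank_bucket(rank: int, n: int) -> int:
    """Fixed-width rank bucket: ranks 1-5 -> 1, 6-10 -> 2, ..., capped at 10.

    Buckets are absolute (independent of the environment size N) so the same
    neighbor at the same rank gets the same token in environments of
    different sizes, keeping documents comparable across N.
    """
    if rank == 0:
        return 0
    return min(10, int(np.ceil(rank / 5.0)))


def _stable_hash(text: str) -> str:
    return hashlib.blake2b(text.encode(), digest_size=8).hexdigest()


@dataclass
class GraphDocument:
    """Multiset of WL subtree labels for one environment."""

    environment_id: str
    tokens: list[str] = field(default_factory=list)


def wl_tokenize(env: LocalEnvironment, iterations: int = 2) -> GraphDocument:
    """Weisfeiler-Lehman relabeling of a local environment.

    Iteration-0 labels are ``E<expr bin>|R<rank decile>`` per node (``PAD``
    for padding entries, which carry no edges); iteration h+1 relabels each
    node with a hash of its own label and the sorted multiset of its
    neighbors' labels. Tokens across all iterations form the document.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")

    labels: dict[str, str] = {
        env.target: f"E{_expr_bin(env.target_expression)}|R0"
    }
    adjacency: dict[str, list[str]] = {env.target: []}
    for rec in env.neighbors:
        if rec.present:
            labels[rec.node] = f"E{_expr_bin(rec.expression)}|R{_rank_bucket(rec.rank, env.n)}"
            adjacency[rec.node] = []
    n_pad = sum(1 for rec in env.neighbors if not rec.present)
    for u, v, _w in env.induced_edges:
        if u in adjacency and v in adjacency:
            adjacency[u].append(v)
            adjacency[v].append(u)

    tokens: list[str] = sorted(labels.values()) + [PAD_LABEL] * n_pad
    for _ in range(iterations):
        new_labels = {}
        for node, own in labels.items():
            neigh = sorted(labels[m] for m in adjacency[node])
            new_labels[node] = _stable_hash(own + "|" + ",".join(neigh))
        labels = new_labels
        tokens.extend(sorted(labels.values()))
        tokens.extend([PAD_LABEL] * n_pad)  # pads never change label
    return GraphDocument(environment_id=env.environment_id(), tokens=tokens)


def _hash_tokens(tokens, dim: int, seed: int) -> np.ndarray:
    """Signed feature hashing of a token multiset, L2-normalized."""
    v = np.zeros(dim)
    salt = f"|{seed}"
    for tok in tokens:
        h = hashlib.blake2b((tok + salt).encode(), digest_size=8).digest()
        idx = int.from_bytes(h[:4], "big") % dim
        sign = 1.0 if h[4] & 1 else -1.0
        v[idx] += sign
    norm = np.linalg.norm(v)
    if norm > 0:
        v /= norm
    return v


def embed_document(
    doc: GraphDocument,
    dim: int = 300,
    backend: str = "hashed",
    seed: int = 0,
    corpus_model: "TrainedDocEmbedder | None" = None,
) -> np.ndarray:
    """Embed one graph document into ``dim`` real coordinates."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if backend == "hashed":
        return _hash_tokens(doc.tokens, dim, seed)
    if backend == "trained":
        if corpus_model is None or not corpus_model.fitted_:
            raise EmbeddingStateError("trained backend requires a fitted corpus model")
        return corpus_model.transform([doc])[0]
    raise ValueError(f"unknown backend {backend!r}")


class HashedGraphEmbedder(TransformerMixin, BaseEstimator):
    """Deterministic WL-token hashing embedder for local environments.

    Parameters
    ----------
    dim : int
        Output dimensionality (300 matches the drug/protein feature width).
    iterations : int
        WL relabeling depth.
    seed : int
        Salt for the hash; same seed, same environment, same vector.
    """

    def __init__(self, dim: int = 300, iterations: int = 2, seed: int = 0):
        self.dim = dim
        self.iterations = iterations
        self.seed = seed

    def fit(self, X, y=None):  # stateless; present for pipeline compatibility
        self.n_features_out_ = self.dim
        return self

    def transform(self, X: list[LocalEnvironment]) -> np.ndarray:
        if len(X) == 0:
            raise ValueError("cannot embed an empty list of environments")
        rows = [
            _hash_tokens(wl_tokenize(env, self.iterations).tokens, self.dim, self.seed)
            for env in X
        ]
        return np.vstack(rows)


class TrainedDocEmbedder(TransformerMixin, BaseEstimator):
    """Corpus-fitted document embedder (randomized-SVD over hashed token counts).

    Stands in for a Doc2Vec-style model: documents are projected onto
    directions learned from a corpus by seeded stochastic factorization.
    """

    def __init__(self, dim: int = 300, hash_dim: int = 4096, seed: int = 0):
        self.dim = dim
        self.hash_dim = hash_dim
        self.seed = seed
        self.fitted_ = False

    def _counts(self, docs) -> np.ndarray:
        M = np.zeros((len(docs), self.hash_dim))
        for i, doc in enumerate(docs):
            for tok in doc.tokens:
                h = hashlib.blake2b(f"{tok}|{self.seed}".encode(), digest_size=8).digest()
                M[i, int.from_bytes(h[:4], "big") % self.hash_dim] += 1.0
        return M

    def fit(self, docs: list[GraphDocument], y=None):
        M = self._counts(docs)
        self._svd = TruncatedSVD(
            n_components=min(self.dim, len(docs) - 1, self.hash_dim - 1),
            algorithm="randomized",
            random_state=self.seed,
        )
        self._svd.fit(M)
        self.fitted_ = True
        return self

    def transform(self, docs: list[GraphDocument]) -> np.ndarray:
        if not self.fitted_:
            raise EmbeddingStateError("TrainedDocEmbedder.transform before fit")
        Z = self._svd.transform(self._counts(docs))
        out = np.zeros((len(docs), self.dim))
        out[:, : Z.shape[1]] = Z
        return out


def embed_environments(
    envs: list[LocalEnvironment],
    dim: int = 300,
    iterations: int = 2,
    backend: str = "hashed",
    seed: int = 0,
) -> np.ndarray:
    """Batch driver: one embedding row per environment, stable ordering."""
    if backend == "hashed":
        return HashedGraphEmbedder(dim=dim, iterations=iterations, seed=seed).fit(
            envs
        ).transform(envs)
    if backend == "trained":
        docs = [wl_tokenize(e, iterations) for e in envs]
        model = TrainedDocEmbedder(dim=dim, seed=seed).fit(docs)
        return model.transform(docs)
    raise ValueError(f"unknown backend {backend!r}")


def write_matrix(path, ids: list[str], matrix: np.ndarray) -> None:
    """Tab-separated matrix with a row-id first column; full float precision."""
    with open(path, "w") as fh:
        for rid, row in zip(ids, matrix):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path) -> tuple[list[str], np.ndarray]:
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return ids, np.asarray(rows)
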