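"""Contextual similarity of medical codes from time-ordered event sequences.

Codes that appear in similar temporal contexts (e.g. a sepsis diagnosis and
the antibiotics ordered around it) should end up in the same phenotype.  The
pipeline is: one token sequence per admission -> distributed embedding of the
code vocabulary -> pairwise cosine similarity per mode -> top-l sparsification
-> normalized-cut rescaling.  The result feeds the symmetric-NMF regularizer
of the constrained decomposition.

Two embedding backends satisfy one contract (codes co-occurring within the
window obtain higher cosine similarity than codes that never co-occur):

* ``"sgns"`` — skip-gram with negative sampling, the stochastic word2vec
  estimator, implemented in numpy and fully seeded;
* ``"ppmi-svd"`` — positive pointwise mutual information of windowed
  co-occurrence followed by rank-d truncated SVD.  Deterministic; the
  default for tests and reproducible runs (SGNS factorizes a shifted PMI
  matrix implicitly, so the two agree qualitatively).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import eigsh
from sklearn.cluster import KMeans

from .data import EventTable
from .errors import ParameterError, PhenotensorError, UndefinedSimilarityError

log = logging.getLogger(__name__)


@dataclass
class SequenceCorpus:
    """Per-admission ordered token lists (diagnoses and prescriptions
    interleaved by time)."""

    sequences: list[list[str]]

    @property
    def vocabulary(self) -> list[str]:
        return sorted({tok for seq in self.sequences for tok in seq})


@dataclass
class EmbeddingTable:
    """token -> dense real vector, all of one dimension."""

    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ParameterError(f"inconsistent embedding dimensions: {dims}")

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[0]

    def __getitem__(self, token: str) -> np.ndarray:
        if token not in self.vectors:
            raise PhenotensorError(f"token {token!r} has no embedding")
        return self.vectors[token]


@dataclass
class SimilarityMatrix:
    """Symmetric nonnegative (after sparsification) similarity per mode."""

    mode: str
    matrix: np.ndarray
    tokens: list[str]
    normalized_cut_applied: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ParameterError("similarity matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ParameterError("similarity matrix must be symmetric")


def build_sequences(events: EventTable) -> SequenceCorpus:
    """One sequence per admission; token order follows the canonical event
    order (timestamp, then diagnosis before prescription, then code), so a
    shuffled copy of the same rows yields the identical corpus."""
    df = events.events  # already canonically sorted by EventTable
    sequences = [
        list(grp["code"]) for _, grp in df.groupby(["patient_id", "admission_id"], sort=True)
    ]
    return SequenceCorpus(sequences=sequences)


# ---------------------------------------------------------------------------
# Embedding backends


def _window_cooccurrence(corpus: SequenceCorpus, vocab: list[str], w: int) -> np.ndarray:
    idx = {t: i for i, t in enumerate(vocab)}
    n = len(vocab)
    counts = np.zeros((n, n))
    for seq in corpus.sequences:
        ids = [idx[t] for t in seq]
        for pos, a in enumerate(ids):
            for b in ids[pos + 1 : pos + 1 + w]:
                counts[a, b] += 1.0
                counts[b, a] += 1.0
    return counts


def _embed_ppmi_svd(corpus: SequenceCorpus, vocab: list[str], d: int, w: int) -> np.ndarray:
    counts = _window_cooccurrence(corpus, vocab, w)
    total = counts.sum()
    if total == 0:
        raise PhenotensorError("corpus has no within-window co-occurrences")
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total / (row @ row.T))
    ppmi = np.where(np.isfinite(pmi), np.maximum(pmi, 0.0), 0.0)
    u, s, _ = np.linalg.svd(ppmi, hermitian=False)
    d = min(d, len(vocab))
    u, s = u[:, :d], s[:d]
    # deterministic sign: largest-magnitude loading of each component positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    return u * flip * np.sqrt(s)


def _embed_sgns(
    corpus: SequenceCorpus,
    vocab: list[str],
    d: int,
    w: int,
    seed: int,
    epochs: int = 5,
    negatives: int = 5,
    lr: float = 0.025,
    batch: int = 1024,
) -> np.ndarray:
    """Minimal seeded skip-gram with negative sampling (vectorized batches)."""
    rng = np.random.default_rng(seed)
    idx = {t: i for i, t in enumerate(vocab)}
    n = len(vocab)
    centers, contexts = [], []
    for seq in corpus.sequences:
        ids = [idx[t] for t in seq]
        for pos, a in enumerate(ids):
            lo = max(0, pos - w)
            for b in ids[lo:pos] + ids[pos + 1 : pos + 1 + w]:
                centers.append(a)
                contexts.append(b)
    if not centers:
        raise PhenotensorError("corpus has no within-window co-occurrences")
    centers = np.asarray(centers)
    contexts = np.asarray(contexts)

    freq = np.bincount(contexts, minlength=n).astype(float)
    noise = freq**0.75
    noise /= noise.sum()

    W = (rng.random((n, d)) - 0.5) / d  # input vectors
    Ctx = np.zeros((n, d))  # output vectors
    n_pairs = centers.size
    total_steps = epochs * n_pairs
    done = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            sl = order[start : start + batch]
            c, o = centers[sl], contexts[sl]
            neg = rng.choice(n, size=(sl.size, negatives), p=noise)
            alpha = lr * max(1e-4, 1.0 - done / total_steps)
            vc = W[c]  # (b, d)
            # positive pair
            pos_score = 1.0 / (1.0 + np.exp(-np.einsum("bd,bd->b", vc, Ctx[o])))
            g_pos = (pos_score - 1.0)[:, None]
            grad_c = g_pos * Ctx[o]
            np.add.at(Ctx, o, -alpha * g_pos * vc)
            # negative pairs
            vn = Ctx[neg]  # (b, k, d)
            neg_score = 1.0 / (1.0 + np.exp(-np.einsum("bd,bkd->bk", vc, vn)))
            grad_c += np.einsum("bk,bkd->bd", neg_score, vn)
            np.add.at(Ctx, neg, -alpha * neg_score[:, :, None] * vc[:, None, :])
            W[c] -= alpha * grad_c
            done += sl.size
    return W


def embed_tokens(
    corpus: SequenceCorpus,
    d: int = 500,
    w: int = 30,
    backend: str = "ppmi-svd",
    seed: int = 0,
) -> EmbeddingTable:
    """Embed the corpus vocabulary into R^d using a symmetric context window
    of ``w`` tokens on each side (within one admission sequence)."""
    if d < 2:
        raise ParameterError("embedding dimension must be >= 2")
    if w < 1:
        raise ParameterError("window must be >= 1")
    vocab = corpus.vocabulary
    if len(vocab) < 2:
        raise PhenotensorError("vocabulary must contain at least 2 tokens")
    if backend == "ppmi-svd":
        if d >= len(vocab):
            warnings.warn(
                f"embedding dim {d} >= vocabulary size {len(vocab)}; clipping",
                stacklevel=2,
            )
        mat = _embed_ppmi_svd(corpus, vocab, d, w)
    elif backend == "sgns":
        mat = _embed_sgns(corpus, vocab, d, w, seed)
    else:
        raise ParameterError(f"unknown embedding backend {backend!r}")
    return EmbeddingTable(vectors={t: mat[i] for i, t in enumerate(vocab)})


# ---------------------------------------------------------------------------
# Similarity construction


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (||u|| ||v||); raises for zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedSimilarityError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def pairwise_similarity_matrix(
    emb: EmbeddingTable, tokens_of_mode: list[str], mode: str = "diagnosis"
) -> SimilarityMatrix:
    """Raw symmetric cosine matrix over one mode's tokens, zero diagonal."""
    missing = [t for t in tokens_of_mode if t not in emb.vectors]
    if missing:
        raise PhenotensorError(f"tokens missing from embedding table: {missing[:5]}")
    mat = np.stack([emb[t] for t in tokens_of_mode])
    norms = np.linalg.norm(mat, axis=1)
    if (norms == 0).any():
        raise UndefinedSimilarityError("zero embedding vector in similarity matrix")
    sims = (mat / norms[:, None]) @ (mat / norms[:, None]).T
    sims = (sims + sims.T) / 2.0
    np.fill_diagonal(sims, 0.0)
    return SimilarityMatrix(mode=mode, matrix=sims, tokens=list(tokens_of_mode))


def auto_top_l(n: int) -> int:
    """The default sparsification degree: floor(log2 n)."""
    l = int(np.floor(np.log2(n))) if n > 0 else 0
    if l <= 0:
        raise ParameterError(f"auto top-l requires matrix order >= 2, got n={n}")
    return l


def sparsify_top_l(S: SimilarityMatrix, l: int | str = "auto") -> SimilarityMatrix:
    """Keep, per row, the l largest nonnegative similarities (ties at the
    cutoff all kept); negatives are dissimilarity and dropped first; result is
    symmetrized by elementwise maximum so no kept edge is lost."""
    if isinstance(l, str):
        if l != "auto":
            raise ParameterError(f"l must be a positive integer or 'auto', got {l!r}")
        l_val = auto_top_l(S.matrix.shape[0])
    else:
        l_val = int(l)
        if l_val <= 0:
            raise ParameterError(f"l must be > 0, got {l_val}")
    mat = np.maximum(S.matrix, 0.0)
    np.fill_diagonal(mat, 0.0)
    n = mat.shape[0]
    kept = np.zeros_like(mat)
    for row in range(n):
        vals = mat[row]
        positive = vals > 0
        if not positive.any():
            continue
        k = min(l_val, int(positive.sum()))
        cutoff = np.sort(vals[positive])[::-1][k - 1]
        keep = positive & (vals >= cutoff)  # ties at the cutoff all survive
        kept[row, keep] = vals[keep]
    sym = np.maximum(kept, kept.T)
    return SimilarityMatrix(mode=S.mode, matrix=sym, tokens=list(S.tokens))


def normalized_cut(S: SimilarityMatrix) -> SimilarityMatrix:
    """Degree-normalize: S <- D^{-1/2} S D^{-1/2}, D = diag(row sums).

    Rows with zero degree (isolated codes) stay identically zero.  The output
    has spectral radius <= 1, which keeps the symmetric-NMF target bounded.
    """
    mat = S.matrix
    if (mat < 0).any():
        raise ParameterError("normalized cut requires a nonnegative matrix")
    d = mat.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    out = mat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return SimilarityMatrix(
        mode=S.mode, matrix=out, tokens=list(S.tokens), normalized_cut_applied=True
    )


def build_similarity(
    events: EventTable,
    mode: str,
    d: int = 500,
    w: int = 30,
    backend: str = "ppmi-svd",
    top_l: int | str = "auto",
    seed: int = 0,
    nc_order: str = "sparsify-first",
) -> SimilarityMatrix:
    """Full similarity pipeline for one mode: sequences -> embedding ->
    cosine -> top-l -> normalized cut.  ``nc_order="nc-first"`` applies the
    normalized cut before sparsification instead."""
    if mode not in ("diagnosis", "prescription"):
        raise ParameterError(f"mode must be diagnosis/prescription, got {mode!r}")
    corpus = build_sequences(events)
    emb = embed_tokens(corpus, d=d, w=w, backend=backend, seed=seed)
    tokens = events.codes(mode)
    raw = pairwise_similarity_matrix(emb, tokens, mode=mode)
    if nc_order == "sparsify-first":
        return normalized_cut(sparsify_top_l(raw, top_l))
    if nc_order == "nc-first":
        clipped = SimilarityMatrix(mode=mode, matrix=np.maximum(raw.matrix, 0.0), tokens=tokens)
        return sparsify_top_l(normalized_cut(clipped), top_l)
    raise ParameterError(f"unknown nc_order {nc_order!r}")


def spectral_partition(S: SimilarityMatrix, k: int, seed: int = 0) -> np.ndarray:
    """Spectral clustering of a (preferably normalized-cut) similarity matrix
    into k groups: leading k eigenvectors, row-normalized, then k-means."""
    n = S.matrix.shape[0]
    if not (2 <= k <= n):
        raise ParameterError(f"need 2 <= k <= n, got k={k}, n={n}")
    if k < n - 1:
        _, vecs = eigsh(S.matrix, k=k, which="LA")
    else:
        _, full = np.linalg.eigh(S.matrix)
        vecs = full[:, -k:]
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    features = vecs / norms
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(features)
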