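"""Seed-lexicon expansion via bigram phrases and skip-gram embeddings.

To pull every note mentioning a memory-loss complaint out of a large
corpus, a small expert seed lexicon (``memory loss``, ``confusion``,
``forgetting``, ...) is expanded: frequent collocations are first merged
into single tokens ("memory loss" -> ``memory_loss``) using the
count-based phrase score

    score(a, b) = (count(ab) - delta) * |V| / (count(a) * count(b)),

then a skip-gram word2vec model with negative sampling is trained on the
merged corpus and the nearest neighbours of each seed are proposed as
expansion candidates.  Candidates are written out for human curation;
only accepted terms join the retrieval query.  Retrieval itself is
case-insensitive, word-boundary-anchored matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Seed terms for memory-loss complaints (unigrams or space-separated
#: bigrams; bigrams are matched against merged phrase tokens).
DEFAULT_SEED_TERMS = (
    "memory loss",
    "confusion",
    "cognition impairment",
    "trouble remembering",
    "not recalling",
    "forgetting",
    "blackout",
)


@dataclass
class SeedLexicon:
    terms: List[str] = field(
        default_factory=lambda: [t for t in DEFAULT_SEED_TERMS])

    def __post_init__(self):
        if not self.terms:
            raise ValueError("seed lexicon must be non-empty")
        self.terms = [t.lower().strip() for t in self.terms]

    def as_tokens(self) -> List[str]:
        """Seed terms in merged-phrase form (spaces -> underscores)."""
        return [t.replace(" ", "_") for t in self.terms]


@dataclass
class EmbeddingConfig:
    dim: int = 50
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    lr: float = 0.025
    min_count: int = 2
    seed: int = 13

    def __post_init__(self):
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")


@dataclass
class ExpansionCandidate:
    term: str
    similarity: float
    nearest_seed: str


def detect_bigrams(corpus: Sequence[Sequence[str]], min_count: int = 5,
                   threshold: float = 10.0, delta: float = 5.0
                   ) -> Tuple[List[List[str]], Dict[str, float]]:
    """Merge collocations into phrase tokens.

    Returns the merged corpus and the accepted phrase vocabulary with
    scores.  A bigram ``(a, b)`` is merged into ``a_b`` iff
    ``count(ab) >= min_count`` and its score exceeds ``threshold``.
    Merging is greedy left-to-right and non-overlapping.
    """
    if not corpus or all(not s for s in corpus):
        raise ValueError("corpus must be non-empty")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    unigram: Dict[str, int] = {}
    bigram: Dict[Tuple[str, str], int] = {}
    for sent in corpus:
        for tok in sent:
            unigram[tok] = unigram.get(tok, 0) + 1
        for a, b in zip(sent, sent[1:]):
            bigram[(a, b)] = bigram.get((a, b), 0) + 1
    vocab_size = len(unigram)
    phrases: Dict[str, float] = {}
    for (a, b), nab in bigram.items():
        if nab < min_count:
            continue
        score = (nab - delta) * vocab_size / (unigram[a] * unigram[b])
        if score > threshold:
            phrases[f"{a}_{b}"] = score
    merged: List[List[str]] = []
    for sent in corpus:
        out: List[str] = []
        i = 0
        while i < len(sent):
            if i + 1 < len(sent) and f"{sent[i]}_{sent[i + 1]}" in phrases:
                out.append(f"{sent[i]}_{sent[i + 1]}")
                i += 2
            else:
                out.append(sent[i])
                i += 1
        merged.append(out)
    return merged, phrases


class EmbeddingModel:
    """Skip-gram word2vec with negative sampling, trained by plain SGD.

    Deterministic for a fixed config seed (single-threaded).  Vectors are
    row-indexed by ``vocabulary``; ``vector`` returns the input embedding.
    """

    def __init__(self, vocabulary: Dict[str, int], vectors: np.ndarray,
                 config: EmbeddingConfig):
        self.vocabulary = vocabulary
        self.vectors = vectors
        self.config = config

    def __contains__(self, term: str) -> bool:
        return term in self.vocabulary

    def vector(self, term: str) -> np.ndarray:
        return self.vectors[self.vocabulary[term]]

    def similarity(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        denom = np.linalg.norm(va) * np.linalg.norm(vb)
        return float(va @ vb / denom) if denom else 0.0

    def most_similar(self, term: str, k: int = 10
                     ) -> List[Tuple[str, float]]:
        v = self.vector(term)
        norms = np.linalg.norm(self.vectors, axis=1) * np.linalg.norm(v)
        norms[norms == 0] = np.inf
        sims = self.vectors @ v / norms
        sims[self.vocabulary[term]] = -np.inf
        order = np.argsort(-sims)[:k]
        inv = {i: w for w, i in self.vocabulary.items()}
        return [(inv[int(i)], float(sims[int(i)])) for i in order]


def train_embeddings(corpus: Sequence[Sequence[str]],
                     config: Optional[EmbeddingConfig] = None
                     ) -> EmbeddingModel:
    """Train skip-gram embeddings with negative sampling on a tokenized
    (post-phrase-merge) corpus."""
    config = config or EmbeddingConfig()
    if not corpus or all(not s for s in corpus):
        raise ValueError("corpus must be non-empty")
    counts: Dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab_words = sorted(w for w, c in counts.items()
                         if c >= config.min_count)
    if not vocab_words:
        raise ValueError("no token meets min_count")
    vocab = {w: i for i, w in enumerate(vocab_words)}
    V, D = len(vocab), config.dim

    rng = np.random.default_rng(config.seed)
    W_in = (rng.random((V, D)) - 0.5) / D
    W_out = np.zeros((V, D))

    # Unigram^0.75 negative-sampling table.
    freq = np.array([counts[w] for w in vocab_words], dtype=float) ** 0.75
    neg_prob = freq / freq.sum()

    sents = [np.array([vocab[t] for t in sent if t in vocab], dtype=int)
             for sent in corpus]
    sents = [s for s in sents if len(s) > 1]
    total_steps = config.epochs * sum(len(s) for s in sents)
    step = 0
    for _ in range(config.epochs):
        for ids in sents:
            n = len(ids)
            # Dynamic window per center, as in the reference algorithm.
            reduced = rng.integers(1, config.window + 1, size=n)
            for pos in range(n):
                step += 1
                lr = config.lr * max(1e-4, 1.0 - step / (total_steps + 1))
                w = reduced[pos]
                lo, hi = max(0, pos - w), min(n, pos + w + 1)
                ctx = np.concatenate([ids[lo:pos], ids[pos + 1:hi]])
                if len(ctx) == 0:
                    continue
                center = ids[pos]
                negs = rng.choice(V, size=len(ctx) * config.negatives,
                                  p=neg_prob)
                targets = np.concatenate([ctx, negs])
                labels = np.concatenate(
                    [np.ones(len(ctx)), np.zeros(len(negs))])
                v = W_in[center]
                u = W_out[targets]
                scores = 1.0 / (1.0 + np.exp(-np.clip(u @ v, -30, 30)))
                g = (labels - scores) * lr
                dv = g @ u
                np.add.at(W_out, targets, g[:, None] * v[None, :])
                W_in[center] += dv
    return EmbeddingModel(vocab, W_in, config)


def expand_terms(model: EmbeddingModel, seeds: SeedLexicon, k: int = 20,
                 min_sim: float = 0.5) -> List[ExpansionCandidate]:
    """Nearest-neighbour expansion candidates for each seed term.

    Seeds absent from the vocabulary are skipped with a warning.  The
    result is deduplicated (best similarity wins), excludes the seeds
    themselves, and is sorted by similarity descending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seed_tokens = seeds.as_tokens()
    best: Dict[str, ExpansionCandidate] = {}
    for seed in seed_tokens:
        if seed not in model:
            logger.warning("seed term %r not in embedding vocabulary", seed)
            continue
        for term, sim in model.most_similar(seed, k):
            if term in seed_tokens or sim < min_sim:
                continue
            if term not in best or sim > best[term].similarity:
                best[term] = ExpansionCandidate(term, sim, seed)
    return sorted(best.values(),
                  key=lambda c: (-c.similarity, c.term))


def _term_pattern(term: str) -> re.Pattern:
    words = [re.escape(w) for w in term.replace("_", " ").split()]
    return re.compile(r"\b" + r"\s+".join(words) + r"\b", re.IGNORECASE)


def match_query(text: str, lexicon: SeedLexicon
                ) -> List[Tuple[int, int]]:
    """Character spans of lexicon-term matches in ``text``.

    Case-insensitive and word-boundary anchored; multi-word terms match
    across a single run of whitespace.  A note counts as retrieved iff
    at least one span matches.
    """
    spans = set()
    for term in lexicon.terms:
        for m in _term_pattern(term).finditer(text):
            spans.add((m.start(), m.end()))
    return sorted(spans)


def retrieved(text: str, lexicon: SeedLexicon) -> bool:
    return bool(match_query(text, lexicon))


def write_candidates(path, candidates: Sequence[ExpansionCandidate]) -> None:
    """Write the human-curation candidate file (term, similarity, seed)."""
    import csv
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["term", "similarity", "nearest_seed"])
        for c in candidates:
            w.writerow([c.term, f"{c.similarity:.4f}", c.nearest_seed])
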