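"""BiLSTM-CRF sequence tagger for the 9-entity BIO scheme.

Architecture: each token is represented by a word embedding (lowercased,
with a learned UNK vector and a capitalization bit) concatenated with the
final states of a character-level BiLSTM; the sequence of token vectors
runs through a word-level BiLSTM whose outputs are projected to per-tag
emission scores, decoded jointly by a linear-chain CRF whose transition
matrix hard-forbids ill-formed BIO sequences.

Everything is plain numpy with hand-written gradients (see
:mod:`memotrace.layers`); training minimizes the CRF negative
log-likelihood with Adam, records span-level validation micro-F1 per
epoch, and early-stops on patience.  All randomness flows from the config
seed, so runs are reproducible single-threaded.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import crf
from .layers import Adam, BiLSTM, Dropout, Embedding, Linear, Param
from .ontology import (AnnotatedNote, Entity, TaggedSequence, bio_tagset,
                       bio_to_entities)
from .text import tokenize

logger = logging.getLogger(__name__)

PAD, UNK = "<pad>", "<unk>"


@dataclass
class TaggerConfig:
    word_dim: int = 64
    char_dim: int = 16          # 0 disables the character channel
    char_hidden: int = 16
    hidden: int = 100           # per direction
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    dropout: float = 0.5
    seed: int = 13
    patience: int = 5
    min_word_count: int = 1

    def __post_init__(self):
        if min(self.word_dim, self.char_hidden, self.hidden, self.epochs,
               self.batch_size) <= 0 or self.char_dim < 0:
            raise ValueError("dimensions and counts must be positive "
                             "(char_dim may be 0)")


def train_validation_sizes(n: int, split: float) -> Tuple[int, int]:
    """Sizes of an ``split``/``1-split`` partition of ``n`` documents."""
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    n_train = int(round(n * split))
    n_train = min(max(n_train, 1), n - 1)
    return n_train, n - n_train


def spans_from_tags(tags: Sequence[str]) -> Set[Tuple[str, int, int]]:
    """Token-index entity spans implied by a BIO tag sequence."""
    out = set()
    i, n = 0, len(tags)
    while i < n:
        if tags[i].startswith("B-"):
            label = tags[i][2:]
            j = i + 1
            while j < n and tags[j] == f"I-{label}":
                j += 1
            out.add((label, i, j))
            i = j
        else:
            i += 1
    return out


def span_micro_f1(gold: Sequence[Sequence[str]],
                  pred: Sequence[Sequence[str]]) -> float:
    """Exact-span micro-F1 between aligned gold and predicted tag rows."""
    tp = fp = fn = 0
    for g, p in zip(gold, pred):
        gs, ps = spans_from_tags(g), spans_from_tags(p)
        tp += len(gs & ps)
        fp += len(ps - gs)
        fn += len(gs - ps)
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


class _Encoder:
    """Token/character vocabularies and batch encoding."""

    def __init__(self, word_vocab: Dict[str, int], char_vocab: Dict[str, int]):
        self.word_vocab = word_vocab
        self.char_vocab = char_vocab

    @classmethod
    def build(cls, sequences: Sequence[TaggedSequence],
              min_word_count: int = 1) -> "_Encoder":
        wc: Dict[str, int] = {}
        chars: Set[str] = set()
        for seq in sequences:
            for tok in seq.tokens:
                w = tok.text.lower()
                wc[w] = wc.get(w, 0) + 1
                chars.update(tok.text)
        words = [PAD, UNK] + sorted(w for w, c in wc.items()
                                    if c >= min_word_count)
        cvoc = [PAD, UNK] + sorted(chars)
        return cls({w: i for i, w in enumerate(words)},
                   {c: i for i, c in enumerate(cvoc)})

    def encode_batch(self, token_rows: Sequence[Sequence[str]]):
        B = len(token_rows)
        T = max(len(r) for r in token_rows)
        W = max((len(t) for r in token_rows for t in r), default=1)
        word_ids = np.zeros((B, T), dtype=int)
        caps = np.zeros((B, T, 1))
        mask = np.zeros((B, T), dtype=bool)
        char_ids = np.zeros((B, T, W), dtype=int)
        char_mask = np.zeros((B, T, W), dtype=bool)
        char_mask[:, :, 0] = True  # padded words get one pad char
        for b, row in enumerate(token_rows):
            for t, tok in enumerate(row):
                word_ids[b, t] = self.word_vocab.get(tok.lower(),
                                                     self.word_vocab[UNK])
                caps[b, t, 0] = 1.0 if any(ch.isupper() for ch in tok) else 0.0
                mask[b, t] = True
                for k, ch in enumerate(tok[:W]):
                    char_ids[b, t, k] = self.char_vocab.get(
                        ch, self.char_vocab[UNK])
                    char_mask[b, t, k] = True
        return word_ids, caps, mask, char_ids, char_mask


class BiLSTMCRF:
    """The trainable model: embedding channels, BiLSTM encoder, CRF head."""

    def __init__(self, encoder: _Encoder, tags: Sequence[str],
                 config: TaggerConfig, rng: np.random.Generator,
                 pretrained: Optional[Dict[str, np.ndarray]] = None):
        self.encoder = encoder
        self.tags = list(tags)
        self.config = config
        L = len(self.tags)
        self.word_emb = Embedding("word_emb", len(encoder.word_vocab),
                                  config.word_dim, rng)
        if pretrained:
            hits = 0
            for w, i in encoder.word_vocab.items():
                vec = pretrained.get(w)
                if vec is not None and len(vec) == config.word_dim:
                    self.word_emb.table.value[i] = vec
                    hits += 1
            logger.info("initialized %d/%d word vectors from pretrained "
                        "embeddings", hits, len(encoder.word_vocab))
        d_token = config.word_dim + 1
        self.use_chars = config.char_dim > 0
        if self.use_chars:
            self.char_emb = Embedding("char_emb", len(encoder.char_vocab),
                                      config.char_dim, rng)
            self.char_lstm = BiLSTM("char_lstm", config.char_dim,
                                    config.char_hidden, rng)
            d_token += 2 * config.char_hidden
        self.lstm = BiLSTM("lstm", d_token, config.hidden, rng)
        self.proj = Linear("proj", 2 * config.hidden, L, rng)
        self.allowed = crf.bio_transition_mask(self.tags)
        trans0 = rng.normal(0.0, 0.01, size=(L + 2, L + 2))
        self.trans = Param("trans", np.where(self.allowed, trans0, crf.NEG_INF))
        self.dropout = Dropout(config.dropout)

    @property
    def params(self) -> List[Param]:
        ps = self.word_emb.params
        if self.use_chars:
            ps = ps + self.char_emb.params + self.char_lstm.params
        return ps + self.lstm.params + self.proj.params + [self.trans]

    def transitions(self) -> np.ndarray:
        return np.where(self.allowed, self.trans.value, crf.NEG_INF)

    # -- forward/backward ---------------------------------------------
    def _emissions(self, batch, rng: Optional[np.random.Generator],
                   train: bool):
        word_ids, caps, mask, char_ids, char_mask = batch
        B, T = word_ids.shape
        wv, wv_cache = self.word_emb.forward(word_ids)
        feats = [wv, caps]
        cache: Dict[str, object] = {"wv_cache": wv_cache, "mask": mask}
        if self.use_chars:
            Hc = self.config.char_hidden
            flat_ids = char_ids.reshape(B * T, -1)
            flat_mask = char_mask.reshape(B * T, -1)
            cv, cv_cache = self.char_emb.forward(flat_ids)
            ch_out, ch_cache = self.char_lstm.forward(cv, flat_mask)
            char_feat = np.concatenate(
                [ch_out[:, -1, :Hc], ch_out[:, 0, Hc:]], axis=1)
            feats.append(char_feat.reshape(B, T, 2 * Hc))
            cache.update(cv_cache=cv_cache, ch_cache=ch_cache,
                         ch_T=ch_out.shape[1])
        x = np.concatenate(feats, axis=2)
        x, dm_in = self.dropout.forward(x, rng, train)
        h, lstm_cache = self.lstm.forward(x, mask)
        h, dm_out = self.dropout.forward(h, rng, train)
        emis, proj_cache = self.proj.forward(h)
        cache.update(lstm_cache=lstm_cache, proj_cache=proj_cache,
                     dm_in=dm_in, dm_out=dm_out, B=B, T=T)
        return emis, cache

    def _backward(self, d_emis: np.ndarray, cache) -> None:
        dh = self.proj.backward(d_emis, cache["proj_cache"])
        dh = self.dropout.backward(dh, cache["dm_out"])
        dx = self.lstm.backward(dh, cache["lstm_cache"])
        dx = self.dropout.backward(dx, cache["dm_in"])
        Dw = self.config.word_dim
        self.word_emb.backward(dx[:, :, :Dw], cache["wv_cache"])
        if self.use_chars:
            Hc = self.config.char_hidden
            B, T = cache["B"], cache["T"]
            d_char = dx[:, :, Dw + 1:].reshape(B * T, 2 * Hc)
            d_ch_out = np.zeros((B * T, cache["ch_T"], 2 * Hc))
            d_ch_out[:, -1, :Hc] = d_char[:, :Hc]
            d_ch_out[:, 0, Hc:] = d_char[:, Hc:]
            d_cv = self.char_lstm.backward(d_ch_out, cache["ch_cache"])
            self.char_emb.backward(d_cv, cache["cv_cache"])

    def loss_and_step(self, batch, tag_ids: np.ndarray, opt: Adam,
                      rng: np.random.Generator) -> float:
        opt.zero_grad()
        emis, cache = self._emissions(batch, rng, train=True)
        nll, d_emis, d_trans = crf.crf_nll_and_grad(
            emis, self.transitions(), tag_ids, cache["mask"])
        self._backward(d_emis, cache)
        self.trans.grad += np.where(self.allowed, d_trans, 0.0)
        opt.step()
        self.trans.value = np.where(self.allowed, self.trans.value,
                                    crf.NEG_INF)
        return nll

    def decode_batch(self, token_rows: Sequence[Sequence[str]]
                     ) -> List[List[str]]:
        if not token_rows:
            return []
        batch = self.encoder.encode_batch(token_rows)
        emis, cache = self._emissions(batch, None, train=False)
        trans = self.transitions()
        out = []
        for b, row in enumerate(token_rows):
            path, _ = crf.viterbi_decode(emis[b, :len(row), :], trans)
            out.append([self.tags[i] for i in path])
        return out

    # -- persistence ---------------------------------------------------
    def state_arrays(self) -> Dict[str, np.ndarray]:
        return {p.name: p.value for p in self.params}

    def load_state(self, arrays: Dict[str, np.ndarray]) -> None:
        for p in self.params:
            p.value[...] = arrays[p.name]

    def snapshot(self) -> Dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params}


@dataclass
class TrainedTagger:
    """A trained model plus its provenance (config, history, tag set)."""

    model: BiLSTMCRF
    config: TaggerConfig
    tags: List[str]
    history: List[dict] = field(default_factory=list)
    rounds: List[dict] = field(default_factory=list)
    reached_threshold: bool = True

    def predict(self, text: str) -> List[Entity]:
        """Extract entities from raw note text."""
        tokens = tokenize(text)
        if not tokens:
            return []
        tag_rows = self.model.decode_batch([[t.text for t in tokens]])
        return bio_to_entities(text, tokens, tag_rows[0])

    def predict_note(self, note: AnnotatedNote) -> AnnotatedNote:
        return note.with_entities(self.predict(note.text))

    def predict_many(self, texts: Sequence[str], batch_size: int = 64
                     ) -> List[List[Entity]]:
        """Batched extraction over many notes (padding-bucketed)."""
        token_lists = [tokenize(t) for t in texts]
        order = sorted(range(len(texts)),
                       key=lambda i: len(token_lists[i]))
        results: List[List[Entity]] = [[] for _ in texts]
        chunk: List[int] = []
        for i in order:
            if not token_lists[i]:
                continue
            chunk.append(i)
            if len(chunk) == batch_size:
                self._flush(chunk, token_lists, texts, results)
                chunk = []
        if chunk:
            self._flush(chunk, token_lists, texts, results)
        return results

    def _flush(self, idxs, token_lists, texts, results) -> None:
        rows = [[t.text for t in token_lists[i]] for i in idxs]
        for i, tags in zip(idxs, self.model.decode_batch(rows)):
            results[i] = bio_to_entities(texts[i], token_lists[i], tags)

    @property
    def validation_f1(self) -> float:
        return self.history[-1]["best_val_f1"] if self.history else 0.0

    # -- serialization -------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "tags": self.tags,
            "word_vocab": self.model.encoder.word_vocab,
            "char_vocab": self.model.encoder.char_vocab,
            "history": self.history,
            "rounds": self.rounds,
            "reached_threshold": self.reached_threshold,
        }
        buf = io.BytesIO()
        np.savez(buf, **self.model.state_arrays())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "TrainedTagger":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = dict(np.load(io.BytesIO(zf.read("params.npz"))))
        config = TaggerConfig(**meta["config"])
        enc = _Encoder(meta["word_vocab"], meta["char_vocab"])
        model = BiLSTMCRF(enc, meta["tags"], config,
                          np.random.default_rng(config.seed))
        model.load_state(arrays)
        return cls(model=model, config=config, tags=meta["tags"],
                   history=meta["history"],
                   rounds=meta.get("rounds", []),
                   reached_threshold=meta["reached_threshold"])


def _batches(indices: List[int], size: int) -> List[List[int]]:
    return [indices[i:i + size] for i in range(0, len(indices), size)]


def train(corpus: Sequence[TaggedSequence], config: TaggerConfig = None,
          split: float = 0.8,
          pretrained: Optional[Dict[str, np.ndarray]] = None,
          tags: Optional[Sequence[str]] = None) -> TrainedTagger:
    """Train a BiLSTM-CRF on BIO-tagged sequences.

    The corpus is shuffled (seeded) and split ``split``/``1-split`` into
    training and validation documents; span-level exact micro-F1 on the
    validation split is recorded every epoch and the best-scoring
    parameters are restored at the end (early stop after
    ``config.patience`` epochs without improvement).
    """
    config = config or TaggerConfig()
    if len(corpus) < 2:
        raise ValueError("need at least 2 documents")
    tagset = list(tags) if tags is not None else bio_tagset()
    for seq in corpus:
        for t in seq.tags:
            if t not in tagset:
                raise ValueError(f"tag {t!r} outside the schema tag set")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(corpus))
    n_train, _ = train_validation_sizes(len(corpus), split)
    train_seqs = [corpus[i] for i in order[:n_train]]
    val_seqs = [corpus[i] for i in order[n_train:]]

    enc = _Encoder.build(train_seqs, config.min_word_count)
    model = BiLSTMCRF(enc, tagset, config, rng, pretrained)
    opt = Adam(model.params, lr=config.lr)
    tag_index = {t: i for i, t in enumerate(tagset)}

    # Pre-encode; bucket by length for dense batches.
    tr_order = sorted(range(len(train_seqs)),
                      key=lambda i: len(train_seqs[i].tokens))
    batches = _batches(tr_order, config.batch_size)
    encoded = []
    for batch_idx in batches:
        rows = [[t.text for t in train_seqs[i].tokens] for i in batch_idx]
        enc_batch = enc.encode_batch(rows)
        T = enc_batch[0].shape[1]
        tag_ids = np.zeros((len(batch_idx), T), dtype=int)
        for b, i in enumerate(batch_idx):
            for t, tag in enumerate(train_seqs[i].tags):
                tag_ids[b, t] = tag_index[tag]
        encoded.append((enc_batch, tag_ids))

    val_rows = [[t.text for t in s.tokens] for s in val_seqs]
    val_gold = [s.tags for s in val_seqs]

    history: List[dict] = []
    best_f1, best_state, since_best = -1.0, model.snapshot(), 0
    for epoch in range(config.epochs):
        perm = rng.permutation(len(encoded))
        losses = []
        for bi in perm:
            enc_batch, tag_ids = encoded[bi]
            losses.append(model.loss_and_step(enc_batch, tag_ids, opt, rng))
        val_pred = model.decode_batch(val_rows)
        val_f1 = span_micro_f1(val_gold, val_pred)
        if val_f1 > best_f1:
            best_f1, best_state, since_best = val_f1, model.snapshot(), 0
        else:
            since_best += 1
        history.append({"epoch": epoch + 1,
                        "train_loss": float(np.mean(losses)),
                        "val_f1": val_f1, "best_val_f1": best_f1})
        logger.info("epoch %d loss %.4f val_f1 %.4f", epoch + 1,
                    history[-1]["train_loss"], val_f1)
        if since_best >= config.patience:
            break
    model.load_state(best_state)
    history[-1]["best_val_f1"] = best_f1
    return TrainedTagger(model=model, config=config, tags=tagset,
                         history=history)


def train_until(corpus_batches: Iterable[Sequence[TaggedSequence]],
                config: TaggerConfig = None, f1_threshold: float = 0.8,
                split: float = 0.8,
                pretrained: Optional[Dict[str, np.ndarray]] = None
                ) -> TrainedTagger:
    """Iterative annotate-train loop: add a batch of annotated notes,
    retrain, and stop once validation micro-F1 exceeds ``f1_threshold``.

    If the batches run out before the threshold is met, the best model is
    returned with ``reached_threshold=False`` and a logged warning.
    """
    config = config or TaggerConfig()
    accumulated: List[TaggedSequence] = []
    best: Optional[TrainedTagger] = None
    rounds = []
    n_batches = 0
    for batch in corpus_batches:
        n_batches += 1
        accumulated.extend(batch)
        tagger = train(accumulated, config, split, pretrained)
        rounds.append({"round": n_batches, "n_notes": len(accumulated),
                       "val_f1": tagger.validation_f1})
        if best is None or tagger.validation_f1 >= best.validation_f1:
            best = tagger
        if tagger.validation_f1 > f1_threshold:
            tagger.rounds = rounds
            return tagger
    if n_batches == 0:
        raise ValueError("need at least one batch of annotated notes")
    logger.warning("F1 threshold %.2f not reached after %d batches "
                   "(best %.3f)", f1_threshold, n_batches,
                   best.validation_f1)
    best.reached_threshold = False
    best.rounds = rounds
    return best
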