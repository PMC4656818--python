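"""Latent semantic indexing of a gene -> literature corpus.

Each gene contributes one document (the concatenated text associated with
it).  The pipeline is classic LSI:

1. tokenize (lowercase, split on whitespace and hyphens, strip
   punctuation, drop stop words);
2. weight the term x document count matrix with the log-entropy scheme —
   local weight ``ln(1 + tf)``, global weight
   ``1 + sum_j p_ij ln(p_ij) / ln(n_docs)`` where ``p_ij = tf_ij / gf_i``
   (a term spread evenly over all documents is muted, a term unique to
   one document keeps full weight);
3. truncated SVD ``W ~ U_k S_k V_k^T``; documents are represented as
   ``S_k V_k^T`` columns and a keyword query is folded in as a
   pseudo-document ``U_k^T q``.

Cosine similarity between the folded query and a gene's document scores
the strength of the gene-keyword association.  Scores above 0.2 indicate
an explicit association (the keyword effectively occurs in the gene's
literature); scores in [0.1, 0.2] an implicit one, carried by shared
context terms rather than the keyword itself (a boundary score of exactly
0.2 classes as implicit); below 0.1 no association is claimed.

Word-cloud support: noun phrases are dismantled into individual words and
counted; a word table carries the occurrence count, its z-score across the
table's words, and the latent-space cosine between the word and the
dataset centroid.  Differential word tables subtract these scores between
two datasets for their common words.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Corpus",
    "LsiModel",
    "LsiResults",
    "tokenize",
    "build_weighted_matrix",
    "lsi_reduce",
    "dismantle_and_count",
    "differential_word_scores",
    "EXPLICIT_THRESHOLD",
    "IMPLICIT_THRESHOLD",
]

logger = logging.getLogger(__name__)

EXPLICIT_THRESHOLD = 0.2
IMPLICIT_THRESHOLD = 0.1

#: Minimal English stop-word list; callers may pass their own.
STOPWORDS = frozenset(
    """a an and are as at be by for from has have in is it its of on or that the
    this to was were which with""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")


def tokenize(text: str, stopwords: frozenset = STOPWORDS) -> list[str]:
    """Lowercase, split on whitespace/hyphens, strip punctuation, drop stop words."""
    tokens = _TOKEN_RE.findall(text.lower().replace("-", " "))
    return [t for t in tokens if t not in stopwords]


@dataclass
class Corpus:
    """gene_id -> concatenated literature text."""

    documents: dict[str, str]

    def __post_init__(self) -> None:
        if not self.documents:
            raise ValueError("corpus has no documents")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.documents)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for gene, text in self.documents.items():
                fh.write(json.dumps({"gene_id": gene, "text": text}) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "Corpus":
        docs = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    docs[rec["gene_id"]] = rec["text"]
        return cls(documents=docs)


def _log_entropy(
    corpus: Corpus, stopwords: frozenset
) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    doc_ids = list(corpus.documents)
    if len(doc_ids) < 2:
        raise ValueError("need at least 2 documents")
    counts = [Counter(tokenize(corpus.documents[d], stopwords)) for d in doc_ids]
    terms = sorted(set().union(*counts))
    if not terms:
        raise ValueError("empty vocabulary after tokenization")
    tf = np.zeros((len(terms), len(doc_ids)))
    index = {t: i for i, t in enumerate(terms)}
    for j, c in enumerate(counts):
        for t, n in c.items():
            tf[index[t], j] = n
    gf = tf.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(gf > 0, tf / gf, 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    global_w = 1.0 + plogp.sum(axis=1) / np.log(len(doc_ids))
    matrix = global_w[:, None] * np.log1p(tf)
    return matrix, terms, doc_ids, global_w


def build_weighted_matrix(
    corpus: Corpus, stopwords: frozenset = STOPWORDS
) -> tuple[np.ndarray, list[str], list[str]]:
    """Log-entropy weighted term x document matrix.

    Returns ``(matrix, terms, doc_ids)`` with terms sorted alphabetically.
    Requires >= 2 documents and a non-empty vocabulary.
    """
    matrix, terms, doc_ids, _ = _log_entropy(corpus, stopwords)
    return matrix, terms, doc_ids


def lsi_reduce(matrix: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-k truncated SVD: returns (U_k, s_k, Vt_k)."""
    max_k = min(matrix.shape)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}], got {k}")
    U, s, Vt = np.linalg.svd(matrix, full_matrices=False)
    return U[:, :k], s[:k], Vt[:k, :]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def classify_score(cosine: float) -> str:
    if cosine > EXPLICIT_THRESHOLD:
        return "explicit"
    if cosine >= IMPLICIT_THRESHOLD:
        return "implicit"
    return "none"


class LsiModel:
    """Latent semantic index over a gene-literature corpus.

    Parameters
    ----------
    corpus
        Gene -> text mapping.
    k
        Latent dimensionality; defaults to ``min(300, rank)``.  The
        published thresholds (0.2 explicit / 0.1 implicit) were tuned for
        reduced-rank spaces; at full rank only explicit (shared-term)
        associations survive.
    """

    def __init__(self, corpus: Corpus, k: int | None = None, stopwords: frozenset = STOPWORDS):
        self.corpus = corpus
        self.stopwords = stopwords
        self.matrix, self.terms, self.doc_ids, self.global_weights = _log_entropy(corpus, stopwords)
        self._term_index = {t: i for i, t in enumerate(self.terms)}
        self.k = min(300, min(self.matrix.shape)) if k is None else k

    def fit(self) -> "LsiResults":
        U, s, Vt = lsi_reduce(self.matrix, self.k)
        return LsiResults(self, U, s, Vt)


class LsiResults:
    """Fitted latent space: document/term vectors and query scoring."""

    def __init__(self, model: LsiModel, U: np.ndarray, s: np.ndarray, Vt: np.ndarray):
        self.model = model
        self.U, self.s, self.Vt = U, s, Vt
        #: documents as rows in the k-dim latent space (S V^T columns)
        self.doc_vectors = (self.s[:, None] * self.Vt).T
        #: terms as rows in the k-dim latent space (U S rows)
        self.term_vectors = self.U * self.s[None, :]

    def _raw_query_vector(self, text: str) -> np.ndarray:
        # same local x global weighting as the corpus documents
        tf = Counter(tokenize(text, self.model.stopwords))
        q = np.zeros(len(self.model.terms))
        for t, n in tf.items():
            i = self.model._term_index.get(t)
            if i is not None:
                q[i] = self.model.global_weights[i] * np.log1p(n)
        return q

    def fold_query(self, text: str) -> np.ndarray:
        """Project a keyword query into the latent space as a pseudo-document."""
        q = self._raw_query_vector(text)
        if not q.any():
            warnings.warn(f"query {text!r} has no in-vocabulary term; scores will be 0")
            return np.zeros(len(self.s))
        return self.U.T @ q

    def keyword_gene_scores(self, query: str, genes: Sequence[str] | None = None) -> pd.DataFrame:
        """Cosine scores of genes against a keyword query, best first.

        Scores > 0.2 class as ``explicit``, [0.1, 0.2] as ``implicit``,
        below 0.1 as ``none``.
        """
        genes = list(genes) if genes is not None else self.model.doc_ids
        missing = set(genes) - set(self.model.doc_ids)
        if missing:
            raise KeyError(f"genes not in corpus: {sorted(missing)}")
        q = self.fold_query(query)
        rows = []
        for g in genes:
            v = self.doc_vectors[self.model.doc_ids.index(g)]
            c = _cosine(q, v)
            rows.append({"subject": g, "query": query, "cosine": c, "class": classify_score(c)})
        return (
            pd.DataFrame(rows, columns=["subject", "query", "cosine", "class"])
            .sort_values("cosine", ascending=False, kind="mergesort")
            .reset_index(drop=True)
        )

    def word_score_table(self, words: Iterable[str]) -> pd.DataFrame:
        """Occurrence count, z-score and centroid cosine for each word.

        Occurrences are counted over the whole corpus; the z-score
        standardizes the counts across the listed words (population SD);
        the cosine compares the word's latent term vector against the
        centroid of all document vectors.  Words absent from the corpus
        are dropped.
        """
        corpus_counts = Counter()
        for text in self.model.corpus.documents.values():
            corpus_counts.update(tokenize(text, self.model.stopwords))
        listed = [w.lower() for w in words]
        rows = []
        centroid = self.doc_vectors.mean(axis=0)
        for w in dict.fromkeys(listed):  # preserve order, dedupe
            n = corpus_counts.get(w, 0)
            if n < 1:
                continue
            i = self.model._term_index[w]
            rows.append({"word": w, "occurrence_count": n, "cosine": _cosine(self.term_vectors[i], centroid)})
        table = pd.DataFrame(rows, columns=["word", "occurrence_count", "cosine"])
        if len(table):
            c = table["occurrence_count"].to_numpy(float)
            sd = c.std()
            table.insert(2, "z_score", (c - c.mean()) / sd if sd > 0 else np.zeros(len(c)))
        else:
            table.insert(2, "z_score", pd.Series(dtype=float))
        return table


def dismantle_and_count(noun_phrases: Sequence[str]) -> pd.DataFrame:
    """Dismantle noun phrases into individual words and count occurrences.

    Phrases are split on whitespace and hyphens, lowercased and stripped
    of punctuation; returns a table of (word, occurrence_count) sorted by
    descending count then alphabetically.
    """
    counts = Counter()
    for phrase in noun_phrases:
        counts.update(tokenize(phrase, stopwords=frozenset()))
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["word", "occurrence_count"])


def differential_word_scores(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-word score differences (a - b) for words common to both tables.

    Subtracts ``z_score`` and ``cosine`` columns where present; sorted by
    descending delta_z (falling back to delta_cosine).  Empty intersection
    yields an empty table with a warning.
    """
    common = sorted(set(a["word"]) & set(b["word"]))
    if not common:
        warnings.warn("no words common to both tables")
        return pd.DataFrame(columns=["word", "delta_z", "delta_cosine"])
    ai = a.set_index("word")
    bi = b.set_index("word")
    out = pd.DataFrame({"word": common})
    for src, dst in (("z_score", "delta_z"), ("cosine", "delta_cosine")):
        if src in a.columns and src in b.columns:
            out[dst] = (ai.loc[common, src].to_numpy() - bi.loc[common, src].to_numpy())
        else:
            out[dst] = np.nan
    sort_key = "delta_z" if out["delta_z"].notna().any() else "delta_cosine"
    return out.sort_values(sort_key, ascending=False, kind="mergesort").reset_index(drop=True)
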