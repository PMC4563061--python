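"""Linear-chain conditional random field over IOB tag sequences.

The model defines p(Y|W) proportional to exp of a sum, over token positions,
of unigram weights lambda_(f, y_t) for every feature f active at t, plus
transition weights lambda_(y_{t-1}, y_t) on adjacent-tag cliques (a virtual
START state supplies the t=0 transition; there is no STOP state).  Training
maximizes the L2-penalized conditional log-likelihood

    sum_seq log p(Y | W)  -  c * ||lambda||^2

which is concave; the optimizer is L-BFGS-B on the exact gradient from the
forward-backward marginals.  Decoding is exact Viterbi with ties broken by
the fixed label order B < I < O, so outputs are bit-reproducible.

One sequence = one physical line of a note: headings never cross line
breaks, and per-line sequences keep the DP short and the training batchable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import scipy.optimize
import scipy.sparse

from .features import FeatureConfig, FeatureSet, Lexicon, build_occurrence_table, extract_all
from .textmodel import Document, HeadingSpan, align_document, decode_iob

logger = logging.getLogger(__name__)

LABELS = ("B", "I", "O")
_LABEL_INDEX = {l: i for i, l in enumerate(LABELS)}
_L = len(LABELS)


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """Numerically stable log-sum-exp along one axis."""
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


@dataclass
class CrfModel:
    """Learned weights: (feature, tag) unigrams plus (tag, tag) transitions."""

    feature_index: dict[str, int]
    unigram: np.ndarray      # (F, 3)
    transition: np.ndarray   # (3, 3), [prev, cur]
    start: np.ndarray        # (3,), virtual START -> tag
    regularization: float = 1.0
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.unigram).all() and np.isfinite(self.transition).all()
                and np.isfinite(self.start).all()):
            raise ValueError("model weights must be finite")

    @classmethod
    def from_weights(
        cls,
        unigram: dict[tuple[str, str], float] | None = None,
        transitions: dict[tuple[str, str], float] | None = None,
        start: dict[str, float] | None = None,
        regularization: float = 0.0,
    ) -> "CrfModel":
        """Build a small explicit model; handy for oracles and worked examples."""
        unigram = unigram or {}
        feats = sorted({f for f, _ in unigram})
        index = {f: i for i, f in enumerate(feats)}
        W = np.zeros((len(feats), _L))
        for (f, tag), w in unigram.items():
            W[index[f], _LABEL_INDEX[tag]] = w
        T = np.zeros((_L, _L))
        for (a, b), w in (transitions or {}).items():
            T[_LABEL_INDEX[a], _LABEL_INDEX[b]] = w
        T0 = np.zeros(_L)
        for tag, w in (start or {}).items():
            T0[_LABEL_INDEX[tag]] = w
        return cls(index, W, T, T0, regularization)

    # -- scoring ------------------------------------------------------------

    def local_scores(self, feats: list[FeatureSet]) -> np.ndarray:
        """Per-position unigram score for each tag; unknown features score 0."""
        U = np.zeros((len(feats), _L))
        for i, fs in enumerate(feats):
            for f in fs:
                j = self.feature_index.get(f)
                if j is not None:
                    U[i] += self.unigram[j]
        return U

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        obj = {
            "labels": list(LABELS),
            "features": {f: self.unigram[i].tolist() for f, i in self.feature_index.items()},
            "transitions": self.transition.tolist(),
            "start": self.start.tolist(),
            "regularization": self.regularization,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(obj), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CrfModel":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        if tuple(obj["labels"]) != LABELS:
            raise ValueError(f"unsupported label set {obj['labels']}")
        names = list(obj["features"])
        index = {f: i for i, f in enumerate(names)}
        W = np.array([obj["features"][f] for f in names]).reshape(len(names), _L)
        return cls(
            index,
            W,
            np.array(obj["transitions"]),
            np.array(obj["start"]),
            float(obj["regularization"]),
            obj.get("metadata", {}),
        )


def score_sequence(model: CrfModel, feats: list[FeatureSet], tags: list[str]) -> float:
    """Unnormalized log-score of one tagging (log p plus log Z)."""
    if len(feats) != len(tags):
        raise ValueError("feature sets and tags must have equal length")
    if not feats:
        return 0.0
    y = [_LABEL_INDEX[t] for t in tags]
    U = model.local_scores(feats)
    s = model.start[y[0]] + U[np.arange(len(y)), y].sum()
    for a, b in zip(y, y[1:]):
        s += model.transition[a, b]
    return float(s)


def log_partition(model: CrfModel, feats: list[FeatureSet]) -> float:
    """log Z by the forward algorithm in log space."""
    if not feats:
        raise ValueError("log_partition is undefined for an empty sequence")
    U = model.local_scores(feats)
    alpha = model.start + U[0]
    for t in range(1, len(feats)):
        alpha = _lse(alpha[:, None] + model.transition, axis=0) + U[t]
    return float(_lse(alpha, axis=0))


def viterbi(model: CrfModel, feats: list[FeatureSet]) -> list[str]:
    """Exact max-score tagging; ties resolved toward the first label in B < I < O."""
    n = len(feats)
    if n == 0:
        return []
    U = model.local_scores(feats)
    delta = model.start + U[0]
    back = np.zeros((n, _L), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + model.transition  # [prev, cur]
        back[t] = cand.argmax(axis=0)  # argmax returns the first maximum: B < I < O
        delta = cand.max(axis=0) + U[t]
    path = [int(delta.argmax())]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return [LABELS[i] for i in reversed(path)]


# ---------------------------------------------------------------------------
# Training


def _prepare(data: list[tuple[list[FeatureSet], list[str]]]):
    """Index features, build the sparse design matrix and length-grouped rows."""
    seqs = [(f, t) for f, t in data if len(f) > 0]
    if not seqs:
        raise ValueError("no non-empty training sequences")
    index: dict[str, int] = {}
    rows, cols = [], []
    y_parts = []
    r = 0
    for feats, tags in seqs:
        if len(feats) != len(tags):
            raise ValueError("feature sets and tags must have equal length")
        for fs, tag in zip(feats, tags):
            for f in sorted(fs):
                j = index.setdefault(f, len(index))
                rows.append(r)
                cols.append(j)
            y_parts.append(_LABEL_INDEX[tag])
            r += 1
    N, F = r, len(index)
    X = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(N, F), dtype=np.float64
    )
    y = np.array(y_parts, dtype=np.intp)

    # Row ids per sequence, grouped by length for batched forward-backward.
    groups: dict[int, list[list[int]]] = {}
    r = 0
    for feats, _ in seqs:
        L = len(feats)
        groups.setdefault(L, []).append(list(range(r, r + L)))
        r += L
    grouped = {L: np.array(rs, dtype=np.intp) for L, rs in groups.items()}

    # Empirical transition counts.
    C_T = np.zeros((_L, _L))
    C_T0 = np.zeros(_L)
    r = 0
    for feats, tags in seqs:
        yy = y[r : r + len(feats)]
        C_T0[yy[0]] += 1
        np.add.at(C_T, (yy[:-1], yy[1:]), 1)
        r += len(feats)

    Y1 = np.zeros((N, _L))
    Y1[np.arange(N), y] = 1.0
    return index, X, y, Y1, grouped, C_T, C_T0


def _nll_and_grad(theta, X, y, Y1, grouped, C_T, C_T0, reg):
    N, F = X.shape
    W = theta[: F * _L].reshape(F, _L)
    T = theta[F * _L : F * _L + _L * _L].reshape(_L, _L)
    T0 = theta[F * _L + _L * _L :]

    U = X @ W  # (N, 3)
    P = np.empty((N, _L))
    E_T = np.zeros((_L, _L))
    E_T0 = np.zeros(_L)
    logZ_total = 0.0
    n_seqs = 0

    for L, rows in grouped.items():  # rows: (m, L)
        m = rows.shape[0]
        n_seqs += m
        u = U[rows]  # (m, L, 3)
        alpha = np.empty((m, L, _L))
        alpha[:, 0] = T0 + u[:, 0]
        for t in range(1, L):
            alpha[:, t] = _lse(alpha[:, t - 1][:, :, None] + T[None], axis=1) + u[:, t]
        logZ = _lse(alpha[:, L - 1], axis=1)  # (m,)
        logZ_total += logZ.sum()
        beta = np.empty((m, L, _L))
        beta[:, L - 1] = 0.0
        for t in range(L - 2, -1, -1):
            beta[:, t] = _lse(T[None] + (u[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2)
        marg = np.exp(alpha + beta - logZ[:, None, None])  # (m, L, 3)
        P[rows.ravel()] = marg.reshape(m * L, _L)
        E_T0 += marg[:, 0].sum(axis=0)
        for t in range(1, L):
            M = np.exp(
                alpha[:, t - 1][:, :, None]
                + T[None]
                + (u[:, t] + beta[:, t])[:, None, :]
                - logZ[:, None, None]
            )
            E_T += M.sum(axis=0)

    gold = U[np.arange(N), y].sum() + (C_T * T).sum() + (C_T0 * T0).sum()
    loglik = gold - logZ_total
    penalty = reg * (np.dot(theta, theta))
    nll = -loglik + penalty

    gW = X.T @ (P - Y1) + 2.0 * reg * W
    gT = (E_T - C_T) + 2.0 * reg * T
    gT0 = (E_T0 - C_T0) + 2.0 * reg * T0
    grad = np.concatenate([np.asarray(gW).ravel(), gT.ravel(), gT0.ravel()])
    return nll, grad


def train(
    data: list[tuple[list[FeatureSet], list[str]]],
    regularization: float = 1.0,
    max_iter: int = 200,
    seed: int = 0,
    verbose: bool = False,
) -> CrfModel:
    """Fit CRF weights on (feature sets, IOB tags) sequences.

    Empty sequences (blank lines) are skipped.  The optimization is
    deterministic given the data order; ``seed`` is recorded in the model
    metadata for provenance of any upstream sampling.
    """
    t0 = time.time()
    index, X, y, Y1, grouped, C_T, C_T0 = _prepare(data)
    F = len(index)
    theta0 = np.zeros(F * _L + _L * _L + _L)
    res = scipy.optimize.minimize(
        _nll_and_grad,
        theta0,
        args=(X, y, Y1, grouped, C_T, C_T0, regularization),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": max_iter, "maxfun": 5 * max_iter},
    )
    W = res.x[: F * _L].reshape(F, _L)
    T = res.x[F * _L : F * _L + _L * _L].reshape(_L, _L)
    T0 = res.x[F * _L + _L * _L :]
    meta = {
        "n_sequences": int(sum(g.shape[0] for g in grouped.values())),
        "n_tokens": int(X.shape[0]),
        "n_features": F,
        "iterations": int(res.nit),
        "final_nll": float(res.fun),
        "converged": bool(res.success),
        "seed": seed,
        "max_iter": max_iter,
        "train_seconds": round(time.time() - t0, 2),
    }
    if verbose:
        logger.info("CRF trained: %s", meta)
    return CrfModel(index, W, T, T0, regularization, meta)


# ---------------------------------------------------------------------------
# Document-level plumbing


def sequences_from_document(
    doc: Document,
    gold: list[HeadingSpan],
    lexicon: Lexicon | None,
    config: FeatureConfig = FeatureConfig(),
    occ: dict[str, str] | None = None,
    lenient: bool = True,
) -> list[tuple[list[FeatureSet], list[str]]]:
    """Per-line (features, tags) training sequences; blank lines are dropped.

    Lenient alignment skips gold spans broken by tokenization noise (merged
    tokens), logging them, which mirrors how corrupted transcriptions have to
    be handled in practice.
    """
    feats = extract_all(doc, lexicon, occ, config)
    tags = align_document(doc, gold, lenient=lenient)
    return [(f, t) for f, t in zip(feats, tags) if f]


def train_on_documents(
    pairs: list[tuple[Document, list[HeadingSpan]]],
    lexicon: Lexicon | None,
    config: FeatureConfig = FeatureConfig(),
    regularization: float = 1.0,
    max_iter: int = 200,
    seed: int = 0,
) -> CrfModel:
    """Extract features over annotated documents and fit the tagger."""
    occ = build_occurrence_table(lexicon) if (lexicon and config.lexicon) else None
    data: list[tuple[list[FeatureSet], list[str]]] = []
    for doc, gold in pairs:
        data.extend(sequences_from_document(doc, gold, lexicon, config, occ))
    model = train(data, regularization=regularization, max_iter=max_iter, seed=seed)
    model.metadata["feature_config"] = {
        k: getattr(config, k) for k in ("word", "affix", "ortho", "lexicon", "semantic", "layout")
    }
    return model


def tag_document(
    model: CrfModel,
    doc: Document,
    lexicon: Lexicon | None = None,
    config: FeatureConfig = FeatureConfig(),
    occ: dict[str, str] | None = None,
) -> list[HeadingSpan]:
    """Predict heading spans: extract -> Viterbi per line -> IOB decode."""
    if config.lexicon and lexicon is not None and occ is None:
        occ = build_occurrence_table(lexicon)
    spans: list[HeadingSpan] = []
    feats = extract_all(doc, lexicon, occ, config)
    for line_feats, toks in zip(feats, doc.tokens_by_line):
        if not toks:
            continue
        tags = viterbi(model, line_feats)
        spans.extend(decode_iob(toks, tags, doc.raw_text))
    return sorted(spans)
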