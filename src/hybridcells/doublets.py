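"""Doublet scoring: co-expression (cxds), classifier (bcds) and combined.

Droplet doublets carry the transcriptomes of two cells, so they (a)
co-detect gene pairs that are mutually exclusive among real cells and
(b) resemble artificial doublets built by summing random cell pairs.
The co-expression score exploits (a), the classifier score (b), and the
combined score stacks the two into one calibrated doublet probability
(or, optionally, averages them after scaling each to [0, 1]).

Fusion hybrids also carry a two-lineage transcriptome, so naive doublet
scoring removes them along with true doublets.  The classifier here is
hybrid-aware: its negative class is augmented with depth-preserving
synthetic fusions, steering it toward the doublet's doubled
library-size/complexity signature instead of co-expression per se.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .io import CountMatrix
from .preprocess import LogNormalizer

__all__ = [
    "DoubletScoreSet",
    "DoubletThreshold",
    "CxdsScorer",
    "BcdsScorer",
    "DoubletScorer",
    "make_artificial_doublets",
    "make_synthetic_fusions",
    "score_cxds",
    "score_bcds",
    "combine_hybrid_score",
    "derive_threshold",
]


@dataclass
class DoubletScoreSet:
    cxds: np.ndarray
    bcds: np.ndarray
    hybrid_score: np.ndarray


@dataclass
class DoubletThreshold:
    method: str  # "mean_plus_2sd" | "fixed"
    value: float
    mean: float = float("nan")
    sd: float = float("nan")


class CxdsScorer(BaseEstimator):
    """Co-expression doublet score.

    Counts are binarized to detection calls.  For each pair of genes the
    mutual-exclusivity weight is the negative log lower-tail binomial
    probability of the observed co-detection count under independence,
    Binom(n, p_i * p_j): pairs co-detected far *below* expectation get
    large weights.  A cell's score sums the weights of the
    ``n_top_pairs`` most exclusive pairs it co-detects, so doublets —
    which merge two detection patterns — score high.  The score depends
    only on the detection pattern, never on count magnitude.
    """

    def __init__(self, n_top_pairs: int = 500, n_top_genes: int = 500):
        self.n_top_pairs = n_top_pairs
        self.n_top_genes = n_top_genes

    def fit(self, X, y=None):
        B = (sp.csc_matrix(X) > 0).astype(np.int8)
        n = B.shape[0]
        p = np.asarray(B.mean(axis=0)).ravel()
        expressed = np.flatnonzero(p > 0)
        if expressed.size < 2:
            raise ValueError("need at least 2 genes expressed in at least 1 cell")
        # restrict to the most variable detection patterns
        k = min(self.n_top_genes, expressed.size)
        var = (p * (1 - p))[expressed]
        subset = expressed[np.argsort(-var, kind="stable")[:k]]
        subset.sort()
        Bs = B[:, subset]
        ps = p[subset]

        O = np.asarray((Bs.T @ Bs).todense(), dtype=float)
        iu, ju = np.triu_indices(k, k=1)
        exp_p = ps[iu] * ps[ju]
        # log-space tail probability: graded weights without underflow
        w = -stats.binom.logcdf(O[iu, ju], n, exp_p)
        bad = ~np.isfinite(w)
        if bad.any():  # logcdf can still hit -inf in the extreme far tail
            w[bad] = 1.05 * w[~bad].max() if (~bad).any() else 1.0

        n_pairs = min(self.n_top_pairs, w.size)
        if n_pairs < self.n_top_pairs:
            warnings.warn(
                f"n_top_pairs={self.n_top_pairs} clamped to {w.size} available pairs")
        top = np.argsort(-w, kind="stable")[:n_pairs]
        self.pair_i_ = subset[iu[top]]
        self.pair_j_ = subset[ju[top]]
        self.pair_weights_ = w[top]
        self.scores_ = self.score_samples(X)
        return self

    def score_samples(self, X) -> np.ndarray:
        B = (sp.csc_matrix(X) > 0).astype(np.int8)
        both = B[:, self.pair_i_].multiply(B[:, self.pair_j_])
        return np.asarray(both @ self.pair_weights_).ravel()


def _random_pairs(rng: np.random.Generator, n: int, k: int):
    a = rng.integers(0, n, k)
    b = rng.integers(0, n, k)
    clash = a == b
    while clash.any():
        b[clash] = rng.integers(0, n, int(clash.sum()))
        clash = a == b
    return a, b


def make_artificial_doublets(X: sp.spmatrix, k: int,
                             rng: np.random.Generator) -> sp.csr_matrix:
    """k artificial doublets: exact sums of random distinct cell pairs."""
    X = sp.csr_matrix(X)
    a, b = _random_pairs(rng, X.shape[0], k)
    return (X[a] + X[b]).tocsr()


def make_synthetic_fusions(X: sp.spmatrix, k: int,
                           rng: np.random.Generator) -> sp.csr_matrix:
    """k depth-preserving synthetic fusions.

    A fusion mixes two cells' transcriptomes *without* doubling the
    library: random pair sums are binomially downsampled to a library
    size drawn from the observed cells.  Used as extra negative examples
    so the doublet classifier learns the doublet's depth/complexity
    signature rather than penalizing lineage co-expression itself — which
    would (and in practice does) remove true fusion hybrids.
    """
    X = sp.csr_matrix(X)
    summed = make_artificial_doublets(X, k, rng).tocoo()
    lib_obs = np.asarray(X.sum(axis=1)).ravel()
    total = np.asarray(summed.tocsr().sum(axis=1)).ravel()
    target = rng.choice(lib_obs, size=k)
    frac = np.minimum(target / np.maximum(total, 1), 1.0)
    data = rng.binomial(summed.data.astype(np.int64), frac[summed.row])
    return sp.csr_matrix((data, (summed.row, summed.col)), shape=summed.shape)


class BcdsScorer(BaseEstimator):
    """Classifier doublet score.

    Artificial doublets (summed random cell pairs) are the positive
    class; observed cells — optionally augmented with depth-preserving
    synthetic fusions (``hybrid_aware``, default on) — are the negative
    class.  A gradient-boosted tree classifier (logistic regression as
    fallback) is trained on log-normalized high-variance features plus
    two library-complexity features (log library size, log detected-gene
    count): summed transcriptomes are roughly twice as deep and complex
    as single cells, which is exactly what distinguishes them from fusion
    hybrids.  Scores for observed cells are out-of-fold predicted
    probabilities, so every cell is scored by a model that never saw it.
    """

    def __init__(self, n_artificial: int | None = None, n_hvg: int = 500,
                 classifier: str = "xgboost", n_folds: int = 5,
                 hybrid_aware: bool = True, seed: int = 0):
        self.n_artificial = n_artificial
        self.n_hvg = n_hvg
        self.classifier = classifier
        self.n_folds = n_folds
        self.hybrid_aware = hybrid_aware
        self.seed = seed

    def _make_classifier(self):
        if self.classifier == "xgboost":
            from xgboost import XGBClassifier

            return XGBClassifier(
                n_estimators=150, max_depth=4, learning_rate=0.2,
                tree_method="hist", n_jobs=1, random_state=self.seed,
                eval_metric="logloss",
            )
        if self.classifier == "logistic":
            from sklearn.linear_model import LogisticRegression

            return LogisticRegression(max_iter=2000, random_state=self.seed)
        raise ValueError(f"unknown classifier {self.classifier!r}")

    def fit(self, X, y=None):
        X = sp.csr_matrix(X)
        n = X.shape[0]
        if n < 100:
            raise ValueError(f"bcds needs >= 100 cells, got {n}")
        rng = np.random.default_rng(self.seed)
        n_art = self.n_artificial or n
        if n_art < 1:
            raise ValueError("need at least one artificial doublet")
        self.artificial_ = make_artificial_doublets(X, n_art, rng)
        n_fus = n_art // 2 if self.hybrid_aware else 0
        self.fusions_ = (make_synthetic_fusions(X, n_fus, rng)
                         if n_fus else sp.csr_matrix((0, X.shape[1])))
        stacked = sp.vstack([X, self.fusions_, self.artificial_], format="csr")

        norm = LogNormalizer().transform(stacked)
        mean = np.asarray(norm.mean(axis=0)).ravel()
        sq = np.asarray(norm.multiply(norm).mean(axis=0)).ravel()
        var = np.maximum(sq - mean ** 2, 0.0)
        feat = np.argsort(-var, kind="stable")[: min(self.n_hvg, norm.shape[1])]
        lib = np.asarray(stacked.sum(axis=1)).ravel()
        detected = np.asarray((stacked > 0).sum(axis=1)).ravel()
        F = np.hstack([
            np.asarray(norm[:, feat].todense(), dtype=np.float32),
            np.log(lib)[:, None].astype(np.float32),
            np.log1p(detected)[:, None].astype(np.float32),
        ])
        labels = np.concatenate([np.zeros(n + n_fus, dtype=int),
                                 np.ones(n_art, dtype=int)])

        cv = StratifiedKFold(self.n_folds, shuffle=True, random_state=self.seed)
        proba = cross_val_predict(self._make_classifier(), F, labels, cv=cv,
                                  method="predict_proba")[:, 1]
        self.scores_ = proba[:n]
        self.fusion_scores_ = proba[n:n + n_fus]
        self.artificial_scores_ = proba[n + n_fus:]
        self.training_labels_ = labels
        return self


def combine_hybrid_score(cxds: np.ndarray, bcds: np.ndarray,
                         mode: str = "minmax") -> np.ndarray:
    """Average of the two scores after per-score normalization to [0, 1].

    ``minmax`` (default) preserves each score's shape, keeping the
    combined distribution right-skewed so a mean + 2 SD cut isolates the
    high-scoring tail; ``rank`` uses average ranks instead.  A constant
    input score normalizes to zeros, so the combination degrades
    gracefully to the informative score alone.
    """
    cxds = np.asarray(cxds, dtype=float)
    bcds = np.asarray(bcds, dtype=float)
    if cxds.shape != bcds.shape:
        raise ValueError(f"score length mismatch: {cxds.shape} vs {bcds.shape}")
    if not (np.isfinite(cxds).all() and np.isfinite(bcds).all()):
        raise ValueError("doublet scores must be finite")

    def _scale(s: np.ndarray) -> np.ndarray:
        if mode == "minmax":
            span = s.max() - s.min()
            return (s - s.min()) / span if span > 0 else np.zeros_like(s)
        if mode == "rank":
            if s.size == 1:
                return np.zeros_like(s)
            r = stats.rankdata(s, method="average")
            return (r - 1.0) / (s.size - 1.0)
        raise ValueError(f"unknown combine mode {mode!r}")

    return 0.5 * (_scale(cxds) + _scale(bcds))


def derive_threshold(scores: np.ndarray, method: str = "mean_plus_2sd",
                     fixed_value: float | None = None) -> DoubletThreshold:
    """Doublet-removal threshold: mean + 2 sample SD, or a fixed value."""
    scores = np.asarray(scores, dtype=float)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed threshold requires fixed_value")
        return DoubletThreshold("fixed", float(fixed_value))
    if method == "mean_plus_2sd":
        if scores.size < 2:
            raise ValueError("mean_plus_2sd needs at least 2 scores")
        m = float(scores.mean())
        sd = float(scores.std(ddof=1))
        return DoubletThreshold("mean_plus_2sd", m + 2 * sd, mean=m, sd=sd)
    raise ValueError(f"unknown threshold method {method!r}")


class DoubletScorer(BaseEstimator):
    """cxds + bcds + combined score in one estimator.

    The default combination (``combine='stack'``) refits a logistic
    model on the two component scores using the artificial-doublet /
    synthetic-fusion training set the classifier score already built:
    the meta-model learns, from data with known labels and without any
    reference to external truth, how much weight each component deserves
    and returns a calibrated doublet probability.  ``'minmax'`` and
    ``'rank'`` fall back to the plain normalized average.
    """

    def __init__(self, n_top_pairs: int = 500, n_top_genes: int = 500,
                 n_artificial: int | None = None, n_hvg: int = 500,
                 classifier: str = "xgboost", combine: str = "stack",
                 hybrid_aware: bool = True, seed: int = 0):
        self.n_top_pairs = n_top_pairs
        self.n_top_genes = n_top_genes
        self.n_artificial = n_artificial
        self.n_hvg = n_hvg
        self.classifier = classifier
        self.combine = combine
        self.hybrid_aware = hybrid_aware
        self.seed = seed

    def fit(self, X, y=None):
        cx = CxdsScorer(self.n_top_pairs, self.n_top_genes).fit(X)
        bc = BcdsScorer(self.n_artificial, self.n_hvg, self.classifier,
                        hybrid_aware=self.hybrid_aware, seed=self.seed).fit(X)
        self.cxds_ = cx.scores_
        self.bcds_ = bc.scores_
        if self.combine == "stack":
            self.hybrid_score_ = self._stack(X, cx, bc)
        else:
            self.hybrid_score_ = combine_hybrid_score(self.cxds_, self.bcds_,
                                                      mode=self.combine)
        return self

    def _stack(self, X, cx: CxdsScorer, bc: BcdsScorer) -> np.ndarray:
        from sklearn.linear_model import LogisticRegression

        n = sp.csr_matrix(X).shape[0]
        cx_all = np.concatenate([
            cx.scores_,
            cx.score_samples(bc.fusions_) if bc.fusions_.shape[0] else np.empty(0),
            cx.score_samples(bc.artificial_),
        ])
        span = cx_all.max() - cx_all.min()
        cx_scaled = ((cx_all - cx_all.min()) / span if span > 0
                     else np.zeros_like(cx_all))
        bc_all = np.concatenate([bc.scores_, bc.fusion_scores_,
                                 bc.artificial_scores_])
        Z = np.column_stack([cx_scaled, bc_all])
        cv = StratifiedKFold(bc.n_folds, shuffle=True, random_state=self.seed)
        meta = LogisticRegression(max_iter=1000, random_state=self.seed)
        proba = cross_val_predict(meta, Z, bc.training_labels_, cv=cv,
                                  method="predict_proba")[:, 1]
        return proba[:n]


def score_cxds(counts: CountMatrix, n_top_pairs: int = 500,
               n_top_genes: int = 500) -> np.ndarray:
    return CxdsScorer(n_top_pairs, n_top_genes).fit(counts.X).scores_


def score_bcds(counts: CountMatrix, n_artificial: int | None = None,
               seed: int = 0, **kwargs) -> np.ndarray:
    return BcdsScorer(n_artificial=n_artificial, seed=seed, **kwargs).fit(
        counts.X).scores_


def score_doublets(counts: CountMatrix, seed: int = 0, **kwargs) -> DoubletScoreSet:
    est = DoubletScorer(seed=seed, **kwargs).fit(counts.X)
    return DoubletScoreSet(cxds=est.cxds_, bcds=est.bcds_,
                           hybrid_score=est.hybrid_score_)
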