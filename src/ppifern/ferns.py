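"""Random Ferns semi-naive Bayes classification.

A fern is an ordered set of S binary tests; the joint outcome of the S
tests indexes one of K = 2^S bins.  An ensemble of M ferns is trained by
counting, per fern, how often each outcome k co-occurs with each class ci
(N_{k,ci}).  Scoring assumes independence *between* ferns but not within
one: the class-conditional likelihood is the product over ferns of the
smoothed outcome probability

    p_{k,ci} = (Nr + N_{k,ci}) / (K * Nr + N_{ci}),

with Nr an additive regularization count so unseen outcomes keep positive
probability.  With a uniform class prior the posterior argmax reduces to
the likelihood argmax; scores are accumulated in the log domain to avoid
underflow at large M.

Binary tests on continuous features are thresholds: f = [x[dim] >
threshold], with thresholds drawn uniformly inside each dimension's
training range.  A pairwise-comparison variant f = [x[d1] > x[d2]] is
available via ``test_kind="pairwise"``.

With the default depth S = 20 each fern has K = 1,048,576 possible
outcomes; tables are stored sparsely (observed outcomes only), so memory
scales with the training set, not with K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_S = 20
DEFAULT_M = 50
DEFAULT_NR = 1.0


@dataclass(frozen=True)
class FernTest:
    """One binary test.  ``threshold`` kind: x[dim] > threshold;
    ``pairwise`` kind: x[dim] > x[dim2]."""

    dim: int
    threshold: float = 0.0
    kind: str = "threshold"
    dim2: int = -1

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "pairwise"):
            raise ValueError(f"unknown test kind {self.kind!r}")
        if self.kind == "threshold" and not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.kind == "pairwise" and self.dim2 < 0:
            raise ValueError("pairwise test needs dim2")


@dataclass
class Fern:
    """S ordered binary tests plus a sparse per-class outcome count table."""

    tests: list[FernTest]
    table: dict[int, np.ndarray] = field(default_factory=dict)  # k -> counts (2,)

    @property
    def S(self) -> int:
        return len(self.tests)


@dataclass
class FernsModel:
    ferns: list[Fern]
    S: int
    M: int
    Nr: float
    class_totals: np.ndarray  # (2,) training instances per class
    train_feature_ranges: np.ndarray  # (D, 2) per-dim (min, max)
    seed: int = 0
    classes: tuple[int, int] = (0, 1)

    @property
    def K(self) -> int:
        return 1 << self.S

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "M": self.M,
            "Nr": self.Nr,
            "seed": self.seed,
            "class_totals": [int(c) for c in self.class_totals],
            "train_feature_ranges": self.train_feature_ranges.tolist(),
            "ferns": [
                {
                    "tests": [
                        {
                            "dim": t.dim,
                            "threshold": t.threshold,
                            "kind": t.kind,
                            "dim2": t.dim2,
                        }
                        for t in fern.tests
                    ],
                    "table": [
                        [int(k), int(c[0]), int(c[1])]
                        for k, c in sorted(fern.table.items())
                    ],
                }
                for fern in self.ferns
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FernsModel":
        ferns = []
        for fd in d["ferns"]:
            tests = [FernTest(**td) for td in fd["tests"]]
            table = {
                int(k): np.array([c0, c1], dtype=np.int64)
                for k, c0, c1 in fd["table"]
            }
            ferns.append(Fern(tests=tests, table=table))
        return cls(
            ferns=ferns,
            S=int(d["S"]),
            M=int(d["M"]),
            Nr=float(d["Nr"]),
            class_totals=np.asarray(d["class_totals"], dtype=np.int64),
            train_feature_ranges=np.asarray(d["train_feature_ranges"], dtype=float),
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# Construction


def sample_ferns(
    D: int,
    S: int,
    M: int,
    ranges: np.ndarray,
    rng: np.random.Generator,
    test_kind: str = "threshold",
) -> list[Fern]:
    """Sample M ferns of S tests each, with empty count tables.

    Test dimensions are uniform over [0, D); thresholds uniform within the
    dimension's (min, max) training range.  A degenerate range (min == max)
    gets its threshold pinned to that value (the test is then always
    false under strict comparison) with a logged warning.
    """
    if D < 1 or S < 1 or M < 1:
        raise ValueError("D, S and M must all be >= 1")
    ranges = np.asarray(ranges, dtype=float)
    if ranges.shape != (D, 2) or not np.isfinite(ranges).all():
        raise ValueError(f"ranges must be finite with shape ({D}, 2)")
    if (ranges[:, 0] > ranges[:, 1]).any():
        raise ValueError("every range must satisfy min <= max")
    degenerate = ranges[:, 0] == ranges[:, 1]
    warned = False
    ferns = []
    for _ in range(M):
        tests = []
        for _ in range(S):
            dim = int(rng.integers(0, D))
            if test_kind == "pairwise":
                dim2 = int(rng.integers(0, D))
                tests.append(FernTest(dim=dim, kind="pairwise", dim2=dim2))
                continue
            lo, hi = ranges[dim]
            if degenerate[dim]:
                if not warned:
                    logger.warning(
                        "degenerate feature range at dim %d (min == max == %g); "
                        "threshold pinned", dim, lo,
                    )
                    warned = True
                threshold = float(lo)
            else:
                threshold = float(rng.uniform(lo, hi))
            tests.append(FernTest(dim=dim, threshold=threshold))
        ferns.append(Fern(tests=tests))
    return ferns


def fern_index(x: np.ndarray, fern: Fern) -> int:
    """The joint outcome of one fern's S tests on a single sample.

    Bit s is 1 iff test s fires; the FIRST test is the least-significant
    bit, so the outcome is sum_s b_s 2^(s-1) in [0, 2^S).
    """
    x = np.asarray(x, dtype=float)
    k = 0
    for s, t in enumerate(fern.tests):
        if t.kind == "threshold":
            bit = x[t.dim] > t.threshold
        else:
            bit = x[t.dim] > x[t.dim2]
        if bit:
            k |= 1 << s
    return k


def _fern_indices(X: np.ndarray, fern: Fern) -> np.ndarray:
    """Vectorized fern_index over the rows of X."""
    dims = np.array([t.dim for t in fern.tests])
    if all(t.kind == "threshold" for t in fern.tests):
        thresholds = np.array([t.threshold for t in fern.tests])
        bits = X[:, dims] > thresholds
    else:
        bits = np.empty((X.shape[0], len(fern.tests)), dtype=bool)
        for s, t in enumerate(fern.tests):
            if t.kind == "threshold":
                bits[:, s] = X[:, t.dim] > t.threshold
            else:
                bits[:, s] = X[:, t.dim] > X[:, t.dim2]
    weights = 1 << np.arange(len(fern.tests), dtype=np.int64)
    return bits @ weights


def fit(
    X: np.ndarray,
    y: np.ndarray,
    S: int = DEFAULT_S,
    M: int = DEFAULT_M,
    Nr: float = DEFAULT_NR,
    rng: np.random.Generator | int = 0,
    test_kind: str = "threshold",
) -> FernsModel:
    """Fit a ferns model: sample tests from the data ranges, then count
    per-fern outcome/class co-occurrences."""
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, D) with one label per row")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"need at least one instance of each class {{0, 1}}, got {classes}"
        )
    ranges = np.stack([X.min(axis=0), X.max(axis=0)], axis=1)
    ferns = sample_ferns(X.shape[1], S, M, ranges, rng, test_kind=test_kind)
    for fern in ferns:
        ks = _fern_indices(X, fern)
        for ci in (0, 1):
            outcomes, counts = np.unique(ks[y == ci], return_counts=True)
            for k, c in zip(outcomes, counts):
                entry = fern.table.setdefault(int(k), np.zeros(2, dtype=np.int64))
                entry[ci] += c
    class_totals = np.array([(y == 0).sum(), (y == 1).sum()], dtype=np.int64)
    return FernsModel(
        ferns=ferns,
        S=S,
        M=M,
        Nr=Nr,
        class_totals=class_totals,
        train_feature_ranges=ranges,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Scoring


def smoothed_prob(
    fern: Fern,
    k: int,
    ci: int,
    Nr: float,
    K: int,
    class_totals: np.ndarray,
) -> float:
    """Regularized outcome probability (Nr + N_{k,ci}) / (K Nr + N_{ci});
    an outcome absent from the sparse table contributes N_{k,ci} = 0."""
    if not 0 <= k < K:
        raise ValueError(f"outcome {k} outside [0, {K})")
    n_kci = float(fern.table[k][ci]) if k in fern.table else 0.0
    return (Nr + n_kci) / (K * Nr + float(class_totals[ci]))


def class_log_scores(model: FernsModel, x: np.ndarray) -> np.ndarray:
    """Per-class log-likelihood over the fern ensemble for one sample or a
    batch of rows; the uniform class prior is a constant and omitted."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    scores = np.zeros((X.shape[0], 2))
    log_denom = np.log(model.K * model.Nr + model.class_totals.astype(float))
    for fern in model.ferns:
        ks = _fern_indices(X, fern)
        if fern.table:
            keys = np.fromiter(sorted(fern.table), dtype=np.int64, count=len(fern.table))
            counts = np.stack([fern.table[int(k)] for k in keys]).astype(float)
        else:
            keys = np.empty(0, dtype=np.int64)
            counts = np.empty((0, 2))
        pos = np.searchsorted(keys, ks)
        pos_clipped = np.clip(pos, 0, max(len(keys) - 1, 0))
        if len(keys):
            hit = keys[pos_clipped] == ks
            n_kci = np.where(hit[:, None], counts[pos_clipped], 0.0)
        else:
            n_kci = np.zeros((X.shape[0], 2))
        scores += np.log(model.Nr + n_kci) - log_denom
    return scores[0] if single else scores


def predict_proba(model: FernsModel, x: np.ndarray) -> np.ndarray:
    """Posterior class probabilities: exp-normalized ensemble log scores."""
    scores = class_log_scores(model, x)
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict(model: FernsModel, x: np.ndarray) -> np.ndarray | int:
    """Most probable class; exact ties break toward class 0 (negative)."""
    scores = class_log_scores(model, x)
    # argmax returns the first maximal index, i.e. class 0 on ties.
    return np.argmax(scores, axis=-1)
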