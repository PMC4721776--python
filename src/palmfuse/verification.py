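"""Genuine/impostor verification with per-identity soft-margin RBF SVMs.

Each enrolled identity gets its own two-class verifier with kernel
K(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 sigma^2)), trained on that
identity's feature vectors (positives) against an equal number of feature
vectors drawn from other identities (negatives).  Performance is reported
as the false rejection rate FRR = NFR/NPT x 100% and false acceptance
rate FAR = NFA/NNT x 100% aggregated over identities and folds of a
k-fold protocol: (k-1)/k of each identity's samples train its verifier,
the held-out 1/k are genuine test trials, matched one-for-one by impostor
trials from other identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import PalmFuseError

GENUINE, IMPOSTOR = 1, 0

#: Hyperparameter grids: C over powers of two, sigma as multiples of the
#: median pairwise training distance (a standard kernel-width heuristic).
C_GRID = tuple(2.0**e for e in range(-2, 9, 2))
SIGMA_FACTOR_GRID = tuple(2.0**e for e in range(-4, 5, 2))


def _sigma_to_gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma * sigma)


class IdentityVerifier(BaseEstimator, ClassifierMixin):
    """Two-class RBF-SVM verifier for one enrolled identity.

    Parameters
    ----------
    C : float or None
        Soft-margin tradeoff.  None selects it by inner 3-fold CV over
        ``C_GRID``.
    sigma : float or None
        RBF kernel width.  None selects it by inner CV over
        ``SIGMA_FACTOR_GRID`` times the median pairwise distance of the
        training set.
    identity : hashable
        Label of the enrolled identity (informational).

    Attributes
    ----------
    svc_ : fitted sklearn SVC
    C_, sigma_ : the hyperparameters actually used
    separable_ : False when the trained model cannot separate its own
        training set (degenerate enrolment), else True.
    """

    def __init__(self, C: float | None = None, sigma: float | None = None, identity=None):
        self.C = C
        self.sigma = sigma
        self.identity = identity

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise PalmFuseError("X must be 2-D (n_samples, n_features)")
        if len(X) != len(y):
            raise PalmFuseError("X and y length mismatch")
        classes = np.unique(y)
        if len(classes) != 2:
            raise PalmFuseError("need exactly two classes (genuine/impostor)")
        self.C_, self.sigma_ = self._select_hyperparameters(X, y)
        self.svc_ = SVC(C=self.C_, kernel="rbf", gamma=_sigma_to_gamma(self.sigma_))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.svc_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        train_acc = float(np.mean(self.svc_.predict(X) == y))
        self.separable_ = train_acc > 0.5
        if not self.separable_:
            warnings.warn(
                f"verifier for identity {self.identity!r} cannot separate its "
                "training data (degenerate enrolment)",
                stacklevel=2,
            )
        return self

    def _median_distance(self, X) -> float:
        if len(X) < 2:
            return 1.0
        d = pdist(X)
        med = float(np.median(d[d > 0])) if (d > 0).any() else 1.0
        return med if med > 0 else 1.0

    def _select_hyperparameters(self, X, y):
        med = self._median_distance(X)
        if self.C is not None and self.sigma is not None:
            return float(self.C), float(self.sigma)
        c_grid = [float(self.C)] if self.C is not None else list(C_GRID)
        s_grid = [float(self.sigma)] if self.sigma is not None else [f * med for f in SIGMA_FACTOR_GRID]
        n_splits = min(3, int(np.min(np.bincount(y.astype(int)))))
        if n_splits < 2:
            return c_grid[0], s_grid[len(s_grid) // 2]
        cv = StratifiedKFold(n_splits=n_splits, shuffle=False)
        best, best_score = (c_grid[0], s_grid[len(s_grid) // 2]), -1.0
        for C in c_grid:
            for sigma in s_grid:
                score = 0.0
                for tr, te in cv.split(X, y):
                    m = SVC(C=C, kernel="rbf", gamma=_sigma_to_gamma(sigma))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        m.fit(X[tr], y[tr])
                    score += float(np.mean(m.predict(X[te]) == y[te]))
                score /= cv.get_n_splits()
                if score > best_score:
                    best, best_score = (C, sigma), score
        return best

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise PalmFuseError("feature dimension mismatch")
        return self.svc_.predict(X)


def train_verifier(pos, neg, C: float | None = None, sigma: float | None = None,
                   identity=None) -> IdentityVerifier:
    """Train a verifier from genuine (pos) and impostor (neg) vectors."""
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if len(pos) == 0 or len(neg) == 0:
        raise PalmFuseError("need at least one sample per class")
    if pos.shape[1] != neg.shape[1]:
        raise PalmFuseError("feature dimension mismatch")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.full(len(pos), GENUINE), np.full(len(neg), IMPOSTOR)])
    return IdentityVerifier(C=C, sigma=sigma, identity=identity).fit(X, y)


def verify_sample(model: IdentityVerifier, feat) -> str:
    """Deterministic genuine/impostor decision for one feature vector."""
    label = int(model.predict(np.atleast_2d(feat))[0])
    return "genuine" if label == GENUINE else "impostor"


@dataclass
class VerificationReport:
    """FRR/FAR with the underlying trial counts and per-trial decisions."""

    NPT: int = 0  # positive (genuine) test trials
    NNT: int = 0  # negative (impostor) test trials
    NFR: int = 0  # false rejections
    NFA: int = 0  # false acceptances
    trials: list = field(default_factory=list)  # (identity, fold, kind, accepted)
    config: dict = field(default_factory=dict)

    @property
    def frr(self) -> float:
        """False rejection rate, percent."""
        return 100.0 * self.NFR / self.NPT if self.NPT else 0.0

    @property
    def far(self) -> float:
        """False acceptance rate, percent."""
        return 100.0 * self.NFA / self.NNT if self.NNT else 0.0

    def recompute_from_trials(self) -> "VerificationReport":
        """Re-derive the counts from the stored per-trial decisions."""
        rep = VerificationReport(config=dict(self.config), trials=list(self.trials))
        for _ident, _fold, kind, accepted in self.trials:
            if kind == "genuine":
                rep.NPT += 1
                rep.NFR += int(not accepted)
            else:
                rep.NNT += 1
                rep.NFA += int(accepted)
        return rep

    def as_dict(self) -> dict:
        return {
            "NPT": self.NPT, "NNT": self.NNT, "NFR": self.NFR, "NFA": self.NFA,
            "FRR_percent": self.frr, "FAR_percent": self.far, "config": self.config,
        }


def _stratified_draw(rng: np.random.Generator, pools: dict, count: int) -> list:
    """Draw `count` items spread round-robin over the pools (no replacement)."""
    order = sorted(pools)
    shuffled = {k: [pools[k][i] for i in rng.permutation(len(pools[k]))] for k in order}
    out, idx = [], 0
    keys = [k for k in order if shuffled[k]]
    while len(out) < count and keys:
        k = keys[idx % len(keys)]
        out.append(shuffled[k].pop())
        if not shuffled[k]:
            keys.remove(k)
        else:
            idx += 1
    if len(out) < count:
        raise PalmFuseError("insufficient samples for negative draws")
    return out


def evaluate_kfold(cohort: dict, k: int, seed: int, C: float | None = None,
                   sigma: float | None = None) -> VerificationReport:
    """k-fold verification over a cohort {identity: (n_i, d) feature array}.

    Per identity and fold: (k-1)/k of its samples are genuine training
    samples, matched by an equal number of impostor training samples drawn
    (seeded, stratified across the other identities, without replacement);
    the held-out 1/k genuine samples and an equal number of held-out
    impostor samples are test trials.  Counts are aggregated over all
    identities and folds.
    """
    if k < 2:
        raise PalmFuseError("k must be >= 2")
    idents = sorted(cohort)
    feats = {i: np.asarray(cohort[i], dtype=float) for i in idents}
    if len(idents) < 2:
        raise PalmFuseError("need at least two identities")
    for i in idents:
        if len(feats[i]) < k:
            raise PalmFuseError(f"insufficient samples: identity {i!r} has "
                                f"{len(feats[i])} < k={k}")
    rng = np.random.default_rng(seed)
    report = VerificationReport(config={"k": k, "seed": seed, "C": C, "sigma": sigma})

    folds = {}
    for i in idents:
        n = len(feats[i])
        perm = rng.permutation(n)
        folds[i] = np.array_split(perm, k)

    for fold in range(k):
        for ident in idents:
            test_idx = folds[ident][fold]
            train_idx = np.concatenate([folds[ident][f] for f in range(k) if f != fold])
            if len(test_idx) == 0:
                continue
            pos_train = feats[ident][train_idx]
            pos_test = feats[ident][test_idx]
            # impostor pools: other identities, same fold split roles
            train_pool = {
                j: [feats[j][t] for f in range(k) if f != fold for t in folds[j][f]]
                for j in idents if j != ident
            }
            test_pool = {
                j: [feats[j][t] for t in folds[j][fold]] for j in idents if j != ident
            }
            neg_train = np.array(_stratified_draw(rng, train_pool, len(pos_train)))
            neg_test = np.array(_stratified_draw(rng, test_pool, len(pos_test)))

            model = train_verifier(pos_train, neg_train, C=C, sigma=sigma, identity=ident)
            for x in pos_test:
                accepted = verify_sample(model, x) == "genuine"
                report.NPT += 1
                report.NFR += int(not accepted)
                report.trials.append((ident, fold, "genuine", accepted))
            for x in neg_test:
                accepted = verify_sample(model, x) == "genuine"
                report.NNT += 1
                report.NFA += int(accepted)
                report.trials.append((ident, fold, "impostor", accepted))
    return report
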