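"""Weighted k-NN assignment of step parameters to NtC classes.

The classifier works in the scaled, periodicity-aware 12-dimensional
parameter space: for the ten angular dimensions the per-axis displacement is
the circular difference, for the two distances the absolute difference, each
divided by a positive per-dimension scale.  Among the k nearest training
points each votes for its class with weight 1/d^2; a query whose nearest
training point lies beyond the rejection cutoff goes to the formally 97th
"unassigned" class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .geometry import StepParameters, circular_difference
from .reference import ReferenceSet, UNASSIGNED_CANA, UNASSIGNED_NTC

__all__ = [
    "parameter_distance",
    "NtCClassifier",
    "assign_step",
    "Assignment",
    "DistanceProfile",
    "DEFAULT_CUTOFF",
]

#: default rejection cutoff in scaled units
DEFAULT_CUTOFF = 4.5

_N_CIRCULAR = 10


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, StepParameters):
        X = X.as_array()[None, :]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != 12:
        raise ValueError(f"expected (n, 12) parameter vectors, got shape {X.shape}")
    return X


def _distance_matrix(P: np.ndarray, Q: np.ndarray, scaling: np.ndarray) -> np.ndarray:
    """Pairwise scaled periodicity-aware distances, shape (len(P), len(Q))."""
    d_ang = circular_difference(P[:, None, :_N_CIRCULAR], Q[None, :, :_N_CIRCULAR])
    d_lin = np.abs(P[:, None, _N_CIRCULAR:] - Q[None, :, _N_CIRCULAR:])
    d = np.concatenate([d_ang, d_lin], axis=2) / scaling
    return np.sqrt(np.sum(d * d, axis=2))


def parameter_distance(p, q, scaling=None) -> float:
    """Scaled periodicity-aware Euclidean distance between two parameter vectors.

    ``scaling`` is a vector of 12 positive weights (defaults to all ones);
    angular displacements use the circular difference.
    """
    P = _as_matrix(p)
    Q = _as_matrix(q)
    scaling = np.ones(12) if scaling is None else np.asarray(scaling, dtype=float)
    if scaling.shape != (12,) or np.any(scaling <= 0):
        raise ValueError("scaling must be 12 positive weights")
    return float(_distance_matrix(P, Q, scaling)[0, 0])


@dataclass
class DistanceProfile:
    """Per-class distances of one step: scaled parameter-space distance and,
    once diagnostics fill it in, the Cartesian r.m.s.d. to each representative."""

    euclid: dict = field(default_factory=dict)  # ntc code -> float
    rmsd: dict = field(default_factory=dict)    # ntc code -> float (may be empty)


@dataclass
class Assignment:
    """Result of assigning one step."""

    step_name: str
    ntc: str
    cana: str
    nn_distance: float
    votes: dict = field(default_factory=dict)
    distance_profile: DistanceProfile | None = None
    confal: "object" = None         # ConfalBreakdown, filled by confal scoring
    rmsd_to_assigned: float | None = None

    @property
    def assigned(self) -> bool:
        return self.ntc != UNASSIGNED_NTC


class NtCClassifier(ClassifierMixin, BaseEstimator):
    """Periodicity-aware inverse-square-weighted k-NN conformer classifier.

    Parameters
    ----------
    k : int or None
        Neighborhood size.  ``None`` selects 1 when the training set has a
        single point per class (the class-means fallback) and 11 otherwise.
    cutoff : float or None
        Rejection threshold in scaled units: a query whose nearest training
        point is farther than this is labeled ``unassigned_label``.  ``None``
        disables rejection.
    scaling : array-like of 12 positive floats, or None
        Per-dimension scale making degrees and angstroms commensurate.
        ``None`` means unit weights; :meth:`from_reference` substitutes the
        class-pooled e.s.d.
    unassigned_label : str
        Label reported for rejected queries.

    Attributes
    ----------
    X_ : ndarray of shape (n_samples, 12)
        Training parameter vectors.
    y_ : ndarray of shape (n_samples,)
        Training labels.
    classes_ : ndarray
        Sorted unique training labels.
    k_ : int
        Effective neighborhood size.
    scaling_ : ndarray of shape (12,)
        Effective per-dimension scaling.
    """

    def __init__(self, k: int | None = None, cutoff: float | None = DEFAULT_CUTOFF,
                 scaling=None, unassigned_label: str = UNASSIGNED_NTC):
        self.k = k
        self.cutoff = cutoff
        self.scaling = scaling
        self.unassigned_label = unassigned_label

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y disagree in length")
        if len(X) == 0:
            raise ValueError("training set must be non-empty")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        if self.k is not None:
            if self.k < 1:
                raise ValueError("k must be >= 1")
            self.k_ = int(self.k)
        else:
            self.k_ = 1 if max(counts.values()) == 1 else 11
        self.k_ = min(self.k_, len(X))
        if self.scaling is None:
            self.scaling_ = np.ones(12)
        else:
            self.scaling_ = np.asarray(self.scaling, dtype=float)
            if self.scaling_.shape != (12,) or np.any(self.scaling_ <= 0):
                raise ValueError("scaling must be 12 positive weights")
        return self

    @classmethod
    def from_reference(cls, refset: ReferenceSet, training=None, k=None,
                       cutoff=DEFAULT_CUTOFF, scaling=None) -> "NtCClassifier":
        """Fit against a reference set.

        Without an explicit ``training`` pair (X, y) the classifier falls
        back to one point per class — the class means — which makes the
        assignment nearest-class behavior.  ``scaling=None`` uses the
        class-pooled e.s.d. per parameter.
        """
        if scaling is None:
            scaling = refset.pooled_esd()
        est = cls(k=k, cutoff=cutoff, scaling=scaling)
        if training is None:
            est.fit(refset.means_matrix(), np.array(refset.codes))
        else:
            est.fit(*training)
        return est

    def _check_fitted(self):
        if not hasattr(self, "X_"):
            raise RuntimeError("classifier is not fitted")

    def distances(self, X) -> np.ndarray:
        """Scaled distances from each query row to every training point."""
        self._check_fitted()
        return _distance_matrix(_as_matrix(X), self.X_, self.scaling_)

    def _assign_row(self, dist: np.ndarray):
        order = np.argsort(dist, kind="stable")
        nn = float(dist[order[0]])
        if self.cutoff is not None and nn > self.cutoff:
            return self.unassigned_label, nn, {}
        if nn == 0.0:  # exact hit: immediate assignment
            label = self.y_[order[0]]
            return label, nn, {label: np.inf}
        kidx = order[:self.k_]
        votes: dict = {}
        nearest: dict = {}
        for i in kidx:
            label = self.y_[i]
            votes[label] = votes.get(label, 0.0) + 1.0 / float(dist[i]) ** 2
            nearest[label] = min(nearest.get(label, np.inf), float(dist[i]))
        # maximal summed weight; ties -> smaller nearest-member distance,
        # then lexicographic code (determinism)
        label = min(votes, key=lambda c: (-votes[c], nearest[c], str(c)))
        return label, nn, votes

    def predict(self, X) -> np.ndarray:
        D = self.distances(X)
        return np.array([self._assign_row(row)[0] for row in D])

    def predict_detail(self, X):
        """Like predict, but returns (label, nn_distance, votes) per query."""
        D = self.distances(X)
        return [self._assign_row(row) for row in D]


def assign_step(params, training, k: int | None = None,
                cutoff: float | None = DEFAULT_CUTOFF, scaling=None,
                refset: ReferenceSet | None = None,
                step_name: str = "") -> Assignment:
    """Assign one step's parameter vector to an NtC class.

    ``training`` is either a fitted :class:`NtCClassifier` or an ``(X, y)``
    pair of labeled parameter vectors.  The per-class scaled-distance profile
    is filled from class means when ``refset`` is given.
    """
    if isinstance(training, NtCClassifier):
        clf = training
    else:
        clf = NtCClassifier(k=k, cutoff=cutoff, scaling=scaling).fit(*training)
    p = params.as_array() if isinstance(params, StepParameters) else np.asarray(params, float)
    label, nn, votes = clf.predict_detail(p)[0]
    profile = None
    cana = UNASSIGNED_CANA
    if refset is not None:
        d = _distance_matrix(p[None, :], refset.means_matrix(), clf.scaling_)[0]
        profile = DistanceProfile(euclid=dict(zip(refset.codes, map(float, d))))
        cana = refset.cana_of(label) if label in refset.codes or label == refset.unassigned_code \
            else UNASSIGNED_CANA
    return Assignment(step_name=step_name, ntc=str(label), cana=cana,
                      nn_distance=nn, votes=votes, distance_profile=profile)
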