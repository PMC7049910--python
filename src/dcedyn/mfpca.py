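"""Multivariate functional PCA: one score per subject per region unit.

A dynamic descriptor is a set of D elements, each a function of time
observed on a common frame grid for P subjects.  The reduction is
four-step: (1) center each element across subjects; (2) univariate
functional PCA per element, keeping M eigenfunctions (default 5) with
scores given by the quadrature-weighted inner product of each subject's
curve with each eigenfunction; (3) stack the P x M score blocks of all
elements into a P x (D*M) matrix; (4) eigenanalysis of that matrix's
covariance, projecting subjects on the leading eigenvector.  The first-mode
projection is the subject's score.

The time integral is discretised with trapezoidal quadrature weights
(exact for piecewise-linear curves on the frame grid); eigenfunctions are
orthonormal under the weighted inner product and eigenvalue k equals the
sample variance of score k.  Eigenvector signs are arbitrary in principle;
here each univariate eigenfunction has its largest-magnitude value
positive, and the joint first mode is oriented to correlate non-negatively
with the row sums of the score matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FunctionalSample", "UnivariateFpcaResult", "JointScoreMatrix",
           "center", "univariate_fpca", "assemble_scores", "first_mode_scores",
           "trapezoid_weights", "mfpca_first_mode"]


def trapezoid_weights(times: np.ndarray) -> np.ndarray:
    """Trapezoidal quadrature weights; they sum to the total duration."""
    t = np.asarray(times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 time points")
    w = np.empty_like(t)
    w[0] = (t[1] - t[0]) / 2
    w[-1] = (t[-1] - t[-2]) / 2
    w[1:-1] = (t[2:] - t[:-2]) / 2
    return w


@dataclass
class FunctionalSample:
    """P subjects' curves for one element: ``values[i, t]`` on a common grid."""

    values: np.ndarray
    times: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[1] != len(self.times):
            raise ValueError("values and times disagree on grid length")
        if self.weights is None:
            self.weights = trapezoid_weights(self.times)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("quadrature weights must be positive")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class UnivariateFpcaResult:
    eigenfunctions: np.ndarray   # M x T, orthonormal under the quadrature product
    eigenvalues: np.ndarray      # M, non-increasing
    scores: np.ndarray           # P x M
    mean: np.ndarray             # T
    total_variance: float        # sum of all covariance-operator eigenvalues
    weights: np.ndarray

    @property
    def explained_fraction(self) -> np.ndarray:
        if self.total_variance <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance


def center(sample: FunctionalSample) -> FunctionalSample:
    """Subtract the pointwise-in-t mean across subjects."""
    if sample.n_subjects < 2:
        raise ValueError("centering requires at least 2 subjects")
    return FunctionalSample(values=sample.values - sample.values.mean(axis=0),
                            times=sample.times, weights=sample.weights)


def univariate_fpca(sample: FunctionalSample, M: int = 5) -> UnivariateFpcaResult:
    """Eigenpairs of the empirical covariance operator, quadrature discretised.

    With W = diag(weights), the operator eigenproblem reduces to the SVD of
    ``Xc sqrt(W)``: eigenfunctions are the right singular vectors rescaled
    by 1/sqrt(w), eigenvalues are squared singular values / (P-1), and the
    scores (integral of eigenfunction times curve) are U * s.  If the data
    rank is below M the missing modes are zero-padded with a warning.
    """
    P, T = sample.values.shape
    if M < 1 or M > min(P - 1, T):
        raise ValueError(f"M={M} must satisfy 1 <= M <= min(P-1, T) = {min(P-1, T)}")
    mean = sample.values.mean(axis=0)
    Xc = sample.values - mean
    sw = np.sqrt(sample.weights)
    U, s, Vt = np.linalg.svd(Xc * sw, full_matrices=False)
    eigvals_all = s ** 2 / (P - 1)
    total = float(eigvals_all.sum())

    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    keep = min(M, rank)
    if keep < M:
        warnings.warn(f"data rank {keep} below M={M}; padding modes with zeros",
                      stacklevel=2)
    phi = np.zeros((M, T))
    scores = np.zeros((P, M))
    eigvals = np.zeros(M)
    for k in range(keep):
        f = Vt[k] / sw
        # deterministic sign: largest-magnitude value positive
        j = int(np.argmax(np.abs(f)))
        sign = 1.0 if f[j] >= 0 else -1.0
        phi[k] = sign * f
        scores[:, k] = sign * U[:, k] * s[k]
        eigvals[k] = eigvals_all[k]
    return UnivariateFpcaResult(eigenfunctions=phi, eigenvalues=eigvals,
                                scores=scores, mean=mean, total_variance=total,
                                weights=sample.weights)


@dataclass
class JointScoreMatrix:
    """Stacked univariate scores: row i is (xi_i1^(1)..xi_iM^(1), ..., xi_iM^(D))."""

    matrix: np.ndarray                       # P x sum(M_j)
    blocks: list[tuple[int, int]] = field(default_factory=list)  # (start, stop) per element


def assemble_scores(results: list[UnivariateFpcaResult]) -> JointScoreMatrix:
    """Concatenate each element's P x M score block, in element order."""
    if not results:
        raise ValueError("no univariate results to assemble")
    P = results[0].scores.shape[0]
    if any(r.scores.shape[0] != P for r in results):
        raise ValueError("inconsistent subject count across elements")
    blocks = []
    start = 0
    for r in results:
        stop = start + r.scores.shape[1]
        blocks.append((start, stop))
        start = stop
    return JointScoreMatrix(matrix=np.hstack([r.scores for r in results]),
                            blocks=blocks)


def first_mode_scores(joint: JointScoreMatrix | np.ndarray
                      ) -> tuple[np.ndarray, float]:
    """Project subjects on the leading eigenvector of cov(Xi).

    Returns (scores, explained-variance fraction).  The sign is fixed so
    the scores correlate non-negatively with the row sums of Xi.
    """
    Xi = joint.matrix if isinstance(joint, JointScoreMatrix) else np.asarray(joint)
    P = Xi.shape[0]
    if P < 2:
        raise ValueError("need at least 2 subjects")
    Xc = Xi - Xi.mean(axis=0)
    cov = Xc.T @ Xc / (P - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] <= max(1e-300, 1e-14 * abs(np.trace(cov))):
        raise ValueError("degenerate covariance: no varying direction")
    scores = Xc @ evecs[:, 0]
    rowsum = Xc.sum(axis=1)
    if scores @ rowsum < 0:
        scores = -scores
    explained = float(evals[0] / evals.sum())
    return scores, explained


def mfpca_first_mode(trajectories: np.ndarray, times: np.ndarray, M: int = 5
                     ) -> tuple[np.ndarray, float]:
    """Full four-step reduction of a P x D x T descriptor array.

    Returns the P first-mode scores and the joint explained-variance
    fraction.  M is capped per element at min(P-1, T); elements whose data
    rank is below M contribute zero-padded score columns.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3:
        raise ValueError("trajectories must be P x D x T")
    P, D, T = traj.shape
    m_eff = min(M, P - 1, T)
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank padding is routine for sparse bins
        for j in range(D):
            sample = center(FunctionalSample(values=traj[:, j, :], times=times))
            results.append(univariate_fpca(sample, M=m_eff))
    return first_mode_scores(assemble_scores(results))
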