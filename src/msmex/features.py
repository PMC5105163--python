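"""Pairwise-CA-distance featurization and time-lagged independent
component analysis (TICA).

TICA solves the generalized symmetric eigenproblem

    C_tau_sym v = lambda (C_0 + eps I) v

with mean-free covariances accumulated over trajectories (lagged pairs are
formed within a trajectory only, sliding window) and the time-lagged
covariance symmetrized, C_tau_sym = (C_tau + C_tau^T)/2.  Eigenvalues are
lagged autocorrelations of the corresponding components; the slowest
components approximate the system's slow reaction coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import ResidueSelection, TrajectoryEnsemble


@dataclass
class FeatureMatrix:
    """Per-trajectory feature time series under one condition."""

    data: list[np.ndarray]         # each (frames, d)
    descriptors: list[str]
    condition_id: str = "default"

    def __post_init__(self) -> None:
        d = len(self.descriptors)
        for i, x in enumerate(self.data):
            x = np.asarray(x)
            if x.ndim != 2 or x.shape[1] != d:
                raise ValueError(f"trajectory {i}: expected (frames, {d})")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"trajectory {i}: non-finite feature values")
            self.data[i] = x

    @property
    def dim(self) -> int:
        return len(self.descriptors)


def pairwise_ca_distances(
    ens: TrajectoryEnsemble,
    sel: ResidueSelection,
    dtype=np.float64,
    chunk: int = 4000,
) -> FeatureMatrix:
    """All pairwise CA-CA distances over a residue selection, in Angstrom.

    Columns are ordered lexicographically in the pair index (i < j), i.e.
    the condensed-distance-matrix convention.  Every selected residue must
    have exactly one CA atom.
    """
    top = ens.topology
    ca_idx = []
    for chain_id, res_id in sel.residues:
        ai = top.atom_indices(chain_id=chain_id, res_id=res_id, name="CA")
        if len(ai) != 1:
            raise ValueError(
                f"residue {chain_id}{res_id} has {len(ai)} CA atoms (need 1)")
        ca_idx.append(int(ai[0]))
    ca_idx = np.asarray(ca_idx)
    iu, ju = np.triu_indices(len(ca_idx), k=1)
    descriptors = [
        f"{sel.residues[i][0]}{sel.residues[i][1]}CA-"
        f"{sel.residues[j][0]}{sel.residues[j][1]}CA"
        for i, j in zip(iu, ju)
    ]
    data = []
    for xyz in ens.trajectories:
        ca = xyz[:, ca_idx, :]
        out = np.empty((ca.shape[0], len(iu)), dtype=dtype)
        for lo in range(0, ca.shape[0], chunk):
            block = ca[lo:lo + chunk]
            diff = block[:, iu, :] - block[:, ju, :]
            out[lo:lo + chunk] = np.sqrt((diff * diff).sum(axis=-1))
        data.append(out)
    return FeatureMatrix(data=data, descriptors=descriptors,
                         condition_id=ens.condition_id)


@dataclass
class TICAModel:
    lag_frames: int
    mean: np.ndarray
    c0: np.ndarray                 # instantaneous covariance
    ctau: np.ndarray               # symmetrized time-lagged covariance
    eigenvalues: np.ndarray        # sorted by |lambda| descending
    eigenvectors: np.ndarray       # columns, (C0+epsI)-orthonormal
    n_components: int
    reg: float

    def timescales_frames(self) -> np.ndarray:
        """-tau / ln |lambda_i| per retained component."""
        lam = np.abs(self.eigenvalues)
        with np.errstate(divide="ignore"):
            return np.where(lam < 1.0, -self.lag_frames / np.log(lam), np.inf)


class _CovAccumulator:
    """Streaming accumulation of C0 / C_tau over trajectories."""

    def __init__(self, d: int, lag: int):
        self.d, self.lag = d, lag
        self.s = np.zeros(d)
        self.c00 = np.zeros((d, d))
        self.c0t = np.zeros((d, d))
        self.n = 0

    def add(self, x: np.ndarray) -> None:
        if x.shape[0] <= self.lag:
            raise ValueError(
                f"trajectory length {x.shape[0]} must exceed lag {self.lag}")
        x0 = np.asarray(x[:-self.lag], dtype=np.float64)
        xt = np.asarray(x[self.lag:], dtype=np.float64)
        self.s += x0.sum(axis=0) + xt.sum(axis=0)
        self.c00 += x0.T @ x0 + xt.T @ xt
        self.c0t += x0.T @ xt
        self.n += x0.shape[0]

    def finalize(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mean = self.s / (2 * self.n)
        c0 = self.c00 / (2 * self.n) - np.outer(mean, mean)
        ct = (self.c0t + self.c0t.T) / (2 * self.n) - np.outer(mean, mean)
        return mean, c0, ct


def fit_tica(
    features: FeatureMatrix | list[FeatureMatrix],
    lag_frames: int,
    n_components: int = 3,
    reg: float | None = None,
) -> TICAModel:
    """Fit TICA on one or more feature matrices (conditions pooled).

    ``reg`` is the ridge added to C0; the default 1e-6 * trace(C0)/d keeps
    rank-deficient distance sets solvable.  Components are returned sorted
    by |eigenvalue|, signs fixed so each component's largest-magnitude
    loading is positive.
    """
    fms = [features] if isinstance(features, FeatureMatrix) else list(features)
    d = fms[0].dim
    acc = _CovAccumulator(d, lag_frames)
    for fm in fms:
        if fm.dim != d:
            raise ValueError("feature dimension differs between inputs")
        for x in fm.data:
            acc.add(x)
    mean, c0, ct = acc.finalize()
    if reg is None:
        reg = 1e-6 * np.trace(c0) / d
    if reg == 0 and np.any(np.diag(c0) <= 1e-15):
        raise np.linalg.LinAlgError(
            "singular instantaneous covariance (constant feature); "
            "set reg > 0")
    if n_components > d:
        raise ValueError("n_components exceeds feature dimension")
    b = c0 + reg * np.eye(d)
    try:
        w, v = scipy.linalg.eigh(ct, b)
    except scipy.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"generalized eigenproblem failed ({e}); increase reg") from e
    order = np.argsort(-np.abs(w))[:n_components]
    w = w[order]
    v = v[:, order]
    for j in range(v.shape[1]):  # deterministic sign convention
        if v[np.argmax(np.abs(v[:, j])), j] < 0:
            v[:, j] = -v[:, j]
    return TICAModel(lag_frames=lag_frames, mean=mean, c0=c0, ctau=ct,
                     eigenvalues=w, eigenvectors=v, n_components=n_components,
                     reg=reg)


def transform_tica(
    model: TICAModel, features: FeatureMatrix | np.ndarray
) -> list[np.ndarray] | np.ndarray:
    """Project mean-free features onto the TICA eigenvectors."""
    if isinstance(features, FeatureMatrix):
        if features.dim != model.mean.shape[0]:
            raise ValueError("feature dimension does not match model")
        return [
            (np.asarray(x, dtype=np.float64) - model.mean) @ model.eigenvectors
            for x in features.data
        ]
    x = np.asarray(features, dtype=np.float64)
    if x.shape[-1] != model.mean.shape[0]:
        raise ValueError("feature dimension does not match model")
    return (x - model.mean) @ model.eigenvectors
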