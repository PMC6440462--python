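"""Abundance-based beta-diversity dissimilarities and distance matrices.

Five quantitative dissimilarities operating on abundance vectors:
Jensen-Shannon distance (base-2, so values lie in [0, 1]), its square root,
Bray-Curtis, Morisita-Horn and Kulczynski.  All are implemented directly from
their algebraic definitions; no pseudocounts are added and ``0 * log(0)``
terms contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "METRICS",
    "DistanceMatrix",
    "jsd",
    "rjsd",
    "bray_curtis",
    "morisita_horn",
    "kulczynski",
    "distance_matrix",
    "pairwise",
]

_COMP_TOL = 1e-6


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities under one named metric."""

    metric_id: str
    sample_ids: list[str]
    values: np.ndarray
    #: skip the [0, 1] range check for matrices from arbitrary geometry
    bounded: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0):
            raise ValueError("matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("non-zero diagonal")
        if np.any(v < -1e-12) or (self.bounded and np.any(v > 1 + 1e-12)):
            raise ValueError("distances outside the expected [0, 1] range")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, indices) -> np.ndarray:
        """Induced sub-matrix for integer sample positions (dups allowed)."""
        idx = np.asarray(indices, dtype=int)
        return self.values[np.ix_(idx, idx)]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(["", *self.sample_ids]) + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                fh.write("\t".join([sid, *(repr(float(x)) for x in row)]) + "\n")


def _check_pair(x, y, require_composition: bool):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundance vectors must be non-negative")
    if require_composition:
        for name, v in (("p", x), ("q", y)):
            if abs(v.sum() - 1.0) > _COMP_TOL:
                raise ValueError(
                    f"{name} is not a composition (sum {v.sum():.6g} != 1)"
                )
    return x, y


def _xlogx(v: np.ndarray) -> np.ndarray:
    out = np.zeros_like(v)
    pos = v > 0
    out[pos] = v[pos] * np.log2(v[pos])
    return out


def jsd(p, q) -> float:
    """Jensen-Shannon distance between two compositions, log base 2.

    Equals ``H(m) - (H(p) + H(q)) / 2`` with ``m = (p + q)/2`` and base-2
    entropies, i.e. the symmetrised, bounded KL divergence in [0, 1].
    """
    p, q = _check_pair(p, q, require_composition=True)
    m = 0.5 * (p + q)
    val = float(_xlogx(p).sum() / 2 + _xlogx(q).sum() / 2 - _xlogx(m).sum())
    return min(max(val, 0.0), 1.0)


def rjsd(p, q) -> float:
    """Square root of :func:`jsd`."""
    return float(np.sqrt(jsd(p, q)))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)``."""
    x, y = _check_pair(x, y, require_composition=False)
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def morisita_horn(x, y) -> float:
    """Morisita-Horn dissimilarity (abundance-weighted overlap complement)."""
    x, y = _check_pair(x, y, require_composition=False)
    sx, sy = float(x.sum()), float(y.sum())
    if sx == 0 or sy == 0:
        raise ValueError("Morisita-Horn undefined for an all-zero vector")
    dx = float((x * x).sum()) / sx**2
    dy = float((y * y).sum()) / sy**2
    sim = 2.0 * float((x * y).sum()) / ((dx + dy) * sx * sy)
    return min(max(1.0 - sim, 0.0), 1.0)


def kulczynski(x, y) -> float:
    """Quantitative Kulczynski dissimilarity."""
    x, y = _check_pair(x, y, require_composition=False)
    sx, sy = float(x.sum()), float(y.sum())
    if sx == 0 or sy == 0:
        raise ValueError("Kulczynski undefined for an all-zero vector")
    w = float(np.minimum(x, y).sum())
    return min(max(1.0 - 0.5 * (w / sx + w / sy), 0.0), 1.0)


METRICS = {
    "jsd": jsd,
    "rjsd": rjsd,
    "braycurtis": bray_curtis,
    "morisitahorn": morisita_horn,
    "kulczynski": kulczynski,
}


def _pairwise_jsd(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    hx = _xlogx(X).sum(axis=1)  # -H(p) in bits
    out = np.zeros((n, n))
    for i in range(n - 1):
        m = 0.5 * (X[i + 1:] + X[i])
        hm = _xlogx(m).sum(axis=1)
        out[i, i + 1:] = 0.5 * (hx[i + 1:] + hx[i]) - hm
    out = out + out.T
    return np.clip(out, 0.0, 1.0)


def _pairwise_braycurtis(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    s = X.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n - 1):
        out[i, i + 1:] = np.abs(X[i + 1:] - X[i]).sum(axis=1) / (s[i + 1:] + s[i])
    return out + out.T


def _pairwise_morisitahorn(X: np.ndarray) -> np.ndarray:
    s = X.sum(axis=1)
    d = (X * X).sum(axis=1) / s**2
    cross = X @ X.T
    sim = 2.0 * cross / ((d[:, None] + d[None, :]) * np.outer(s, s))
    out = np.clip(1.0 - sim, 0.0, 1.0)
    np.fill_diagonal(out, 0.0)
    return out


def _pairwise_kulczynski(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    s = X.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n - 1):
        w = np.minimum(X[i + 1:], X[i]).sum(axis=1)
        out[i, i + 1:] = 1.0 - 0.5 * (w / s[i + 1:] + w / s[i])
    return np.clip(out + out.T, 0.0, 1.0)


def pairwise(X: np.ndarray, metric_id: str) -> np.ndarray:
    """All-pairs dissimilarity matrix for rows of a composition matrix."""
    X = np.asarray(X, dtype=float)
    if metric_id == "jsd":
        return _pairwise_jsd(X)
    if metric_id == "rjsd":
        return np.sqrt(_pairwise_jsd(X))
    if metric_id == "braycurtis":
        return _pairwise_braycurtis(X)
    if metric_id == "morisitahorn":
        return _pairwise_morisitahorn(X)
    if metric_id == "kulczynski":
        return _pairwise_kulczynski(X)
    raise KeyError(f"unknown metric {metric_id!r}; choose from {sorted(METRICS)}")


def distance_matrix(table, metric_id: str) -> DistanceMatrix:
    """Pairwise :class:`DistanceMatrix` for a normalized abundance table."""
    if metric_id not in METRICS:
        raise KeyError(f"unknown metric {metric_id!r}; choose from {sorted(METRICS)}")
    if not table.normalized:
        raise ValueError("distance_matrix requires a normalized table")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    values = pairwise(table.values, metric_id)
    # enforce exact symmetry against float round-off
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(metric_id=metric_id, sample_ids=list(table.sample_ids),
                          values=values)
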