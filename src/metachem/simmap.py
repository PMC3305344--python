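"""Fingerprints, Tanimoto similarity, threshold clustering, and the 2D
structural cluster map.

The map is a Sammon-style non-linear mapping (NLM): compound i and j are a
distance delta_ij = 1 - TC_ij apart in fingerprint space, and 2D positions
are found by minimizing the distance-weighted fractional error

    E = (sum delta_ij)^-1 * sum (delta_ij - d_ij)^2 / delta_ij

by a diagonal second-order gradient iteration from a PCA initialization.
Pairs with delta = 0 (identical fingerprints) are excluded from the sums
and placed coincident afterward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from metachem.io import Metabolite


@dataclass(frozen=True)
class Fingerprint:
    """Binary substructural fingerprint as a set of on-bit indices."""

    bits: frozenset
    n_bits: int

    @property
    def n_set(self) -> int:
        return len(self.bits)


def fingerprint(m: Metabolite | Chem.Mol, n_bits: int = 2048) -> Fingerprint:
    """Hashed path-based fingerprint (deterministic for a given molecule)."""
    mol = m.mol if isinstance(m, Metabolite) else m
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    bits = set(fp.GetOnBits())
    if not bits:
        # single-atom molecules have no bond paths; encode atomic composition
        bits = {(17 * a.GetAtomicNum()) % n_bits for a in mol.GetAtoms()}
    return Fingerprint(frozenset(bits), n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """TC = N_c / (N_a + N_b - N_c); two empty fingerprints give 0."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint universes differ: {a.n_bits} vs {b.n_bits}")
    nc = len(a.bits & b.bits)
    denom = a.n_set + b.n_set - nc
    return nc / denom if denom else 0.0


def distance_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """delta_ij = 1 - TC_ij for all pairs."""
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - tanimoto(fps[i], fps[j])
    return d


def cluster_threshold(fps: Sequence[Fingerprint], t: float = 0.85) -> list[int]:
    """Pool compounds into clusters: connected components of the graph with an
    edge wherever TC > t (strict).  Returns a cluster id per compound;
    ids are the smallest member index of each component, so the labeling is
    independent of input order up to relabeling."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    if not fps:
        raise ValueError("need at least one fingerprint")
    n = len(fps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto(fps[i], fps[j]) > t:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    return [find(i) for i in range(n)]


@dataclass
class EmbeddingPoint:
    id: str
    x: float
    y: float
    cluster_id: int
    cluster_size: int


@dataclass
class SammonResult:
    coords: np.ndarray        # (n, 2)
    stress: float
    stress_history: list[float]


def _pca_init(X: np.ndarray, seed: int) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    # SVD is deterministic up to sign; fix signs by the largest component
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = U[:, :2] * s[:2]
    if pcs.shape[1] < 2:
        pcs = np.hstack([pcs, np.zeros((pcs.shape[0], 2 - pcs.shape[1]))])
    for k in range(2):
        j = np.argmax(np.abs(Vt[k])) if k < Vt.shape[0] else 0
        if k < Vt.shape[0] and Vt[k, j] < 0:
            pcs[:, k] *= -1
    rng = np.random.default_rng(seed)
    pcs = pcs + rng.normal(scale=1e-6, size=pcs.shape)  # break exact ties
    return pcs


def sammon(
    delta: np.ndarray,
    init: np.ndarray,
    n_iter: int = 300,
    tol: float = 1e-9,
) -> SammonResult:
    """Minimize the Sammon stress of a 2D configuration.

    Uses Sammon's diagonal pseudo-Newton update with step halving whenever a
    step would increase the stress, so accepted stress values are
    non-increasing.  Zero entries of ``delta`` (off the diagonal) are
    excluded from all sums.
    """
    n = delta.shape[0]
    mask = (delta > 0) & ~np.eye(n, dtype=bool)
    c = delta[mask].sum() / 2.0
    if c == 0:  # all points identical: degenerate, coincident with stress 0
        return SammonResult(np.zeros((n, 2)), 0.0, [0.0])
    Y = init.astype(float).copy()

    def pair_dist(Y: np.ndarray) -> np.ndarray:
        diff = Y[:, None, :] - Y[None, :, :]
        return np.sqrt((diff**2).sum(-1))

    def stress_of(Y: np.ndarray) -> float:
        d = pair_dist(Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(mask, (delta - d) ** 2 / np.where(mask, delta, 1.0), 0.0)
        return e.sum() / (2.0 * c)

    history = [stress_of(Y)]
    eps = 1e-12
    for _ in range(n_iter):
        d = pair_dist(Y)
        d_safe = np.where(mask, np.maximum(d, eps), 1.0)
        delta_safe = np.where(mask, delta, 1.0)
        w = np.where(mask, 1.0 / (delta_safe * d_safe), 0.0)  # 1/(delta_ij d_ij)
        diff = Y[:, None, :] - Y[None, :, :]
        resid = delta - d
        # Sammon's first derivative and diagonal second derivative
        g1 = (-2.0 / c) * ((w * resid)[:, :, None] * diff).sum(axis=1)
        h = (-2.0 / c) * (
            w[:, :, None]
            * (resid[:, :, None]
               - (diff**2) / d_safe[:, :, None] * (1.0 + resid[:, :, None] / d_safe[:, :, None]))
        ).sum(axis=1)
        step = g1 / np.maximum(np.abs(h), eps)
        alpha = 0.3  # Sammon's "magic factor"
        for _halve in range(30):
            Y_new = Y - alpha * step
            s_new = stress_of(Y_new)
            if s_new <= history[-1] + 1e-15:
                break
            alpha *= 0.5
        else:
            break
        Y = Y_new
        history.append(s_new)
        if len(history) > 1 and history[-2] - history[-1] < tol:
            break
    return SammonResult(Y, history[-1], history)


def nlm_embed(
    fps: Sequence[Fingerprint],
    seed: int = 0,
    ids: Optional[Sequence[str]] = None,
    t: float = 0.85,
    n_iter: int = 300,
) -> tuple[list[EmbeddingPoint], SammonResult]:
    """Embed compounds in 2D by NLM and pool them into TC-threshold clusters.

    Duplicate fingerprints (delta = 0) are optimized once and placed
    coincident.  Returns the per-compound points (with cluster id and
    cluster size) and the Sammon result for the unique configuration.
    """
    if len(fps) < 3:
        raise ValueError("need at least 3 compounds to embed")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(fps))]

    # collapse exact-duplicate fingerprints
    rep: dict[frozenset, int] = {}
    group = []
    for fp in fps:
        key = fp.bits
        if key not in rep:
            rep[key] = len(rep)
        group.append(rep[key])
    uniq_idx = {}
    for i, g in enumerate(group):
        uniq_idx.setdefault(g, i)
    uniq = [fps[uniq_idx[g]] for g in range(len(rep))]

    X = np.zeros((len(uniq), uniq[0].n_bits))
    for i, fp in enumerate(uniq):
        X[i, list(fp.bits)] = 1.0
    if len(uniq) == 1:
        res = SammonResult(np.zeros((1, 2)), 0.0, [0.0])
    else:
        delta = distance_matrix(uniq)
        init = _pca_init(X, seed)
        res = sammon(delta, init, n_iter=n_iter)

    labels = cluster_threshold(fps, t)
    sizes = {c: labels.count(c) for c in set(labels)}
    points = [
        EmbeddingPoint(ids[i], float(res.coords[group[i], 0]), float(res.coords[group[i], 1]),
                       labels[i], sizes[labels[i]])
        for i in range(len(fps))
    ]
    return points, res


def embedding_table(points: Sequence[EmbeddingPoint],
                    set_labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "id": [p.id for p in points],
            "x": [p.x for p in points],
            "y": [p.y for p in points],
            "cluster_id": [p.cluster_id for p in points],
            "cluster_size": [p.cluster_size for p in points],
        }
    )
    if set_labels is not None:
        df.insert(1, "set_label", list(set_labels))
    return df
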