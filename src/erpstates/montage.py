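"""Electrode montages and spatial adjacency.

A :class:`Montage` holds electrode labels, 3-D head-centric positions and,
once built, a symmetric neighbor relation.  Adjacency is required by the
spatio-temporal clustering criterion used in the mass-univariate waveform
statistics ("at least N adjacent electrodes"), where "adjacent" must be an
explicit graph over the cap.

Two neighborhood rules are provided:

``delaunay`` (default)
    Delaunay triangulation of the electrodes on an azimuthal-equidistant
    projection of the (fitted) scalp sphere.  This is the standard choice
    for cluster-based ERP statistics and is invariant to global rotation
    and scaling of the electrode cloud, because the projection axis is
    derived from the electrode cloud itself.

``distance``
    Fixed-radius graph: electrodes closer than a caller-supplied threshold
    are neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay


class MontageError(ValueError):
    """Raised for malformed montages (duplicate labels, coincident sites...)."""


@dataclass
class Montage:
    """Electrode identities, positions and neighbor relation.

    Parameters
    ----------
    labels
        Unique electrode names.
    positions
        ``(n, 3)`` array of head-centric coordinates (arbitrary units; only
        relative geometry matters).
    adjacency
        Boolean ``(n, n)`` symmetric, irreflexive matrix; ``None`` until
        :func:`build_adjacency` has been applied.
    """

    labels: list[str]
    positions: np.ndarray
    adjacency: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise MontageError("positions must be an (n, 3) array")
        if len(self.labels) != self.positions.shape[0]:
            raise MontageError(
                f"{len(self.labels)} labels for {self.positions.shape[0]} positions"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise MontageError(f"duplicate electrode labels: {dupes}")
        if not np.all(np.isfinite(self.positions)):
            raise MontageError("electrode positions must be finite")
        if self.adjacency is not None:
            self._check_adjacency(np.asarray(self.adjacency, dtype=bool))

    def _check_adjacency(self, adj: np.ndarray) -> None:
        n = len(self.labels)
        if adj.shape != (n, n):
            raise MontageError("adjacency shape does not match electrode count")
        if adj.diagonal().any():
            raise MontageError("adjacency must be irreflexive")
        if not np.array_equal(adj, adj.T):
            raise MontageError("adjacency must be symmetric")
        if n >= 2 and not adj.any(axis=1).all():
            isolated = [self.labels[i] for i in np.flatnonzero(~adj.any(axis=1))]
            raise MontageError(f"isolated electrodes: {isolated}")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def neighbors(self, label: str) -> list[str]:
        i = self.labels.index(label)
        if self.adjacency is None:
            raise MontageError("adjacency not built; call build_adjacency first")
        return [self.labels[j] for j in np.flatnonzero(self.adjacency[i])]


def read_montage(path) -> Montage:
    """Read a plain-text coordinate file with ``label x y z`` per line.

    Comma- or whitespace-delimited; blank lines and ``#`` comments ignored.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 4:
                raise MontageError(f"{path}:{lineno}: expected 'label x y z'")
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise MontageError(f"{path}:{lineno}: bad coordinate") from exc
    return Montage(labels=labels, positions=np.array(rows, dtype=float))


def write_montage(path, montage: Montage) -> None:
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def _fit_sphere(pos: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit (linear in center and radius^2 - |c|^2)."""
    A = np.column_stack([2 * pos, np.ones(len(pos))])
    b = (pos**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    radius = float(np.sqrt(max(r2, np.finfo(float).tiny)))
    return center, radius


def _azimuthal_projection(pos: np.ndarray) -> np.ndarray:
    """Project electrodes onto a plane through an azimuthal-equidistant map.

    The pole is the mean direction of the electrodes from the fitted sphere
    center, so the projection rotates and scales with the cloud and the
    resulting triangulation is invariant to global rotation/scaling.
    """
    center, radius = _fit_sphere(pos)
    u = pos - center
    norms = np.linalg.norm(u, axis=1)
    if np.any(norms < 1e-12 * max(radius, 1.0)):
        raise MontageError("electrode at fitted sphere center; cannot project")
    u = u / norms[:, None]
    pole = u.mean(axis=0)
    pn = np.linalg.norm(pole)
    if pn < 1e-9:
        # symmetric full-sphere cloud: fall back to +z of the cloud's PCA frame
        _, _, vt = np.linalg.svd(u, full_matrices=False)
        pole = vt[-1]
    else:
        pole = pole / pn
    # orthonormal in-plane basis (any choice; Delaunay ignores in-plane rotation)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ pole) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ pole) * pole
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(pole, e1)
    cos_t = np.clip(u @ pole, -1.0, 1.0)
    theta = np.arccos(cos_t)
    x, y = u @ e1, u @ e2
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def _coincident_pairs(pos: np.ndarray, labels: list[str]) -> list[tuple[str, str]]:
    scale = max(float(np.ptp(pos)), 1.0)
    out = []
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if np.linalg.norm(pos[i] - pos[j]) < 1e-9 * scale:
                out.append((labels[i], labels[j]))
    return out


def build_adjacency(
    montage: Montage,
    rule: str = "delaunay",
    threshold: float | None = None,
) -> Montage:
    """Return a copy of *montage* with its neighbor relation filled in.

    Parameters
    ----------
    rule
        ``"delaunay"`` (default) or ``"distance"``.
    threshold
        Euclidean distance bound, required for the ``distance`` rule.
    """
    n = montage.n_electrodes
    if n < 2:
        raise MontageError("adjacency needs at least 2 electrodes")
    pairs = _coincident_pairs(montage.positions, montage.labels)
    if pairs:
        raise MontageError(f"coincident electrode positions: {pairs}")

    adj = np.zeros((n, n), dtype=bool)
    if rule == "distance":
        if threshold is None or threshold <= 0:
            raise MontageError("distance rule requires a positive threshold")
        d = np.linalg.norm(
            montage.positions[:, None, :] - montage.positions[None, :, :], axis=-1
        )
        adj = d <= threshold
        np.fill_diagonal(adj, False)
    elif rule == "delaunay":
        if n == 2:
            adj[0, 1] = adj[1, 0] = True
        elif n == 3:
            adj[:] = True
            np.fill_diagonal(adj, False)
        else:
            pts = _azimuthal_projection(montage.positions)
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        adj[simplex[a], simplex[b]] = True
                        adj[simplex[b], simplex[a]] = True
    else:
        raise MontageError(f"unknown adjacency rule {rule!r}")

    out = replace(montage, adjacency=adj)
    return out
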