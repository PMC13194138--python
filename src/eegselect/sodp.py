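"""Second-order difference plot (SODP) construction and geometric descriptors.

The SODP of a series ``s`` scatters consecutive first differences,

    x(n) = s(n+1) - s(n)        against        y(n) = s(n+2) - s(n+1),

so a length-``N`` signal yields ``N - 2`` plane points.  Regular, slowly
varying signals produce compact clouds hugging the origin; complex signals
spread out.  The descriptors below summarize the cloud's dispersion
(STD1/STD2/STD, CTM), its path geometry (SAV, STA, SCC, SSVL) and its
distance structure (SDC, SSHD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SODPPoints:
    """The (x, y) difference-plane point cloud of one signal."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("SODP points must be finite")

    def __len__(self) -> int:
        return self.x.size


def sodp_points(signal: np.ndarray) -> SODPPoints:
    """Build the SODP point cloud of a 1-D signal (length >= 3)."""
    s = np.asarray(signal, dtype=float).ravel()
    if s.size < 3:
        raise ValueError(f"signal of length {s.size} has no SODP (need >= 3)")
    d = np.diff(s)
    return SODPPoints(x=d[:-1], y=d[1:])


def _require(p: SODPPoints, n: int, what: str) -> None:
    if len(p) < n:
        raise ValueError(f"{what} needs at least {n} SODP points, got {len(p)}")


def std_descriptors(p: SODPPoints) -> tuple[float, float, float]:
    """Dispersion along the anti-identity and identity axes of the plot.

    STD1 is the population standard deviation of the projection onto the
    line perpendicular to y = x, STD2 that of the projection onto y = x,
    and STD = pi * STD1 * STD2 is the area of the ellipse they define.
    """
    _require(p, 2, "std_descriptors")
    std1 = float(np.sqrt(np.var((p.x - p.y) / np.sqrt(2.0))))
    std2 = float(np.sqrt(np.var((p.x + p.y) / np.sqrt(2.0))))
    return std1, std2, float(np.pi * std1 * std2)


def sav(p: SODPPoints, mode: str = "printed") -> float:
    """Summed angle terms between consecutive point-to-point vectors.

    ``printed`` mode accumulates (a.b) / (|a|^2 + |b|^2) over consecutive
    vector pairs — the normalization by the *sum of squared norms* rather
    than the product of norms; zero-length vectors contribute 0.  ``angle``
    mode accumulates the actual angles arccos(a.b / (|a| |b|)) with the
    cosine clipped to [-1, 1]; pairs containing a zero-length vector are
    skipped.
    """
    _require(p, 3, "sav")
    ax, ay = np.diff(p.x), np.diff(p.y)            # consecutive vectors
    dots = ax[:-1] * ax[1:] + ay[:-1] * ay[1:]
    sq = ax**2 + ay**2
    if mode == "printed":
        denom = sq[:-1] + sq[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
        return float(terms.sum())
    if mode == "angle":
        norms = np.sqrt(sq)
        prod = norms[:-1] * norms[1:]
        valid = prod > 0
        cosines = np.clip(dots[valid] / prod[valid], -1.0, 1.0)
        return float(np.arccos(cosines).sum())
    raise ValueError(f"unknown SAV mode {mode!r}")


def sdc(p: SODPPoints) -> float:
    """Sum of Euclidean distances of all points from the origin."""
    _require(p, 1, "sdc")
    return float(np.hypot(p.x, p.y).sum())


def sta(p: SODPPoints) -> float:
    """Sum of areas of the triangles formed by sliding point triplets."""
    _require(p, 3, "sta")
    x0, x1, x2 = p.x[:-2], p.x[1:-1], p.x[2:]
    y0, y1, y2 = p.y[:-2], p.y[1:-1], p.y[2:]
    cross = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
    return float(0.5 * np.abs(cross).sum())


def sshd(p: SODPPoints) -> float:
    """Sum of shortest (perpendicular) distances to the 45-degree line."""
    _require(p, 1, "sshd")
    return float((np.abs(p.x - p.y) / np.sqrt(2.0)).sum())


def scc(p: SODPPoints) -> float:
    """Sum of distances between centroids of consecutive sliding triangles."""
    _require(p, 4, "scc")
    cx = (p.x[:-2] + p.x[1:-1] + p.x[2:]) / 3.0
    cy = (p.y[:-2] + p.y[1:-1] + p.y[2:]) / 3.0
    return float(np.hypot(np.diff(cx), np.diff(cy)).sum())


def ssvl(p: SODPPoints) -> float:
    """Total path length through the point cloud in plotting order."""
    _require(p, 2, "ssvl")
    return float(np.hypot(np.diff(p.x), np.diff(p.y)).sum())


def ctm(p: SODPPoints, r: float) -> float:
    """Central tendency measure: fraction of points inside the radius-r disk.

    The denominator is the SODP point count, so ctm is in [0, 1] and is
    non-decreasing in ``r``.
    """
    if r <= 0:
        raise ValueError("CTM radius must be positive")
    _require(p, 1, "ctm")
    return float(np.mean(np.hypot(p.x, p.y) <= r))
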