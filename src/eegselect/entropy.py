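"""Sample entropy and fuzzy entropy of 1-D series.

Both are template-matching regularity statistics on delay-embedded vectors
compared under the Chebyshev (maximum-coordinate) distance, with
self-matches excluded.  Sample entropy counts hard matches within a
tolerance ``r``; fuzzy entropy replaces the hard threshold with the
exponential membership ``mu(d) = exp(-(d/r)^n)``, making the statistic
continuous in the data.  Lower values mean more regular, more predictable
signals — the direction in which neurodegeneration shifts resting EEG.

Template counting follows the convention in which both embedding
dimensions ``m`` and ``m + 1`` use the same number of templates
(``N - m`` for sample entropy, ``N - m*tau`` for fuzzy entropy), so the
two match fractions are comparable and their ratio is a probability.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_entropy", "fuzzy_entropy"]


def _resolve_r(signal: np.ndarray, r: float, scale_r: bool) -> float:
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if not scale_r:
        return float(r)
    sd = float(np.std(signal))
    if sd == 0:
        raise ValueError("relative tolerance requested but the series is constant")
    return float(r * sd)


def _chebyshev_pairs(s: np.ndarray, m: int, n_templates: int, tau: int = 1) -> np.ndarray:
    """Pairwise Chebyshev distances between the first ``n_templates``
    delay-embedded m-vectors, as an (n, n) matrix."""
    d = np.zeros((n_templates, n_templates))
    for k in range(m):
        col = s[k * tau: k * tau + n_templates]
        np.maximum(d, np.abs(col[:, None] - col[None, :]), out=d)
    return d


def sample_entropy(signal: np.ndarray, m: int = 2, r: float = 0.15,
                   scale_r: bool = True) -> float:
    """Sample entropy SampEn(m, r) of a series.

    Parameters
    ----------
    signal : array-like
        1-D series of length >= m + 2.
    m : int
        Embedding dimension (default 2).
    r : float
        Tolerance.  With ``scale_r=True`` (default) it is a coefficient of
        the series' population standard deviation, giving the standard
        r = 0.15 * SD configuration; with ``scale_r=False`` it is absolute.

    Returns
    -------
    float
        -ln(A / B) where A and B are the (m+1)- and m-dimensional match
        fractions with self-matches excluded.  Returns ``inf`` when no
        (m+1)-dimensional template pair matches (a flagged sentinel, so
        batch extraction survives pathological epochs) and 0.0 when both
        fractions saturate (e.g. a constant series under absolute r).
    """
    s = np.asarray(signal, dtype=float).ravel()
    if s.size < m + 2:
        raise ValueError(f"series of length {s.size} too short for m={m}")
    r_abs = _resolve_r(s, r, scale_r)
    n = s.size - m  # template count shared by both dimensions
    mask = ~np.eye(n, dtype=bool)
    b = int(np.count_nonzero(_chebyshev_pairs(s, m, n)[mask] <= r_abs))
    a = int(np.count_nonzero(_chebyshev_pairs(s, m + 1, n)[mask] <= r_abs))
    if b == 0 or a == 0:
        return float("inf")
    return float(-np.log(a / b))


def fuzzy_entropy(signal: np.ndarray, m: int = 2, tau: int = 1, n: float = 2.0,
                  r: float = 0.15, scale_r: bool = True) -> float:
    """Fuzzy entropy FuzzyEn(m, tau, n, r) of a series.

    ``n`` is the fuzzy exponent of the membership function
    ``mu(d) = exp(-(d/r)^n)`` applied to Chebyshev distances between
    delay-embedded vectors (delay ``tau``); no vector-baseline removal is
    performed.  Returns ``ln(phi_m) - ln(phi_{m+1})`` with both match
    probabilities averaged over the same ``N - m*tau`` templates.
    """
    s = np.asarray(signal, dtype=float).ravel()
    if tau < 1 or n <= 0:
        raise ValueError("tau must be >= 1 and n > 0")
    if s.size < (m + 1) * tau + 1:
        raise ValueError(f"series of length {s.size} too short for m={m}, tau={tau}")
    r_abs = _resolve_r(s, r, scale_r)
    nt = s.size - m * tau
    mask = ~np.eye(nt, dtype=bool)

    def phi(dim: int) -> float:
        d = _chebyshev_pairs(s, dim, nt, tau)[mask]
        return float(np.mean(np.exp(-np.power(d / r_abs, n))))

    return float(np.log(phi(m)) - np.log(phi(m + 1)))
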