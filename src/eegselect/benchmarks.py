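"""Benchmark objective registry for optimizer validation.

Twelve classic test functions spanning unimodal (f1 Sphere, f2 Step,
f4 Rosenbrock, f10 Quadric/rotated hyper-ellipsoid), multimodal
(f5 Rastrigin, f6 Ackley, f7 Griewank, f8 generalized Schaffer) and
hybrid/composite (f12 constrained sphere, f13 Kursawe-sum, f15 hybrid,
f18 composite) classes.  Functions without a universally printed recipe
(f12, f15, f18) are implemented as the documented, reproducible recipes
below built from the named primitives; f13's natively bi-objective
Kursawe problem is summed into a single objective.  The registry makes no
claim of bit-exact equivalence with any official competition suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["BenchmarkFunction", "benchmark_suite", "evaluate_function",
           "BENCHMARK_IDS"]

BENCHMARK_IDS = ("f1", "f2", "f4", "f5", "f6", "f7", "f8", "f10",
                 "f12", "f13", "f15", "f18")


@dataclass(frozen=True)
class BenchmarkFunction:
    """One benchmark objective with its box and known optimum (if any)."""

    id: str
    name: str
    dim: int
    lower: float
    upper: float
    fn: Callable[[np.ndarray], float]
    optimum_position: np.ndarray | None
    optimum_value: float | None

    def evaluate(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.size != self.dim:
            raise ValueError(f"{self.id} expects dim {self.dim}, got {x.size}")
        return float(self.fn(x))

    __call__ = evaluate


def _sphere(x):
    return np.sum(x ** 2)


def _step(x):
    return np.sum(np.floor(x + 0.5) ** 2)


def _rosenbrock(x):
    return np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2)


def _quadric(x):
    return np.sum(np.cumsum(x) ** 2)


def _rastrigin(x):
    return np.sum(x ** 2 - 10.0 * np.cos(2.0 * np.pi * x) + 10.0)


def _ackley(x):
    n = x.size
    return (-20.0 * np.exp(-0.2 * np.sqrt(np.sum(x ** 2) / n))
            - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n) + 20.0 + np.e)


def _griewank(x):
    i = np.arange(1, x.size + 1)
    return np.sum(x ** 2) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0


def _schaffer_pair(x, y):
    num = np.sin(x ** 2 - y ** 2) ** 2 - 0.5
    den = (1.0 + 0.001 * (x ** 2 + y ** 2)) ** 2
    return 0.5 + num / den


def _schaffer(x):
    return np.sum(_schaffer_pair(x[:-1], x[1:]))


def _constrained_sphere(x, half_range=50.0, penalty=1000.0):
    excess = np.maximum(np.abs(x) - half_range, 0.0)
    return _sphere(x) + penalty * np.sum(excess ** 2)


def _kursawe_sum(x):
    f1 = np.sum(-10.0 * np.exp(-0.2 * np.sqrt(x[:-1] ** 2 + x[1:] ** 2)))
    f2 = np.sum(np.abs(x) ** 0.8 + 5.0 * np.sin(x) ** 3)
    return f1 + f2


def _hybrid_parts(dim: int) -> tuple[slice, slice, slice]:
    a = dim // 3
    b = 2 * dim // 3
    return slice(0, a), slice(a, b), slice(b, dim)


def _hybrid1(x):
    """Sphere / Rastrigin / Griewank on a fixed dimension split, each part
    rescaled from the shared [-100, 100] box to the primitive's native box."""
    s1, s2, s3 = _hybrid_parts(x.size)
    return (_sphere(x[s1])
            + _rastrigin(x[s2] * (5.12 / 100.0))
            + _griewank(x[s3] * (600.0 / 100.0)))


def _composite_shifts(dim: int) -> list[np.ndarray]:
    return [np.zeros(dim), np.full(dim, 30.0), np.full(dim, -40.0)]


def _composite2(x):
    """Min over shifted primitives: sphere at 0, scaled Rastrigin at +30,
    scaled Ackley at -40, each with a height bias so the sheet at the
    origin is the global optimum (value 0)."""
    o1, o2, o3 = _composite_shifts(x.size)
    g1 = _sphere((x - o1) / 10.0)
    g2 = _rastrigin((x - o2) * (5.12 / 100.0)) + 10.0
    g3 = _ackley((x - o3) * (32.0 / 100.0)) + 20.0
    return min(g1, g2, g3)


_SPECS = {
    "f1": ("Sphere", -100.0, 100.0, _sphere, 0.0, 0.0),
    "f2": ("Step", -100.0, 100.0, _step, 0.0, 0.0),
    "f4": ("Rosenbrock", -30.0, 30.0, _rosenbrock, 1.0, 0.0),
    "f5": ("Rastrigin", -5.12, 5.12, _rastrigin, 0.0, 0.0),
    "f6": ("Ackley", -32.0, 32.0, _ackley, 0.0, 0.0),
    "f7": ("Griewank", -600.0, 600.0, _griewank, 0.0, 0.0),
    "f8": ("Schaffer", -100.0, 100.0, _schaffer, 0.0, 0.0),
    "f10": ("Quadric", -100.0, 100.0, _quadric, 0.0, 0.0),
    "f12": ("ConstrainedSphere", -100.0, 100.0, _constrained_sphere, 0.0, 0.0),
    "f13": ("KursaweSum", -5.0, 5.0, _kursawe_sum, None, None),
    "f15": ("Hybrid1", -100.0, 100.0, _hybrid1, 0.0, 0.0),
    "f18": ("Composite2", -100.0, 100.0, _composite2, 0.0, 0.0),
}


def benchmark_suite(dim: int = 10) -> dict[str, BenchmarkFunction]:
    """Instantiate all 12 benchmark functions at the given dimension."""
    if dim < 2:
        raise ValueError("dim must be at least 2")
    suite = {}
    for fid in BENCHMARK_IDS:
        name, lo, hi, fn, opt_pos, opt_val = _SPECS[fid]
        pos = None if opt_pos is None else np.full(dim, float(opt_pos))
        suite[fid] = BenchmarkFunction(id=fid, name=name, dim=dim, lower=lo,
                                       upper=hi, fn=fn, optimum_position=pos,
                                       optimum_value=opt_val)
    return suite


def evaluate_function(fid: str, x: np.ndarray) -> float:
    """Evaluate benchmark ``fid`` at ``x`` (dimension inferred from x)."""
    x = np.asarray(x, dtype=float)
    if fid not in _SPECS:
        raise KeyError(f"unknown benchmark id {fid!r}")
    return benchmark_suite(dim=x.size)[fid].evaluate(x)
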