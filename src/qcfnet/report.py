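"""Recomputation of the headline quantities (grid extrema of the detection
statistics, symbolic vanishing, and exact Jacobian ranks).

Used by the acceptance script and mirrored by the acceptance tests.  Every
quantity is computed from scratch by running the exact engine; grid extrema
are evaluated with a vectorized form of the engine's symbolic CF
polynomials and the optimum is re-verified in exact rational arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Dict, Tuple

import numpy as np

GRID = [Fraction(i, 10) for i in range(1, 10)]


def _symbolic_statistic(family: str, builder):
    """(parameter symbols, statistic expression) with CFs from the engine."""
    import sympy

    from .cfengine import cf_table
    from .fixtures import NETWORK_CATALOG, NamedNetworkSpec, make_named

    keys, _ = NETWORK_CATALOG[family]
    syms = sympy.symbols([f"v_{k}" for k in keys], positive=True)
    net = make_named(NamedNetworkSpec(family, dict(zip(keys, syms))))
    table = cf_table(net, expand=True)
    return list(syms), builder(table)


def _grid_extremum(syms, expr, minimum: bool) -> Tuple[float, Fraction, tuple]:
    """(float extremum, exact value at the arg-optimum, the arg-optimum)."""
    import sympy

    f = sympy.lambdify(syms, expr, "numpy")
    axes = np.array([float(g) for g in GRID])
    n = len(syms)
    grids = [axes.reshape((1,) * i + (-1,) + (1,) * (n - i - 1)) for i in range(n)]
    vals = np.broadcast_to(f(*grids), (len(axes),) * n)
    idx = np.unravel_index(np.argmin(vals) if minimum else np.argmax(vals), vals.shape)
    arg = tuple(GRID[i] for i in idx)
    exact = Fraction(sympy.Rational(expr.subs(dict(zip(syms, arg)))))
    opt = float(vals.min() if minimum else vals.max())
    return opt, exact, arg


def _f_from_table(table):
    return (
        3 * table.cf("a1", "b1", "a2", "c") * table.cf("a1", "b1", "b2", "c")
        - table.cf("a1", "b1", "a2", "b2")
    )


def target_t2() -> Dict[str, float]:
    """Grid minimum of the cherry statistic on the 3(1)-cycle network."""
    syms, f = _symbolic_statistic("N5-31", _f_from_table)
    lo, exact, _ = _grid_extremum(syms, f, minimum=True)
    assert exact > 0
    return {"value": float(exact), "n": len(GRID) ** len(syms)}


def target_t3() -> Dict[str, float]:
    """Grid maximum of the shifted cherry statistic on the 3(2)-cycle network."""
    import sympy

    def builder(table):
        return _f_from_table(table) - table.cf("a1", "b1", "a2", "b2") / 2

    syms, ft = _symbolic_statistic("N5-32", builder)
    hi, exact, _ = _grid_extremum(syms, ft, minimum=False)
    assert exact < 0
    return {"value": float(exact), "n": len(GRID) ** len(syms)}


def target_t4() -> Dict[str, float]:
    """Grid minimum of 9x the first bilinear form on the three-cherry
    3-cycle network."""

    def builder(table):
        return 9 * (
            table.cf("a1", "c1", "a2", "c2") * table.cf("a1", "b1", "b2", "c1")
            - 2 * table.cf("b1", "c1", "b2", "c2") * table.cf("a1", "b1", "a2", "c1")
            + table.cf("a1", "b1", "a2", "b2") * table.cf("a1", "c1", "b1", "c2")
        )

    syms, g9 = _symbolic_statistic("Na", builder)
    lo, exact, _ = _grid_extremum(syms, g9, minimum=True)
    assert exact > 0
    return {"value": float(exact), "n": len(GRID) ** len(syms)}


def target_t5() -> Dict[str, float]:
    """All three bilinear forms vanish symbolically on the three-cherry tree."""
    import sympy

    from .cfengine import cf_table
    from .fixtures import NamedNetworkSpec, make_named
    from .invariants import BlockAssignment, g_statistics

    l1, l2, l3 = sympy.symbols("l1 l2 l3", positive=True)
    net = make_named(NamedNetworkSpec("T6", {"l1": l1, "l2": l2, "l3": l3}))
    table = cf_table(net, expand=True)
    blocks = BlockAssignment(("a1", "a2"), ("b1", "b2"), ("c1", "c2"))
    gs = [sympy.simplify(g) for g in g_statistics(table, blocks)]
    assert all(g == 0 for g in gs)
    return {"value": float(sum(abs(g) for g in gs)), "n": 3}


def target_t6() -> Dict[str, float]:
    """The cherry statistic vanishes symbolically on the 5-taxon tree."""
    import sympy

    from .cfengine import cf_table
    from .fixtures import NamedNetworkSpec, make_named

    l1, l2 = sympy.symbols("l1 l2", positive=True)
    net = make_named(NamedNetworkSpec("T5", {"l1": l1, "l2": l2}))
    table = cf_table(net, expand=True)
    f = sympy.simplify(_f_from_table(table))
    assert f == 0
    return {"value": float(f), "n": 1}


_GENERIC_POINTS = {
    "Ns": {"gamma": Fraction(13, 101), "h1": Fraction(17, 101), "h2": Fraction(19, 101),
           "x1": Fraction(23, 101), "x2": Fraction(29, 101), "l": Fraction(31, 101)},
    "Nw": {"gamma": Fraction(13, 101), "x1": Fraction(17, 101), "x2": Fraction(19, 101),
           "l": Fraction(23, 101)},
    "Nn": {"gamma": Fraction(13, 101), "x1": Fraction(17, 101), "x2": Fraction(19, 101),
           "l": Fraction(23, 101)},
    "pvector": {"gamma": Fraction(13, 101), "l1": Fraction(17, 101), "l2": Fraction(19, 101),
                "l3": Fraction(23, 101), "h1": Fraction(29, 101), "h2": Fraction(31, 101),
                "x": Fraction(37, 101)},
}


def _rank_target(family: str, point=None) -> Dict[str, float]:
    from .invariants import variety_dimension

    pt = point if point is not None else _GENERIC_POINTS[family]
    rank = variety_dimension(family, pt, confirm=True)
    return {"value": float(rank), "n": len(pt)}


def target_t7() -> Dict[str, float]:
    return _rank_target("Ns")


def target_t8() -> Dict[str, float]:
    return _rank_target("Nw")


def target_t9() -> Dict[str, float]:
    return _rank_target("Nn")


def target_t10() -> Dict[str, float]:
    point = {"gamma": Fraction(28, 100), "h1": Fraction(83, 100), "h2": Fraction(78, 100),
             "x": Fraction(98, 100), "l1": Fraction(88, 100), "l2": Fraction(61, 100),
             "l3": Fraction(50, 100)}
    return _rank_target("Na", point)


def target_t11() -> Dict[str, float]:
    """The three bilinear forms sum to zero on arbitrary symbolic tables."""
    import sympy

    c = sympy.symbols("cAA cBB cCC cAB cAC cBC")
    cacac, cbcbc, cabab, cabbc, cabac, cacbc = c
    X = cacac * cabbc
    Y = cbcbc * cabac
    Z = cabab * cacbc
    total = sympy.simplify((X - 2 * Y + Z) + (Y - 2 * Z + X) + (Z - 2 * X + Y))
    assert total == 0
    return {"value": float(total), "n": 6}


def target_t12() -> Dict[str, float]:
    return _rank_target("pvector")


ALL_TARGETS = {
    "t2": target_t2,
    "t3": target_t3,
    "t4": target_t4,
    "t5": target_t5,
    "t6": target_t6,
    "t7": target_t7,
    "t8": target_t8,
    "t9": target_t9,
    "t10": target_t10,
    "t11": target_t11,
    "t12": target_t12,
}
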