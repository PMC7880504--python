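"""Narrow-exchange and narrow-exchange-rate (NER) operators.

Narrow exchange is the minimal branch-rearrangement move: given a node E with
children D (the taller) and C, and D's children A and B, it relocates A to E
so that D's children become B and C. Heights are unchanged, and the tree
changes by Robinson-Foulds distance exactly 1.

NER augments the move with new rates r'_A..r'_D chosen to conserve a subset
of the six pairwise genetic distances among {A, B, C, E}:

    D_AB, D_AC, D_AE, D_BC, D_BE, D_CE

Each subset yields a linear system in the four proposed rates (given the
optionally-walked height t'_D). Systems are solved symbolically once and
cached; unconstrained rates keep their current values, making the empty
subset NER{} exactly classic narrow exchange. The Green ratio is the
determinant of the 5x5 Jacobian of (r'_A..r'_D, t'_D) with respect to
(r_A..r_D, t_D); its last row is (0,0,0,0,1), so it reduces to the 4x4 rate
block. Solvable systems with an identically zero determinant correspond to
irreversible proposals and are discarded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import sympy as sp

from .clock import REAL, QUANT
from .kernels import Kernel
from .operators import Operator, Proposal, _reject, get_real_rate, set_real_rates

CONSTRAINT_NAMES = ("DAB", "DAC", "DAE", "DBC", "DBE", "DCE")

UNSOLVABLE, ZERO_JACOBIAN, VALID = "unsolvable", "zero-jacobian", "valid"

# symbols: current rates/heights, proposed height
_rA, _rB, _rC, _rD = sp.symbols("rA rB rC rD", positive=True)
_tA, _tB, _tC, _tD, _tE, _tDp = sp.symbols("tA tB tC tD tE tDp", real=True)
_rAp, _rBp, _rCp, _rDp = sp.symbols("rAp rBp rCp rDp")

_ARGS = (_rA, _rB, _rC, _rD, _tA, _tB, _tC, _tD, _tE, _tDp)


def _constraint_equations():
    """Constant-genetic-distance equations, before-topology = after-topology."""
    before = {
        "DAB": _rA * (_tD - _tA) + _rB * (_tD - _tB),
        "DAC": _rA * (_tD - _tA) + _rD * (_tE - _tD) + _rC * (_tE - _tC),
        "DAE": _rA * (_tD - _tA) + _rD * (_tE - _tD),
        "DBC": _rB * (_tD - _tB) + _rD * (_tE - _tD) + _rC * (_tE - _tC),
        "DBE": _rB * (_tD - _tB) + _rD * (_tE - _tD),
        "DCE": _rC * (_tE - _tC),
    }
    after = {
        "DAB": _rAp * (_tE - _tA) + _rDp * (_tE - _tDp) + _rBp * (_tDp - _tB),
        "DAC": _rAp * (_tE - _tA) + _rDp * (_tE - _tDp) + _rCp * (_tDp - _tC),
        "DAE": _rAp * (_tE - _tA),
        "DBC": _rBp * (_tDp - _tB) + _rCp * (_tDp - _tC),
        "DBE": _rBp * (_tDp - _tB) + _rDp * (_tE - _tDp),
        "DCE": _rCp * (_tDp - _tC) + _rDp * (_tE - _tDp),
    }
    return {k: sp.Eq(after[k], before[k]) for k in CONSTRAINT_NAMES}


@dataclass
class NERSolution:
    """Closed-form rate updates and Jacobian for one constraint subset."""

    constraints: tuple
    status: str
    exprs: dict = None          # name -> sympy expression for r'_X
    jacobian: sp.Expr = None    # symbolic det of the 4x4 rate block
    _func: callable = None      # numeric (rA..rD, tA..tE, tDp) -> (4 rates, J)

    @property
    def label(self) -> str:
        return "NER{" + ",".join(self.constraints) + "}"

    def evaluate(self, rates, heights, t_d_new):
        """Numeric proposed rates (r'_A, r'_B, r'_C, r'_D) and |J|."""
        if self.status != VALID:
            raise ValueError(f"{self.label} is {self.status}")
        out = self._func(*rates, *heights, t_d_new)
        return np.asarray(out[:4], dtype=float), float(out[4])


def enumerate_constraint_sets():
    """All 2^6 = 64 subsets of the distance constraints, canonically ordered."""
    sets = []
    for k in range(7):
        sets.extend(itertools.combinations(CONSTRAINT_NAMES, k))
    return sets


def _is_zero(expr) -> bool:
    return sp.simplify(expr) == 0


@lru_cache(maxsize=None)
def solve_constraint_set(constraints: tuple) -> NERSolution:
    """Solve the linear system for one subset of distance constraints.

    Unconstrained proposed rates keep their current values (r'_X = r_X), so
    the empty subset is the identity rate map with |J| = 1.
    """
    constraints = tuple(sorted(constraints, key=CONSTRAINT_NAMES.index))
    eqs = _constraint_equations()
    unknowns = (_rAp, _rBp, _rCp, _rDp)
    system = [eqs[name] for name in constraints]
    if system:
        A, b = sp.linear_eq_to_matrix(system, unknowns)
        rank_a = A.rank(iszerofunc=_is_zero)
        rank_aug = A.row_join(b).rank(iszerofunc=_is_zero)
        if rank_aug > rank_a:
            return NERSolution(constraints, UNSOLVABLE)
        sol = sp.linsolve((A, b), unknowns)
        if not sol:
            return NERSolution(constraints, UNSOLVABLE)
        vec = list(sol)[0]
    else:
        vec = unknowns
    # free unknowns (returned as-is by linsolve) keep their current values
    free_map = {_rAp: _rA, _rBp: _rB, _rCp: _rC, _rDp: _rD}
    exprs = {}
    for sym, expr in zip(unknowns, vec):
        exprs[str(sym)] = sp.simplify(sp.sympify(expr).subs(free_map))
    rate_vec = [exprs["rAp"], exprs["rBp"], exprs["rCp"], exprs["rDp"]]
    jac4 = sp.Matrix([[sp.diff(e, r) for r in (_rA, _rB, _rC, _rD)]
                      for e in rate_vec])
    det = sp.simplify(jac4.det())
    if _is_zero(det):
        return NERSolution(constraints, ZERO_JACOBIAN, exprs, sp.Integer(0))
    func = sp.lambdify(_ARGS, rate_vec + [det], modules="numpy")
    return NERSolution(constraints, VALID, exprs, det, func)


def classify_all_solutions():
    """Census of all 64 constraint subsets by solver status.

    Returns a dict with the per-status counts and the number of operator
    variants: each valid solution exists with and without the t_D random walk
    (NER / NERw), with and without counting the null operator separately.
    """
    solutions = [solve_constraint_set(s) for s in enumerate_constraint_sets()]
    counts = {UNSOLVABLE: 0, ZERO_JACOBIAN: 0, VALID: 0}
    for s in solutions:
        counts[s.status] += 1
    census = {
        "total": len(solutions),
        "solvable": counts[VALID] + counts[ZERO_JACOBIAN],
        "zero_jacobian": counts[ZERO_JACOBIAN],
        "valid": counts[VALID],
        "variants": 2 * counts[VALID],
        "variants_excluding_null": 2 * (counts[VALID] - 1),
        "solutions": solutions,
    }
    return census


# ---------------------------------------------------------------------------
# topology move
# ---------------------------------------------------------------------------

def _grandparent_candidates(tree):
    """Internal nodes with at least one internal child (narrow-exchange
    grandparents)."""
    out = []
    for e in tree.internal_nodes(include_root=True):
        c1, c2 = (int(c) for c in tree.children[e])
        if not (tree.is_leaf(c1) and tree.is_leaf(c2)):
            out.append(e)
    return out


def narrow_exchange_topology(tree, rng):
    """Sample the node quintet (E, D, C, A, B) for a narrow-exchange move.

    E is drawn uniformly among internal/root nodes with grandchildren; D is
    E's taller child (reject if a leaf or tied with its sibling C); A and B
    are D's children in random order. Returns None on rejection.
    """
    cand = _grandparent_candidates(tree)
    if not cand:
        return None
    e = int(rng.choice(cand))
    c1, c2 = (int(c) for c in tree.children[e])
    h1, h2 = tree.heights[c1], tree.heights[c2]
    if h1 == h2:
        return None
    d, c = (c1, c2) if h1 > h2 else (c2, c1)
    if tree.is_leaf(d):
        return None
    a, b = (int(x) for x in tree.children[d])
    if rng.random() < 0.5:
        a, b = b, a
    return e, d, c, a, b


def apply_narrow_exchange(tree, e, d, c, a, b):
    """Relocate A to E and C to D (in place); heights untouched."""
    ch_e = tree.children[e]
    ch_e[np.where(ch_e == c)[0][0]] = a
    tree.children[d][0] = b
    tree.children[d][1] = c
    tree.parent[a] = e
    tree.parent[c] = d
    tree.invalidate_topology()


class NEROperator(Operator):
    """Narrow exchange with constant-genetic-distance rate proposals.

    ``constraints=()`` gives NER{} (classic narrow exchange, identity rates);
    passing ``walk`` (a kernel) gives the NERw variant that additionally
    embarks t_D on a random walk. The Hastings ratio carries the ratio of
    eligible-grandparent counts before and after the move.
    """

    modes = (REAL, QUANT)

    def __init__(self, constraints=("DAE", "DBE", "DCE"), walk: Kernel = None,
                 **kw):
        super().__init__(kernel=walk, **kw)
        self.solution = solve_constraint_set(tuple(constraints))
        if self.solution.status != VALID:
            raise ValueError(f"{self.solution.label} is {self.solution.status}")
        self.walk = walk
        self.kernel = walk  # tuned only for NERw
        suffix = "w" if walk is not None else ""
        self.name = kw.get("name") or self.solution.label.replace("NER", f"NER{suffix}", 1)

    def available(self, state):
        if self.solution.constraints and state.rates.mode not in self.modes:
            return False
        return True

    def _propose(self, state, rng):
        tree = state.tree
        quintet = narrow_exchange_topology(tree, rng)
        if quintet is None:
            return _reject(self)
        e, d, c, a, b = quintet
        heights = (float(tree.heights[a]), float(tree.heights[b]),
                   float(tree.heights[c]), float(tree.heights[d]),
                   float(tree.heights[e]))
        t_a, t_b, t_c, t_d, t_e = heights
        t_d_new = t_d
        if self.walk is not None:
            t_d_new = t_d + float(self.walk.step(rng))
        if not (max(t_b, t_c) < t_d_new < t_e):
            return _reject(self)
        rates = get_real_rate(state, [a, b, c, d])
        new_rates, jac = self.solution.evaluate(rates, heights, t_d_new)
        if np.any(new_rates <= 0) or jac == 0 or not np.isfinite(jac):
            return _reject(self)
        g_before = len(_grandparent_candidates(tree))
        new = state.copy()
        apply_narrow_exchange(new.tree, e, d, c, a, b)
        new.tree.heights[d] = t_d_new
        extra = 0.0
        if self.solution.constraints or state.rates.mode == QUANT:
            changed = [a, b, c, d]
            extra = set_real_rates(new, changed, new_rates)
            if extra is None:
                return _reject(self)
        g_after = len(_grandparent_candidates(new.tree))
        lh = float(np.log(g_before) - np.log(g_after))
        return Proposal(new, log_hastings=lh,
                        log_jacobian=float(np.log(abs(jac))) + extra)


def census_report() -> str:
    """Human/machine-readable census of all constraint subsets."""
    census = classify_all_solutions()
    lines = ["subset\tstatus\tjacobian"]
    for s in census["solutions"]:
        jac = "" if s.jacobian is None else str(s.jacobian)
        lines.append(f"{s.label}\t{s.status}\t{jac}")
    lines.append("")
    lines.append(f"total\t{census['total']}")
    lines.append(f"solvable\t{census['solvable']}")
    lines.append(f"zero_jacobian\t{census['zero_jacobian']}")
    lines.append(f"valid\t{census['valid']}")
    lines.append(f"ner_nerw_variants\t{census['variants']}")
    lines.append(f"ner_nerw_variants_excluding_null\t{census['variants_excluding_null']}")
    return "\n".join(lines) + "\n"
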