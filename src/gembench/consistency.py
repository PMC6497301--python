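"""Flux-consistency testing (FASTCC) and blocked-reaction accounting.

A reaction is *blocked* when it cannot carry a flux of magnitude >= eps
in any steady state permitted by the bounds.  FASTCC finds the maximal
flux-consistent subnetwork with a handful of support-maximization LPs
(the LP-7 construction) instead of two LPs per reaction, flipping the
orientation of reversible reactions when only their reverse direction
can be activated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import numpy as np
import pandas as pd

from .lp import solve_lp
from .model import MediumSpec, MetabolicModel, apply_medium

__all__ = ["ConsistencyReport", "fastcc", "blocked_fraction", "DEFAULT_EPSILON"]

#: Default flux-activation threshold (mmol gDW^-1 hr^-1).
DEFAULT_EPSILON = 1e-4

#: Exchange bound magnitude defining the "unconstrained" network state.
UNCONSTRAINED_BOUND = 1000.0


@dataclass
class ConsistencyReport:
    consistent: Set[str]
    blocked: Set[str]
    epsilon: float
    constrained: bool = True
    witness: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reaction_id": r,
                "status": "consistent" if r in self.consistent else "blocked",
                "witness_flux": self.witness.get(r, 0.0),
            }
            for r in sorted(self.consistent | self.blocked)
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _lp7(S, lb, ub, J: List[int], eps: float) -> Optional[np.ndarray]:
    """Maximize the number of reactions in J with flux >= eps.

    max sum z_j  s.t.  S v = 0, bounds, 0 <= z_j <= eps, z_j <= v_j.
    Returns the flux part of the solution (or None when infeasible).
    """
    n = S.shape[1]
    k = len(J)
    if k == 0:
        return np.zeros(n)
    S2 = np.hstack([S, np.zeros((S.shape[0], k))])
    lb2 = np.concatenate([lb, np.zeros(k)])
    ub2 = np.concatenate([ub, np.full(k, eps)])
    # z_j - v_j <= 0
    A = np.zeros((k, n + k))
    for row, j in enumerate(J):
        A[row, n + row] = 1.0
        A[row, j] = -1.0
    c = np.zeros(n + k)
    c[n:] = 1.0
    status, x, _ = solve_lp(S2, lb2, ub2, c, "max", A, np.zeros(k))
    if status != "optimal":
        return None
    return x[:n]


def _support(v: np.ndarray, eps: float) -> Set[int]:
    return set(np.flatnonzero(np.abs(v) >= 0.99 * eps))


def fastcc(model: MetabolicModel, epsilon: float = DEFAULT_EPSILON) -> ConsistencyReport:
    """Partition reactions into flux-consistent and blocked sets."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = model.n_reactions
    if n == 0:
        return ConsistencyReport(set(), set(), epsilon)
    S = model.S.copy()
    lb = model.lb.copy()
    ub = model.ub.copy()
    irreversible = set(np.flatnonzero(model.lb >= 0))

    witness: Dict[int, float] = {}

    def record(v):
        for i in _support(v, epsilon):
            if i not in witness:
                witness[i] = float(v[i])

    A: Set[int] = set()
    J = sorted(set(range(n)) & irreversible)
    v = _lp7(S, lb, ub, J, epsilon)
    if v is not None:
        record(v)
        A |= _support(v, epsilon)
    # irreversible reactions not activated by the first pass are blocked;
    # the loop below only revisits reversible candidates
    J = sorted((set(range(n)) - irreversible) - A)
    flipped = False
    singleton = False
    while J:
        Ji = [J[0]] if singleton else J
        v = _lp7(S, lb, ub, Ji, epsilon)
        supp = _support(v, epsilon) if v is not None else set()
        if v is not None:
            record(v)
        A |= supp
        if set(J) & A:
            J = sorted(set(J) - A)
            flipped = False
            singleton = False
        else:
            if flipped:
                flipped = False
                if singleton:
                    J = J[1:]  # genuinely blocked reversible
                else:
                    singleton = True
            else:
                # flip orientation of the reversible candidates
                for i in Ji:
                    lb[i], ub[i] = -ub[i], -lb[i]
                    S[:, i] = -S[:, i]
                flipped = True
    consistent = {model.reaction_ids[i] for i in A}
    blocked = set(model.reaction_ids) - consistent
    return ConsistencyReport(
        consistent,
        blocked,
        epsilon,
        witness={model.reaction_ids[i]: w for i, w in witness.items()},
    )


def blocked_fraction(
    model: MetabolicModel,
    medium: Optional[MediumSpec] = None,
    epsilon: float = DEFAULT_EPSILON,
    unconstrained: bool = False,
) -> float:
    """Fraction of blocked reactions, optionally under a medium.

    ``unconstrained=True`` opens every exchange reaction symmetrically to
    +-1000 mmol gDW^-1 hr^-1 before testing, probing pure network
    topology rather than the medium.
    """
    m = model
    if medium is not None:
        m = apply_medium(m, medium)
    if unconstrained:
        m = m.copy()
        for rid in m.exchange_ids:
            i = m.reaction_index(rid)
            m.lb[i] = -UNCONSTRAINED_BOUND
            m.ub[i] = UNCONSTRAINED_BOUND
    rep = fastcc(m, epsilon)
    rep.constrained = not unconstrained
    if m.n_reactions == 0:
        return 0.0
    return len(rep.blocked) / m.n_reactions
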