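"""The microarray game: coalitions, marginal contributions, Shapley values.

Each sample column of a group-restricted Boolean matrix defines a *winning
coalition* — the set of genes coded 1 in that sample (its *support*).  The
sample's unit of utility is shared equally among the coalition members, so
a member of a size-``k`` coalition receives a marginal contribution of
``1/k`` and non-members receive 0.  A gene's Shapley value in a condition
is the average of its marginal contributions over all samples of that
condition, empty-coalition samples included in the divisor.

This closed form coincides with the classical Shapley value of the
aggregate coalitional game

    v(T) = (1/|S|) * #{ j : C_j != empty and C_j subseteq T },

i.e. the average of the unanimity games ``u_{C_j}`` over the condition's
samples.  :func:`brute_force_shapley` evaluates the classical
subset-enumeration formula on that game and serves as an independent
oracle for the closed form (exponential in the number of genes, so it is
capped at 20 players).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from collections.abc import Iterable, Sequence

import numpy as np

from .encoding import BooleanMatrix
from .exceptions import MicrogameError

__all__ = [
    "SupportList",
    "ShapleyResult",
    "CoalitionalGame",
    "supports",
    "marginal_contribution",
    "shapley_values",
    "brute_force_shapley",
    "shapley_table",
]

#: brute-force enumeration cap (2^n subsets per player)
MAX_BRUTE_FORCE_PLAYERS = 20

SupportList = list  # list[frozenset[str]], one coalition per sample column


def supports(B_group: BooleanMatrix) -> list[frozenset]:
    """Per-sample winning coalitions: the genes coded 1 in each column."""
    if B_group.n_samples == 0:
        raise MicrogameError("cannot form coalitions from a matrix with no samples")
    genes = np.asarray(B_group.gene_ids, dtype=object)
    return [frozenset(genes[B_group.bits[:, j] == 1]) for j in range(B_group.n_samples)]


def marginal_contribution(gene: str, coalition: Iterable) -> float:
    """Equal split of a coalition's unit utility: ``1/|C|`` for members, else 0."""
    coalition = frozenset(coalition)
    if gene in coalition:
        return 1.0 / len(coalition)
    return 0.0


@dataclass(frozen=True)
class ShapleyResult:
    """Marginal contributions and mean Shapley values for one condition.

    ``marginals[i, j]`` is gene i's share of sample j's unit utility
    (``1/|C_j|`` or 0); ``phi[i]`` is the row mean over the condition's
    samples.  Each nonempty column of ``marginals`` sums to exactly 1, so
    ``phi.sum()`` equals (number of nonempty coalitions) / (number of
    samples) — the efficiency identity of the aggregate game.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    marginals: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)

    def to_series(self):
        import pandas as pd

        return pd.Series(self.phi, index=list(self.gene_ids), name="meanSh")


def shapley_values(B_group: BooleanMatrix) -> ShapleyResult:
    """Closed-form Shapley values of the microarray game of one condition.

    The divisor is the total number of samples in the group; samples whose
    coalition is empty contribute zero to every gene but still count in
    the denominator.
    """
    if B_group.n_samples == 0:
        raise MicrogameError("Shapley values need at least one sample column")
    bits = B_group.bits.astype(float)
    sizes = bits.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        marginals = np.where(sizes > 0, bits / np.where(sizes == 0, 1.0, sizes), 0.0)
    phi = marginals.mean(axis=1)
    return ShapleyResult(
        gene_ids=B_group.gene_ids,
        sample_ids=B_group.sample_ids,
        marginals=marginals,
        phi=phi,
    )


@dataclass(frozen=True)
class CoalitionalGame:
    """The aggregate game induced by one condition's Boolean matrix.

    ``value(T)`` counts the nonempty per-sample coalitions contained in
    ``T`` and divides by the total number of samples; it is 0 on the empty
    set, monotone under set inclusion, and reaches
    ``(#nonempty coalitions)/|S|`` on the grand coalition.
    """

    players: tuple[str, ...]
    sample_supports: tuple[frozenset, ...]
    n_samples: int

    @classmethod
    def from_boolean(cls, B_group: BooleanMatrix) -> "CoalitionalGame":
        return cls(
            players=B_group.gene_ids,
            sample_supports=tuple(supports(B_group)),
            n_samples=B_group.n_samples,
        )

    @classmethod
    def from_supports(
        cls, coalitions: Sequence[Iterable], n_samples: int | None = None
    ) -> "CoalitionalGame":
        sup = tuple(frozenset(c) for c in coalitions)
        players = tuple(sorted(set().union(*sup))) if sup else ()
        return cls(players=players, sample_supports=sup,
                   n_samples=len(sup) if n_samples is None else n_samples)

    def value(self, coalition: Iterable) -> float:
        T = frozenset(coalition)
        hits = sum(1 for s in self.sample_supports if s and s <= T)
        return hits / self.n_samples


def brute_force_shapley(game: CoalitionalGame) -> np.ndarray:
    """Classical Shapley value by exhaustive subset enumeration.

    phi_i = sum over T subseteq N\\{i} of |T|!(n-|T|-1)!/n! * (v(T+i) - v(T)).

    Independent of the closed form: evaluates ``game.value`` on every
    subset via bitmask enumeration.  Raises beyond
    :data:`MAX_BRUTE_FORCE_PLAYERS` players; use :func:`shapley_values`
    (the closed form) for anything larger.
    """
    n = len(game.players)
    if n == 0:
        return np.zeros(0)
    if n > MAX_BRUTE_FORCE_PLAYERS:
        raise MicrogameError(
            f"brute-force enumeration capped at {MAX_BRUTE_FORCE_PLAYERS} players "
            f"(got {n}); use the closed-form shapley_values instead"
        )
    index = {p: k for k, p in enumerate(game.players)}
    # support bitmasks of the nonempty per-sample coalitions
    masks = [
        sum(1 << index[g] for g in s) for s in game.sample_supports if s
    ]
    inv_s = 1.0 / game.n_samples

    def v(mask: int) -> float:
        return inv_s * sum(1 for m in masks if m & mask == m)

    fact = [factorial(k) for k in range(n + 1)]
    weight = [fact[t] * fact[n - t - 1] / fact[n] for t in range(n)]
    phi = np.zeros(n)
    full = (1 << n) - 1
    for i in range(n):
        others = full & ~(1 << i)
        # enumerate all subsets T of the other players
        T = others
        while True:
            gain = v(T | (1 << i)) - v(T)
            if gain:
                phi[i] += weight[bin(T).count("1")] * gain
            if T == 0:
                break
            T = (T - 1) & others
    return phi


def shapley_table(B_group: BooleanMatrix, round_to: int | None = 3):
    """Bits, per-sample marginal contributions and meanSh as one DataFrame.

    Mirrors the per-condition presentation of the worked example: the
    Boolean block, one ``Sh<sample>`` column per sample, and the row mean.
    """
    import pandas as pd

    res = shapley_values(B_group)
    df = B_group.to_dataframe()
    sh = pd.DataFrame(
        res.marginals,
        index=list(B_group.gene_ids),
        columns=[f"Sh{s}" for s in B_group.sample_ids],
    )
    out = pd.concat([df, sh], axis=1)
    out["meanSh"] = res.phi
    if round_to is not None:
        out = out.round(round_to)
    return out
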