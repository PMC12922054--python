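"""Synthetic expression data with known cooperative structure.

The generator draws each gene's baseline expression i.i.d. Gaussian with
a per-gene mean and SD (themselves drawn uniformly from stated ranges),
then plants a *coordinated* shift: in one randomly chosen subset of
experimental samples, every signal gene is moved by
``effect_size x (its own baseline SD)`` up or down.  Shifting the same
samples for all signal genes is what creates joint coalitions — the
cooperative signal the Boolean encoding and the game are built to
detect — as opposed to independent marginal shifts.

Defaults mirror the scale of the worked example: 9 genes, 5 control and
5 experimental samples, baseline means in [3, 7] and SDs in [0.05, 0.3]
(the ranges spanned by the example matrix), a 3-SD shift in 60% of the
experimental samples.  Gaussian baselines match the implicit calibration
of the mean ± SD encoding; heavy-tailed or zero-inflated count models
(RNA-seq, single-cell) are deliberately not emulated.

:func:`table1_fixture` returns the packaged 9 x 10 worked-example matrix
with its 5/5 control/experimental labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .exceptions import DataError
from .io import CONTROL, EXPERIMENTAL, ExpressionMatrix, GroupLabels

__all__ = ["SyntheticSpec", "generate_dataset", "table1_fixture"]

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic expression generator.

    ``signal_genes`` are 0-based row indices; ``effect_size`` is in units
    of each gene's own baseline SD; ``affected_fraction`` is the fraction
    of experimental samples receiving the shift (the same samples for
    every signal gene).
    """

    n_genes: int = 9
    n_control: int = 5
    n_experimental: int = 5
    baseline_mean_range: tuple[float, float] = (3.0, 7.0)
    baseline_sd_range: tuple[float, float] = (0.05, 0.3)
    signal_genes: tuple[int, ...] = ()
    effect_size: float = 3.0
    affected_fraction: float = 0.6
    direction: str = DOWN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise DataError("n_genes must be positive")
        if self.n_control < 2:
            raise DataError("need at least 2 control samples")
        if self.n_experimental < 1:
            raise DataError("need at least 1 experimental sample")
        if self.baseline_sd_range[0] <= 0:
            raise DataError("baseline SDs must be positive")
        sig = tuple(int(g) for g in self.signal_genes)
        object.__setattr__(self, "signal_genes", sig)
        if any(g < 0 or g >= self.n_genes for g in sig):
            raise DataError("signal gene index out of range")
        if self.effect_size < 0:
            raise DataError("effect_size must be >= 0")
        if not 0.0 < self.affected_fraction <= 1.0:
            raise DataError("affected_fraction must lie in (0, 1]")
        if self.direction not in (UP, DOWN):
            raise DataError(f"direction must be '{UP}' or '{DOWN}'")


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, GroupLabels, list[str]]:
    """Draw one dataset; returns (matrix, labels, planted gene ids).

    Reproducible: the same spec (including seed) yields the same data.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_experimental
    means = rng.uniform(*spec.baseline_mean_range, size=spec.n_genes)
    sds = rng.uniform(*spec.baseline_sd_range, size=spec.n_genes)
    values = means[:, None] + sds[:, None] * rng.standard_normal((spec.n_genes, n))

    gene_ids = tuple(f"gene{i + 1}" for i in range(spec.n_genes))
    sample_ids = tuple(
        [f"C{j + 1}" for j in range(spec.n_control)]
        + [f"E{j + 1}" for j in range(spec.n_experimental)]
    )

    planted = [gene_ids[g] for g in spec.signal_genes]
    if planted and spec.effect_size > 0:
        n_affected = max(1, int(round(spec.affected_fraction * spec.n_experimental)))
        affected = rng.choice(spec.n_experimental, size=n_affected, replace=False)
        cols = spec.n_control + affected
        sign = 1.0 if spec.direction == UP else -1.0
        for g in spec.signal_genes:
            values[g, cols] += sign * spec.effect_size * sds[g]

    matrix = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)
    labels = GroupLabels(
        {s: (CONTROL if s.startswith("C") else EXPERIMENTAL) for s in sample_ids}
    )
    return matrix, labels, planted


def table1_fixture() -> tuple[ExpressionMatrix, GroupLabels]:
    """The packaged 9-gene x 10-sample worked-example matrix and labels."""
    from .io import read_expression_matrix

    with resources.as_file(
        resources.files("microgame").joinpath("data/table1.tsv")
    ) as path:
        matrix = read_expression_matrix(path)
    labels = GroupLabels(
        {s: (CONTROL if s.startswith("C") else EXPERIMENTAL) for s in matrix.sample_ids}
    )
    return matrix, labels
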