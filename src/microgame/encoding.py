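"""Boolean encoding of expression relative to control statistics.

Each gene's control mean :math:`\\mu_i^C` and control *sample* standard
deviation :math:`\\sigma_i^C` (divisor ``n-1``) define two indicator
matrices over **all** samples, controls included:

* over-expression  ``B+``: 1 where ``X[i, j] >= mu_i + sd_i``;
* under-expression ``B-``: 1 where ``X[i, j] <= mu_i - sd_i``.

Both comparisons are inclusive at the boundary.  For a gene whose control
values are constant (``sd == 0``) the two thresholds collapse onto the
mean; the formulas are applied literally and a warning lists the affected
genes, since such a gene is coded 1 in *both* matrices wherever its value
equals the mean.

The encoding is invariant under positive affine rescaling of a gene's row
(``x -> a*x + b`` with ``a > 0``), because mean, SD and thresholds rescale
together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError
from .io import CONTROL, EXPERIMENTAL, ExpressionMatrix, GroupLabels

__all__ = [
    "OVER",
    "UNDER",
    "ControlSummary",
    "BooleanMatrix",
    "control_summary",
    "binarize",
    "split_by_group",
]

logger = logging.getLogger(__name__)

OVER = "over"
UNDER = "under"
DIRECTIONS = (OVER, UNDER)


@dataclass(frozen=True)
class ControlSummary:
    """Per-gene mean and sample SD of expression over control samples."""

    gene_ids: tuple[str, ...]
    mean: np.ndarray = field(repr=False)
    sd: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if np.any(self.sd < 0):
            raise DataError("negative standard deviation")


@dataclass(frozen=True)
class BooleanMatrix:
    """A {0,1} matrix flagging one expression property per cell.

    Same shape and identifier ordering as the source expression matrix;
    ``direction`` records which property the 1s mark.
    """

    direction: str
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    bits: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise DataError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        bits = np.asarray(self.bits)
        if not np.isin(bits, (0, 1)).all():
            raise DataError("Boolean matrix may only contain 0 and 1")
        object.__setattr__(self, "bits", bits.astype(np.uint8))
        if self.bits.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("Boolean matrix shape does not match identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.bits.astype(int), index=list(self.gene_ids), columns=list(self.sample_ids)
        )


def control_summary(X: ExpressionMatrix, labels: GroupLabels) -> ControlSummary:
    """Mean and sample SD (divisor ``n-1``) of each gene over control samples.

    Requires a label for every sample and at least 2 controls; an empty
    experimental group is tolerated here (the game layer rejects it).
    """
    missing = [s for s in X.sample_ids if s not in labels.assignment]
    if missing:
        raise DataError(f"samples without a group label: {missing}")
    ctrl_ids = labels.control_ids(X.sample_ids)
    if len(ctrl_ids) < 2:
        raise DataError("control SD undefined: need at least 2 control samples")
    idx = [X.sample_ids.index(s) for s in ctrl_ids]
    ctrl = X.values[:, idx]
    return ControlSummary(
        gene_ids=X.gene_ids,
        mean=ctrl.mean(axis=1),
        sd=ctrl.std(axis=1, ddof=1),
    )


def binarize(X: ExpressionMatrix, labels: GroupLabels, direction: str) -> BooleanMatrix:
    """Encode over- or under-expression of every cell relative to controls.

    All samples are binarized, controls included: the control-side matrices
    are needed both for the control-condition game and for the selection
    threshold downstream.
    """
    if direction not in DIRECTIONS:
        raise DataError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    summary = control_summary(X, labels)
    degenerate = [g for g, s in zip(summary.gene_ids, summary.sd) if s == 0.0]
    if degenerate:
        msg = (
            "constant control expression (sd = 0) for gene(s) "
            f"{degenerate}: both thresholds collapse onto the control mean"
        )
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    mu = summary.mean[:, None]
    sd = summary.sd[:, None]
    if direction == OVER:
        bits = X.values >= mu + sd
    else:
        bits = X.values <= mu - sd
    return BooleanMatrix(
        direction=direction,
        gene_ids=X.gene_ids,
        sample_ids=X.sample_ids,
        bits=bits.astype(np.uint8),
    )


def split_by_group(
    B: BooleanMatrix, labels: GroupLabels
) -> tuple[BooleanMatrix, BooleanMatrix]:
    """Partition a Boolean matrix's columns into (control, experimental) blocks.

    Column order within each block follows the source matrix.  An empty
    experimental block is permitted here (it is rejected by the game layer,
    which needs at least one sample column).
    """
    missing = [s for s in B.sample_ids if s not in labels.assignment]
    if missing:
        raise DataError(f"samples without a group label: {missing}")

    def _restrict(label: str) -> BooleanMatrix:
        ids = [s for s in B.sample_ids if labels.label_of(s) == label]
        idx = [B.sample_ids.index(s) for s in ids]
        return BooleanMatrix(
            direction=B.direction,
            gene_ids=B.gene_ids,
            sample_ids=tuple(ids),
            bits=B.bits[:, idx] if idx else np.zeros((B.n_genes, 0), dtype=np.uint8),
        )

    return _restrict(CONTROL), _restrict(EXPERIMENTAL)
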