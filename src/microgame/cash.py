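"""ADSV and CASh: resampling significance for differential cooperation.

The effect-size statistic is the absolute difference in Shapley values
(ADSV) of each gene between the control-condition and the
experimental-condition game.  CASh (Comparative Analysis of Shapley
values) calibrates it by relabeling samples: for each of ``B`` resamples
the control/experimental labels are reassigned at random, the whole
pipeline is recomputed under the pseudo-labels, and the p-value of gene
``i`` is the fraction of resamples whose ADSV* reaches the observed ADSV:

    p_i = (1/B) * sum_b I(ADSV*_ib >= ADSV_i)

The indicator is inclusive, so a gene with observed ADSV = 0 always gets
p = 1.  With the optional add-one correction the estimate becomes
``(1 + count) / (B + 1)`` and can never be exactly zero.

Two relabeling modes are provided.  ``permute_labels`` (default) draws a
uniformly random relabeling that preserves the observed group sizes —
the group sizes enter the game's divisors, so holding them fixed tests
exchangeability of the samples alone.  ``bootstrap_labels`` relabels each
sample independently (control with probability ``n_C/n``), rejecting
degenerate draws with fewer than 2 pseudo-controls or 1
pseudo-experimental.

By default the Boolean matrices are *recomputed* from raw expression
under each pseudo-labeling, since the encoding thresholds are functions
of whichever samples are currently "controls".  Setting
``recompute_binarization=False`` instead keeps the original Boolean
matrix fixed and only re-partitions its columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import OVER, DIRECTIONS
from .exceptions import DataError, MicrogameError
from .io import CONTROL, EXPERIMENTAL, ExpressionMatrix, GroupLabels
from .selection import adsv_threshold, select_candidates

__all__ = [
    "PERMUTE_LABELS",
    "BOOTSTRAP_LABELS",
    "CashConfig",
    "GameComparison",
    "adsv",
    "resample_labels",
    "cash_pvalues",
]

PERMUTE_LABELS = "permute_labels"
BOOTSTRAP_LABELS = "bootstrap_labels"
_MODES = (PERMUTE_LABELS, BOOTSTRAP_LABELS)

ADJUST_NONE = "none"
ADJUST_BH = "benjamini_hochberg"

#: tie guard: mathematically equal ADSV* computed along a different float
#: summation path still counts as an exceedance
_TIE_EPS = 1e-12

#: bound on consecutive rejected bootstrap draws before giving up
_MAX_REJECTS = 1000


@dataclass(frozen=True)
class CashConfig:
    """Parameters of the CASh resampling procedure.

    Attributes
    ----------
    n_resamples : int
        Number of relabelings ``B`` (default 1000).
    resampling_mode : str
        ``"permute_labels"`` (group-size preserving, default) or
        ``"bootstrap_labels"`` (independent relabeling with rejection).
    recompute_binarization : bool
        Re-run the Boolean encoding under each pseudo-labeling (default
        True); if False, only the columns of the original Boolean matrix
        are re-partitioned.
    alpha : float
        Significance level for the selection criterion (default 0.05).
    seed : int
        Seed of the resampling stream; resample ``b`` is a pure function
        of ``(seed, b)``.
    add_one_correction : bool
        Use ``(1 + count)/(B + 1)`` instead of ``count/B`` (default False).
    adjust : str
        ``"none"`` or ``"benjamini_hochberg"`` across genes within a
        direction (default ``"none"``).
    """

    n_resamples: int = 1000
    resampling_mode: str = PERMUTE_LABELS
    recompute_binarization: bool = True
    alpha: float = 0.05
    seed: int = 0
    add_one_correction: bool = False
    adjust: str = ADJUST_NONE

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise DataError("n_resamples must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise DataError("alpha must lie in (0, 1]")
        if self.resampling_mode not in _MODES:
            raise DataError(f"resampling_mode must be one of {_MODES}")
        if self.adjust not in (ADJUST_NONE, ADJUST_BH):
            raise DataError(f"adjust must be one of {(ADJUST_NONE, ADJUST_BH)}")

    def with_(self, **kwargs) -> "CashConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GameComparison:
    """Per-gene comparison of one direction's control vs experimental game.

    Carries the two Shapley vectors, the ADSV, the magnitude threshold,
    the CASh p-values (optionally BH-adjusted) and the selection flags.
    """

    direction: str
    gene_ids: tuple[str, ...]
    phi_control: np.ndarray = field(repr=False)
    phi_experimental: np.ndarray = field(repr=False)
    adsv: np.ndarray = field(repr=False)
    threshold: float
    p: np.ndarray = field(repr=False)
    alpha: float
    p_adjusted: np.ndarray | None = field(default=None, repr=False)
    selected: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("phi_control", "phi_experimental", "adsv", "p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise DataError(f"{name} must have one entry per gene")
            object.__setattr__(self, name, arr)
        if np.any((self.p < 0) | (self.p > 1)):
            raise DataError("p-values must lie in [0, 1]")
        if self.selected is None:
            object.__setattr__(
                self, "selected", np.array(
                    [g in set(select_candidates(self)) for g in self.gene_ids]
                )
            )

    @property
    def candidates(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.selected) if s]

    def to_frame(self):
        import pandas as pd

        data = {
            "gene_id": list(self.gene_ids),
            "meanShC": self.phi_control,
            "meanShE": self.phi_experimental,
            "ADSV": self.adsv,
            "CASh_p": self.p,
        }
        if self.p_adjusted is not None:
            data["adjusted_p"] = self.p_adjusted
        data["selected"] = np.asarray(self.selected, dtype=bool)
        return pd.DataFrame(data)


def adsv(phi_control: np.ndarray, phi_experimental: np.ndarray) -> np.ndarray:
    """Absolute difference of per-gene Shapley values between conditions."""
    phi_control = np.asarray(phi_control, dtype=float)
    phi_experimental = np.asarray(phi_experimental, dtype=float)
    if phi_control.shape != phi_experimental.shape:
        raise DataError("Shapley vectors differ in length or shape")
    return np.abs(phi_control - phi_experimental)


def _resample_indices(
    n: int, n_control: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask (length n, True = pseudo-control) for one relabeling."""
    if mode == PERMUTE_LABELS:
        mask = np.zeros(n, dtype=bool)
        mask[rng.permutation(n)[:n_control]] = True
        return mask
    if mode == BOOTSTRAP_LABELS:
        p_ctrl = n_control / n
        for _ in range(_MAX_REJECTS):
            mask = rng.random(n) < p_ctrl
            if mask.sum() >= 2 and (~mask).sum() >= 1:
                return mask
        raise MicrogameError(
            f"bootstrap relabeling rejected {_MAX_REJECTS} consecutive "
            "degenerate draws (need >= 2 controls and >= 1 experimental)"
        )
    raise DataError(f"resampling_mode must be one of {_MODES}")


def resample_labels(
    labels: GroupLabels,
    mode: str = PERMUTE_LABELS,
    rng: np.random.Generator | None = None,
    sample_ids=None,
) -> GroupLabels:
    """Draw one random relabeling of the samples.

    ``permute_labels`` preserves the observed group sizes exactly;
    ``bootstrap_labels`` relabels samples independently with the observed
    control proportion, rejecting degenerate draws.
    """
    rng = np.random.default_rng() if rng is None else rng
    ids = list(sample_ids) if sample_ids is not None else list(labels.assignment)
    n_control = sum(1 for s in ids if labels.label_of(s) == CONTROL)
    mask = _resample_indices(len(ids), n_control, mode, rng)
    return GroupLabels(
        {s: (CONTROL if is_ctrl else EXPERIMENTAL) for s, is_ctrl in zip(ids, mask)}
    )


def _phi(bits: np.ndarray, col_idx: np.ndarray) -> np.ndarray:
    """Row means of the equal-split marginal matrix over selected columns."""
    sub = bits[:, col_idx]
    sizes = sub.sum(axis=0, dtype=float)
    np.maximum(sizes, 1.0, out=sizes)  # empty coalitions contribute 0 anyway
    return (sub / sizes).mean(axis=1)


def _adsv_under_mask(
    values: np.ndarray, ctrl_mask: np.ndarray, direction: str
) -> np.ndarray:
    """Recompute encoding + both condition games under a pseudo-labeling."""
    ctrl = values[:, ctrl_mask]
    mu = ctrl.mean(axis=1, keepdims=True)
    sd = ctrl.std(axis=1, ddof=1, keepdims=True)
    bits = (values >= mu + sd) if direction == OVER else (values <= mu - sd)
    bits = bits.astype(float)
    return np.abs(_phi(bits, np.flatnonzero(ctrl_mask))
                  - _phi(bits, np.flatnonzero(~ctrl_mask)))


def cash_pvalues(
    X: ExpressionMatrix,
    labels: GroupLabels,
    direction: str,
    config: CashConfig | None = None,
) -> GameComparison:
    """Observed ADSV plus CASh resampling p-values for one direction.

    Runs the full encode → split → Shapley pipeline on the observed
    labels, then ``config.n_resamples`` times under random relabelings,
    and returns a fully populated :class:`GameComparison` (threshold,
    p-values, optional BH adjustment, selection flags).
    """
    from .encoding import binarize, split_by_group
    from .game import shapley_values

    config = CashConfig() if config is None else config
    if direction not in DIRECTIONS:
        raise DataError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    labels.validate_against(X)

    B = binarize(X, labels, direction)
    B_ctrl, B_exp = split_by_group(B, labels)
    if B_exp.n_samples == 0:
        raise DataError("no experimental samples")
    phi_c = shapley_values(B_ctrl).phi
    phi_e = shapley_values(B_exp).phi
    observed = adsv(phi_c, phi_e)
    threshold = adsv_threshold(phi_c, phi_e)

    values = X.values
    ctrl_mask_obs = np.array(
        [labels.label_of(s) == CONTROL for s in X.sample_ids], dtype=bool
    )
    n = values.shape[1]
    n_control = int(ctrl_mask_obs.sum())
    fixed_bits = B.bits.astype(float) if not config.recompute_binarization else None

    counts = np.zeros(X.n_genes)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_resamples)
    for child in streams:
        rng = np.random.default_rng(child)
        mask = _resample_indices(n, n_control, config.resampling_mode, rng)
        if config.recompute_binarization:
            star = _adsv_under_mask(values, mask, direction)
        else:
            star = np.abs(_phi(fixed_bits, np.flatnonzero(mask))
                          - _phi(fixed_bits, np.flatnonzero(~mask)))
        counts += star >= observed - _TIE_EPS

    if config.add_one_correction:
        p = (1.0 + counts) / (config.n_resamples + 1.0)
    else:
        p = counts / config.n_resamples

    p_adjusted = None
    if config.adjust == ADJUST_BH:
        from statsmodels.stats.multitest import multipletests

        p_adjusted = multipletests(p, method="fdr_bh")[1]

    return GameComparison(
        direction=direction,
        gene_ids=X.gene_ids,
        phi_control=phi_c,
        phi_experimental=phi_e,
        adsv=observed,
        threshold=threshold,
        p=p,
        alpha=config.alpha,
        p_adjusted=p_adjusted,
    )
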