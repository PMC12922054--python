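"""Two-criterion candidate-gene selection.

A gene enters the candidate set of a direction's game when

* its CASh p-value is at most ``alpha``, and
* its ADSV is at least the magnitude threshold ``mean + sample SD``.

The threshold statistic is computed, by default, over the *pooled* 2n
per-gene Shapley values of the game (the n control-condition values and
the n experimental-condition values together, sample SD with divisor
``2n - 1``).  This pooled reading reproduces both reference thresholds of
the worked example (0.130 over, 0.181 under); the mean + SD of the ADSV
column itself — the other plausible reading — matches neither, but is
available as ``stat="adsv"``.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DataError, MicrogameError

__all__ = ["adsv_threshold", "select_candidates", "union_candidates"]

#: float-comparison guard for the inclusive >= boundary
_EPS = 1e-12


def adsv_threshold(
    phi_control: np.ndarray,
    phi_experimental: np.ndarray,
    stat: str = "pooled_shapley",
) -> float:
    """Mean + sample SD magnitude cutoff for the ADSV criterion.

    Parameters
    ----------
    phi_control, phi_experimental : arrays of per-gene Shapley values
        Same gene set and order.
    stat : {"pooled_shapley", "adsv"}
        ``pooled_shapley`` (default) pools the 2n Shapley values of the
        game; ``adsv`` applies mean + sample SD to the n ADSVs directly.
    """
    phi_control = np.asarray(phi_control, dtype=float)
    phi_experimental = np.asarray(phi_experimental, dtype=float)
    if phi_control.shape != phi_experimental.shape:
        raise DataError("control and experimental Shapley vectors differ in length")
    n = phi_control.size
    if n < 2:
        raise DataError("ADSV threshold undefined for fewer than 2 genes")
    if stat == "pooled_shapley":
        pooled = np.concatenate([phi_control, phi_experimental])
        return float(pooled.mean() + pooled.std(ddof=1))
    if stat == "adsv":
        adsv = np.abs(phi_control - phi_experimental)
        return float(adsv.mean() + adsv.std(ddof=1))
    raise MicrogameError(f"unknown threshold statistic {stat!r}")


def select_candidates(comparison, alpha: float | None = None) -> list[str]:
    """Genes passing both criteria, in input gene order.

    ``comparison`` must carry populated ``adsv``, ``p`` and ``threshold``
    fields.  ``alpha`` defaults to the comparison's own level.
    """
    if alpha is None:
        alpha = comparison.alpha
    if not 0.0 <= alpha <= 1.0:
        raise DataError(f"alpha must lie in [0, 1], got {alpha}")
    p = np.asarray(comparison.p, dtype=float)
    adsv = np.asarray(comparison.adsv, dtype=float)
    thr = float(comparison.threshold)
    keep = (p <= alpha + _EPS) & (adsv >= thr - _EPS)
    return [g for g, k in zip(comparison.gene_ids, keep) if k]


def union_candidates(comparisons, alpha: float | None = None) -> list[str]:
    """Union of per-direction candidate sets, ordered by first appearance
    in the (shared) gene ordering."""
    comparisons = list(comparisons)
    if not comparisons:
        return []
    chosen = set()
    for comp in comparisons:
        chosen.update(select_candidates(comp, alpha))
    gene_order = comparisons[0].gene_ids
    return [g for g in gene_order if g in chosen]
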