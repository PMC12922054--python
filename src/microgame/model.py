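"""Model/Results interface to the full workflow.

:class:`MicroarrayGame` bundles an expression matrix with its group
labels; :meth:`MicroarrayGame.fit` runs encoding, the per-condition
games, ADSV, CASh and selection for one or both directions and returns a
:class:`MicroarrayGameResults` carrying the estimates (Shapley vectors,
ADSV), their calibration (CASh p-values), the selection threshold and
the candidate set, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from .cash import CashConfig, GameComparison, cash_pvalues
from .encoding import OVER, UNDER, binarize, split_by_group
from .exceptions import DataError
from .io import ExpressionMatrix, GroupLabels, read_expression_matrix, read_group_labels
from .selection import union_candidates

__all__ = ["MicroarrayGame", "MicroarrayGameResults", "BOTH"]

BOTH = "both"


class MicroarrayGame:
    """Coalitional-game model of differential cooperation in expression data.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x samples normalized expression.
    labels : GroupLabels or mapping
        Control/experimental assignment covering every sample.

    Examples
    --------
    >>> from microgame import MicroarrayGame, table1_fixture
    >>> X, labels = table1_fixture()
    >>> res = MicroarrayGame(X, labels).fit(seed=1)
    >>> sorted(res.candidates)  # doctest: +SKIP
    ['gene7', 'gene8']
    """

    def __init__(self, expression: ExpressionMatrix, labels):
        if not isinstance(labels, GroupLabels):
            labels = GroupLabels(dict(labels))
        labels.validate_against(expression)
        self.expression = expression
        self.labels = labels

    @classmethod
    def from_dataframe(cls, df, labels) -> "MicroarrayGame":
        """Build from a pandas DataFrame (genes as index, samples as columns)."""
        return cls(ExpressionMatrix.from_dataframe(df), labels)

    @classmethod
    def from_files(
        cls, matrix_path, labels_source, delimiter: str | None = None
    ) -> "MicroarrayGame":
        """Build from an expression file and a labels file or token list."""
        return cls(
            read_expression_matrix(matrix_path, delimiter=delimiter),
            read_group_labels(labels_source),
        )

    def boolean_matrices(self, direction: str):
        """The direction's Boolean matrix and its (control, experimental) split."""
        B = binarize(self.expression, self.labels, direction)
        return B, *split_by_group(B, self.labels)

    def fit(
        self,
        direction: str = BOTH,
        n_resamples: int = 1000,
        alpha: float = 0.05,
        seed: int = 0,
        resampling_mode: str = "permute_labels",
        recompute_binarization: bool = True,
        add_one_correction: bool = False,
        adjust: str = "none",
    ) -> "MicroarrayGameResults":
        """Run the full pipeline and return the results object.

        ``direction`` is ``"over"``, ``"under"`` or ``"both"``; with
        ``"both"`` the two games are analyzed independently and the
        candidate set is their union.
        """
        if direction not in (OVER, UNDER, BOTH):
            raise DataError(f"direction must be 'over', 'under' or 'both', got {direction!r}")
        config = CashConfig(
            n_resamples=n_resamples,
            resampling_mode=resampling_mode,
            recompute_binarization=recompute_binarization,
            alpha=alpha,
            seed=seed,
            add_one_correction=add_one_correction,
            adjust=adjust,
        )
        directions = (OVER, UNDER) if direction == BOTH else (direction,)
        comparisons = {
            d: cash_pvalues(self.expression, self.labels, d, config) for d in directions
        }
        return MicroarrayGameResults(self, comparisons, config)


class MicroarrayGameResults:
    """Fitted results: per-direction game comparisons plus the candidate set."""

    def __init__(self, model: MicroarrayGame, comparisons: dict, config: CashConfig):
        self.model = model
        self.comparisons = comparisons
        self.config = config

    def comparison(self, direction: str) -> GameComparison:
        return self.comparisons[direction]

    @property
    def alpha(self) -> float:
        return self.config.alpha

    @property
    def candidates(self) -> list[str]:
        """Union of the per-direction candidate sets, in gene order."""
        return union_candidates(self.comparisons.values())

    def to_frame(self, direction: str):
        return self.comparisons[direction].to_frame()

    def summary(self, round_to: int = 3) -> str:
        """Plain-text summary table per direction plus the candidate set."""
        lines = ["Microarray game / CASh results", "=" * 31]
        lines.append(
            f"samples: {self.model.labels.n_control} control, "
            f"{self.model.labels.n_experimental} experimental; "
            f"B = {self.config.n_resamples} ({self.config.resampling_mode}), "
            f"alpha = {self.config.alpha}, seed = {self.config.seed}"
        )
        for d, comp in self.comparisons.items():
            lines.append("")
            lines.append(f"[{d}-expression game]  ADSV threshold (mean + SD of "
                         f"pooled Shapley values) = {round(comp.threshold, round_to)}")
            df = comp.to_frame().round(round_to)
            lines.append(df.to_string(index=False))
        lines.append("")
        cand = self.candidates
        lines.append(f"candidate genes (p <= {self.alpha} and ADSV >= threshold): "
                     + (", ".join(cand) if cand else "none"))
        return "\n".join(lines)

    def manifest(self) -> dict:
        """Reproducibility record: config plus package/library versions."""
        import microgame
        import numpy
        import pandas

        return {
            "config": asdict(self.config),
            "directions": list(self.comparisons),
            "n_genes": self.model.expression.n_genes,
            "n_samples": self.model.expression.n_samples,
            "versions": {
                "microgame": microgame.__version__,
                "numpy": numpy.__version__,
                "pandas": pandas.__version__,
            },
        }

    def plot_adsv(self, direction: str, ax=None):
        """Bar plot of per-gene ADSV with the selection threshold line."""
        import matplotlib.pyplot as plt

        comp = self.comparisons[direction]
        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, 0.5 * len(comp.gene_ids)), 3))
        x = np.arange(len(comp.gene_ids))
        colors = ["tab:red" if s else "tab:gray" for s in comp.selected]
        ax.bar(x, comp.adsv, color=colors)
        ax.axhline(comp.threshold, ls="--", color="k", lw=1,
                   label=f"threshold {comp.threshold:.3f}")
        ax.set_xticks(x, comp.gene_ids, rotation=90)
        ax.set_ylabel("ADSV")
        ax.set_title(f"{direction}-expression game")
        ax.legend(frameon=False)
        return ax
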