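"""In-memory containers for expression data, PO profiles and gradient traces.

Expression values are log2-scale intensities indexed by gene, with samples
identified by (stage, fraction, replicate). Polysome occupancy (PO) is the
log2 ratio of polysomal to total signal, i.e. a difference of log2 values,
indexed by (stage, replicate).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, PairingError

TOTAL = "T"
POLYSOMAL = "P"
FRACTIONS = (TOTAL, POLYSOMAL)

#: maturation (days after flowering) followed by germination (hours after
#: imbibition) stages, the 2x9x3 design the synthetic generator emulates.
DEFAULT_STAGES = (
    "12DAF", "15DAF", "18DAF", "20DAF",
    "0HAI", "6HAI", "26HAI", "48HAI", "72HAI",
)


def _sample_columns(stages, fraction, n_replicates) -> pd.MultiIndex:
    tuples = [
        (s, fraction, r)
        for s in stages
        for r in range(1, n_replicates + 1)
    ]
    return pd.MultiIndex.from_tuples(tuples, names=["stage", "fraction", "replicate"])


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities for one fraction (total or polysomal).

    ``data`` has the gene identifiers as index and a (stage, fraction,
    replicate) MultiIndex as columns; ``stage_order`` fixes the developmental
    ordering of the stage labels.
    """

    data: pd.DataFrame
    stage_order: tuple = DEFAULT_STAGES

    def __post_init__(self):
        self.stage_order = tuple(self.stage_order)
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.names != ["stage", "fraction", "replicate"]:
            raise FormatError("expression columns must be a (stage, fraction, replicate) MultiIndex")
        if cols.duplicated().any():
            raise FormatError("duplicate sample metadata in expression matrix")
        if self.data.index.duplicated().any():
            raise FormatError("duplicate gene identifiers in expression matrix")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise FormatError("expression matrix contains missing or non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def fraction(self) -> str:
        fractions = set(self.data.columns.get_level_values("fraction"))
        if len(fractions) != 1:
            raise FormatError(f"expected a single fraction, found {sorted(fractions)}")
        return fractions.pop()

    def stage_values(self, stage: str) -> pd.DataFrame:
        """Replicate columns for one stage."""
        return self.data.xs(stage, axis=1, level="stage")

    def subset(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[genes], self.stage_order)


@dataclass
class POProfile:
    """Genes x (stage, replicate) polysome-occupancy values, log2(P) - log2(T)."""

    data: pd.DataFrame
    stage_order: tuple = DEFAULT_STAGES

    def __post_init__(self):
        self.stage_order = tuple(self.stage_order)
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.names != ["stage", "replicate"]:
            raise FormatError("PO columns must be a (stage, replicate) MultiIndex")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise FormatError("PO profile contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def stage_means(self) -> pd.DataFrame:
        """Per-gene mean PO per stage, columns in developmental order."""
        means = self.data.T.groupby(level="stage").mean().T
        return means[[s for s in self.stage_order if s in means.columns]]

    def stage_values(self, stage: str) -> pd.DataFrame:
        return self.data.xs(stage, axis=1, level="stage")

    def sample_matrix(self) -> np.ndarray:
        """Genes x samples array with replicate columns in stage order."""
        ordered = [c for s in self.stage_order for c in self.data.columns if c[0] == s]
        return self.data[ordered].to_numpy()


@dataclass
class AbsorbanceTrace:
    """A254 absorbance along a sucrose-gradient coordinate."""

    positions: np.ndarray
    absorbance: np.ndarray
    regions: dict = field(default_factory=dict)  # name -> (lo, hi) positions

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.absorbance.shape:
            raise FormatError("trace positions and absorbance must be 1-D and equally long")
        if np.any(np.diff(self.positions) <= 0):
            raise FormatError("trace positions must be strictly increasing")
        if not np.isfinite(self.absorbance).all():
            raise FormatError("trace absorbance must be finite")


def check_matched_grids(total: ExpressionMatrix, polysomal: ExpressionMatrix) -> None:
    """Raise PairingError naming orphan samples when (stage, replicate) grids differ."""
    t = {(s, r) for s, _, r in total.data.columns}
    p = {(s, r) for s, _, r in polysomal.data.columns}
    if t != p:
        orphans = sorted(t.symmetric_difference(p))
        raise PairingError(f"unmatched (stage, replicate) samples: {orphans}")
    if not total.genes.equals(polysomal.genes):
        raise PairingError("total and polysomal matrices index different gene sets")
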