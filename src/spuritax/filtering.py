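"""Count-table filtering and normalization.

Two filtering strategies are provided: removal of singletons (taxa backed
by a single read across the whole dataset) and removal of taxa that never
exceed a relative-abundance cutoff in any sample (default 0.25%). The
cutoff is evaluated with a strict inequality (> cutoff) on the per-sample
proportions of the *unfiltered* table; retained taxa keep their raw
counts. Exact ties at the cutoff are removed — this keeps the
relative-abundance filter, the effective-richness statistic and the
"rescale to 1000 reads, drop below 2.5 counts" formulation mutually
consistent.

Normalization comes in two flavors: deterministic scaling of every sample
to the minimum sample sum (preserves proportions exactly) and stochastic
rarefaction (without-replacement subsampling to a fixed depth, seeded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_CUTOFF = 0.0025

FILTER_MODES = ("none", "singleton", "relative_abundance")


@dataclass(frozen=True)
class FilterSpec:
    """A filtering strategy: ``none``, ``singleton`` or ``relative_abundance``.

    ``cutoff`` is a fraction in [0, 1]; it is only consulted in
    ``relative_abundance`` mode (default 0.0025 = 0.25%).
    """

    mode: str = "relative_abundance"
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        if self.mode not in FILTER_MODES:
            raise ValidationError(f"unknown filter mode: {self.mode!r}")
        if not (0.0 <= self.cutoff <= 1.0):
            raise ValidationError(f"cutoff must be in [0, 1], got {self.cutoff}")

    def label(self) -> str:
        if self.mode == "relative_abundance":
            return f"relabund_{self.cutoff:g}"
        return self.mode


def _sample_sums(table: pd.DataFrame) -> pd.Series:
    sums = table.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ValidationError(f"sample(s) with zero total count: {zero}")
    return sums


def relative_abundances(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions p_ij = n_ij / sum_i n_ij (columns sum to 1)."""
    return table / _sample_sums(table)


def _require_integer_counts(table: pd.DataFrame, op: str) -> None:
    values = table.to_numpy()
    if not np.array_equal(values, np.rint(values)):
        raise ValidationError(f"{op} requires integer counts")


def filter_singletons(table: pd.DataFrame) -> pd.DataFrame:
    """Drop taxa whose total count across all samples equals exactly 1."""
    _require_integer_counts(table, "singleton filtering")
    totals = table.sum(axis=1)
    return table.loc[totals != 1]


def filter_relative_abundance(
    table: pd.DataFrame, spec: FilterSpec | float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Keep taxa whose relative abundance exceeds the cutoff in >=1 sample.

    Proportions are computed on the table as given (unfiltered); retained
    rows keep their original counts. ``spec`` may be a FilterSpec or a
    bare cutoff fraction.
    """
    cutoff = spec.cutoff if isinstance(spec, FilterSpec) else float(spec)
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError(f"cutoff must be in [0, 1], got {cutoff}")
    props = relative_abundances(table)
    keep = (props > cutoff).any(axis=1)
    return table.loc[keep]


def apply_filter(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Dispatch on FilterSpec.mode."""
    if spec.mode == "none":
        return table.copy()
    if spec.mode == "singleton":
        return filter_singletons(table)
    return filter_relative_abundance(table, spec)


def normalize_min_sum(table: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample to the minimum sample sum (proportions preserved)."""
    sums = _sample_sums(table)
    return table * (sums.min() / sums)


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Multivariate-hypergeometric draw per sample; reproducible given seed.
    """
    _require_integer_counts(table, "rarefaction")
    depth = int(depth)
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    counts = table.to_numpy().astype(np.int64)
    out = np.empty_like(counts)
    for j, sample in enumerate(table.columns):
        total = counts[:, j].sum()
        if depth > total:
            raise ValidationError(
                f"rarefaction depth {depth} exceeds sum {total} of sample {sample!r}"
            )
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return pd.DataFrame(out.astype(float), index=table.index, columns=table.columns)
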