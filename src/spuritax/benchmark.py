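"""Benchmarking of filtering strategies against reference communities.

Given a count table, a match table (true/spurious classification of every
taxon) and a filtering strategy, these routines quantify, per sample:

* how many retained taxa are spurious (and their cumulative relative
  abundance, on the unfiltered proportions);
* how many reference-community members are still detected ("positive
  hits") — counted as distinct members, so several observed taxa hitting
  the same member (satellites) cannot push the fraction above 100%;
* the relative abundance of the most abundant spurious taxon in the
  unfiltered sample ("first spurious abundance", the statistic used to
  pick a consensus filtering cutoff).

``threshold_sweep`` repeats the benchmark over a grid of
relative-abundance cutoffs (default 0 to 0.5% in 0.05% steps) across
several datasets and reports mean and SD per threshold.

All percentages are on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .filtering import FilterSpec, apply_filter, relative_abundances
from .matching import ReferenceCommunity

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 0.00501, 0.0005), 6))

RESULT_COLUMNS = (
    "n_taxa_total",
    "n_spurious",
    "spurious_fraction",
    "n_positive_hits",
    "positive_hit_fraction",
    "first_spurious_abundance",
    "cumulative_spurious_abundance",
    "matched_taxon_multiplicity",
)


def _check_matches(table: pd.DataFrame, matches: pd.DataFrame) -> None:
    missing = table.index.difference(matches.index)
    if len(missing):
        raise ValidationError(f"taxa missing from match table: {missing.tolist()[:5]}")


def first_spurious_abundance(
    table: pd.DataFrame, matches: pd.DataFrame, sample: str
) -> float | None:
    """Max per-sample relative abundance (percent) over spurious taxa.

    This is the abundance at which the first spurious taxon appears when
    scanning taxa in decreasing abundance; ``None`` if no spurious taxon
    has a nonzero count in the sample.
    """
    if sample not in table.columns:
        raise ValidationError(f"unknown sample: {sample!r}")
    _check_matches(table, matches)
    props = relative_abundances(table[[sample]])[sample]
    spurious = matches.loc[table.index, "status"] == "spurious"
    vals = props[spurious.to_numpy() & (props > 0).to_numpy()]
    if vals.empty:
        return None
    return 100.0 * float(vals.max())


def benchmark_sample(
    table: pd.DataFrame,
    matches: pd.DataFrame,
    spec: FilterSpec,
    reference: ReferenceCommunity | int,
) -> pd.DataFrame:
    """Apply ``spec`` and benchmark every sample of ``table``.

    ``reference`` supplies the member count for positive-hit fractions
    (a ReferenceCommunity or a bare member count). Returns one row per
    sample with the columns of RESULT_COLUMNS.
    """
    _check_matches(table, matches)
    n_members = reference if isinstance(reference, int) else len(reference.members)
    if n_members < 1:
        raise ValidationError("reference community must have at least one member")
    retained = apply_filter(table, spec)
    unfiltered_props = relative_abundances(table)
    status = matches.loc[retained.index, "status"]
    best_ref = matches.loc[retained.index, "best_reference"]
    rows = {}
    for sample in table.columns:
        present = retained[sample] > 0
        n_total = int(present.sum())
        spurious_mask = present & (status == "spurious").to_numpy()
        n_spurious = int(spurious_mask.sum())
        matched_mask = present & (status == "matched").to_numpy()
        hits = best_ref[matched_mask].dropna().unique()
        n_hits = len(hits)
        rows[sample] = {
            "n_taxa_total": n_total,
            "n_spurious": n_spurious,
            "spurious_fraction": 100.0 * n_spurious / n_total if n_total else np.nan,
            "n_positive_hits": n_hits,
            "positive_hit_fraction": 100.0 * n_hits / n_members,
            "first_spurious_abundance": first_spurious_abundance(table, matches, sample),
            "cumulative_spurious_abundance": 100.0
            * float(unfiltered_props.loc[spurious_mask[spurious_mask].index, sample].sum()),
            "matched_taxon_multiplicity": int(matched_mask.sum()) / n_hits
            if n_hits
            else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def summarize_benchmark(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Dataset-level mean +/- SD over replicate samples."""
    numeric = per_sample[list(RESULT_COLUMNS)].astype(float)
    return pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=1)})


@dataclass
class SweepCurve:
    """Mean/SD of spurious and positive-hit fractions per threshold."""

    thresholds: np.ndarray
    mean_spurious_fraction: np.ndarray
    sd_spurious_fraction: np.ndarray
    mean_positive_hit_fraction: np.ndarray
    sd_positive_hit_fraction: np.ndarray
    per_dataset: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "mean_spurious_fraction": self.mean_spurious_fraction,
                "sd_spurious_fraction": self.sd_spurious_fraction,
                "mean_positive_hit_fraction": self.mean_positive_hit_fraction,
                "sd_positive_hit_fraction": self.sd_positive_hit_fraction,
            }
        )


def threshold_sweep(datasets, thresholds=DEFAULT_THRESHOLDS) -> SweepCurve:
    """Benchmark every dataset at every relative-abundance threshold.

    ``datasets`` is a sequence of ``(table, matches, reference)`` triples;
    per dataset and threshold, the sample-level fractions are averaged,
    then mean and SD are taken across datasets.
    """
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValidationError("threshold list must not be empty")
    if np.any(np.diff(thresholds) <= 0):
        raise ValidationError("thresholds must be strictly increasing")
    datasets = list(datasets)
    if not datasets:
        raise ValidationError("at least one dataset is required")
    records = []
    for d_idx, (table, matches, reference) in enumerate(datasets):
        for t in thresholds:
            spec = FilterSpec(mode="relative_abundance", cutoff=float(t))
            res = benchmark_sample(table, matches, spec, reference)
            records.append(
                {
                    "dataset": d_idx,
                    "threshold": float(t),
                    "spurious_fraction": res["spurious_fraction"].mean(),
                    "positive_hit_fraction": res["positive_hit_fraction"].mean(),
                }
            )
    per_dataset = pd.DataFrame(records)
    grouped = per_dataset.groupby("threshold", sort=True)
    mean = grouped.mean()
    sd = grouped.std(ddof=1).fillna(0.0) if len(datasets) > 1 else grouped.mean() * 0.0
    return SweepCurve(
        thresholds=thresholds,
        mean_spurious_fraction=mean["spurious_fraction"].to_numpy(),
        sd_spurious_fraction=sd["spurious_fraction"].to_numpy(),
        mean_positive_hit_fraction=mean["positive_hit_fraction"].to_numpy(),
        sd_positive_hit_fraction=sd["positive_hit_fraction"].to_numpy(),
        per_dataset=per_dataset,
    )
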