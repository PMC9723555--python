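"""Prevalence and exclusivity of spurious taxa across sample categories and runs.

Given an occurrence map of spurious taxa over a large sample collection
(columns annotated with a category such as human/mouse/soil/freshwater/
marine), prevalence is the percentage of a category's samples in which a
taxon exceeds an abundance threshold (default 0.25% relative abundance).
Samples with no hit to any spurious taxon are dropped from denominators
by default, since an absence there cannot be distinguished from a primer
mismatch.

Exclusivity of a taxon for its top category is assessed with a pooled
two-proportion z-test of the top category against the runner-up
(two-sided), Benjamini-Hochberg adjusted across all tested taxa.

Run redundancy collapses the spurious sequences of several sequencing
runs at 97% identity and counts, per cluster, the number of distinct runs
contributing at least one member — the signature separating sporadic
cross-contamination (one run) from generalist artifacts (many runs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .errors import ValidationError
from .filtering import DEFAULT_CUTOFF, relative_abundances
from .matching import collapse_redundant

ALPHA = 0.05


def positive_counts(
    occurrence: pd.DataFrame,
    meta: pd.DataFrame,
    abundance_threshold: float = DEFAULT_CUTOFF,
    values: str = "proportions",
    drop_no_hit: bool = True,
):
    """Per taxon x category counts of positive samples and category totals.

    ``values`` is ``"proportions"`` if the occurrence map already stores
    relative abundances, or ``"counts"`` to convert per sample first.
    Returns (positives, totals): a taxa x categories frame and a
    per-category Series.
    """
    if values not in ("proportions", "counts"):
        raise ValidationError(f"unknown values kind: {values!r}")
    missing = [s for s in occurrence.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata category: {missing[:5]}")
    data = relative_abundances(occurrence) if values == "counts" else occurrence
    if drop_no_hit:
        has_hit = (data > 0).any(axis=0)
        data = data.loc[:, has_hit]
    if data.shape[1] == 0:
        raise ValidationError("no samples left after dropping no-hit samples")
    categories = meta.loc[data.columns, "category"]
    if (categories == "").any():
        raise ValidationError("samples with empty category label")
    positive = (data > abundance_threshold).T.groupby(categories.to_numpy()).sum().T
    totals = categories.value_counts()
    return positive, totals.loc[positive.columns]


def prevalence_by_category(
    occurrence: pd.DataFrame,
    meta: pd.DataFrame,
    abundance_threshold: float = DEFAULT_CUTOFF,
    values: str = "proportions",
    drop_no_hit: bool = True,
) -> pd.DataFrame:
    """Prevalence map: percent of category samples positive per taxon,
    the top category, and BH-adjusted exclusivity of top vs runner-up."""
    positive, totals = positive_counts(
        occurrence, meta, abundance_threshold, values, drop_no_hit
    )
    prevalence = 100.0 * positive / totals
    records = []
    pvals = []
    for taxon in prevalence.index:
        prev = prevalence.loc[taxon].sort_values(ascending=False)
        top, runner = prev.index[0], prev.index[1] if len(prev) > 1 else None
        if runner is None:
            raise ValidationError("exclusivity needs at least two categories")
        z, p = exclusivity_ztest(
            (int(positive.loc[taxon, top]), int(totals[top])),
            (int(positive.loc[taxon, runner]), int(totals[runner])),
        )
        records.append(
            {
                "taxon_id": taxon,
                "top_category": top,
                "top_prevalence": prev.iloc[0],
                "runner_up_category": runner,
                "runner_up_prevalence": prev.iloc[1],
                "z": z,
            }
        )
        pvals.append(p)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(records).set_index("taxon_id")
    out["exclusivity_p"] = p_adj
    out["exclusive"] = (out["exclusivity_p"] < ALPHA) & (
        out["top_prevalence"] > out["runner_up_prevalence"]
    )
    return prevalence.join(out, how="left")


def exclusivity_ztest(top: tuple, runner: tuple) -> tuple:
    """Pooled two-proportion z-test (two-sided) of (positives, total) pairs.

    Returns (z, p); z is signed top-minus-runner-up. Identical proportions
    give z = 0, p = 1.
    """
    (x1, n1), (x2, n2) = top, runner
    if n1 < 1 or n2 < 1:
        raise ValidationError("each category needs at least one sample")
    if x1 == 0 and x2 == 0:
        return 0.0, 1.0  # pooled variance degenerate; proportions identical
    if x1 == n1 and x2 == n2:
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def exclusivity_test(per_category: dict) -> tuple:
    """Exclusivity of the top-prevalence category against the runner-up.

    ``per_category`` maps category -> (positives, total). Categories with
    total 0 are excluded; fewer than two usable categories is an error.
    Returns (z, p_raw, exclusive_at_raw_alpha); for the BH-adjusted
    decision across many taxa use :func:`prevalence_by_category`.
    """
    usable = {c: (x, n) for c, (x, n) in per_category.items() if n >= 1}
    if len(usable) < 2:
        raise ValidationError("exclusivity test needs >= 2 categories with samples")
    ranked = sorted(usable.items(), key=lambda kv: (-kv[1][0] / kv[1][1], kv[0]))
    (_, top), (_, runner) = ranked[0], ranked[1]
    z, p = exclusivity_ztest(top, runner)
    exclusive = p < ALPHA and top[0] / top[1] > runner[0] / runner[1]
    return z, p, exclusive


def run_redundancy(per_run_sequences: dict, identity_threshold: float = 0.97) -> pd.Series:
    """Number of distinct runs contributing to each 97%-identity cluster.

    ``per_run_sequences`` maps run id -> SequenceSet of that run's
    spurious sequences. Sequence ids are namespaced by run before pooled
    clustering; the returned Series maps cluster id -> run count.
    """
    if not per_run_sequences or all(not s for s in per_run_sequences.values()):
        raise ValidationError("no spurious sequences supplied")
    pooled = {}
    origin = {}
    for run, seqs in per_run_sequences.items():
        for taxon, seq in seqs.items():
            key = f"{run}::{taxon}"
            pooled[key] = seq
            origin[key] = run
    clusters = collapse_redundant(pooled, identity_threshold)
    runs_per_cluster = (
        pd.Series({k: origin[k] for k in clusters.index}, name="run")
        .groupby(clusters["cluster_id"])
        .nunique()
    )
    runs_per_cluster.name = "n_runs"
    return runs_per_cluster


def redundancy_histogram(runs_per_cluster: pd.Series) -> pd.Series:
    """Histogram: number of clusters observed in exactly k runs."""
    hist = runs_per_cluster.value_counts().sort_index()
    hist.index.name = "n_runs"
    hist.name = "n_clusters"
    return hist
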