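"""Alpha-diversity, reproducibility statistics and phylogenetic beta-diversity.

Alpha-diversity per sample:

* richness — taxa with nonzero count;
* effective microbial richness (EMR) — taxa with relative abundance
  strictly above a cutoff (default 0.25%). EMR is invariant to rescaling
  the sample, hence to sequencing depth and normalization; it equals the
  count of taxa surviving rescaling to 1000 reads with removal of those
  below 2.5 rescaled counts;
* Shannon effective count — exp(H) with H the natural-log Shannon entropy
  of the sample's proportions (an evenness-aware effective species number).

Reproducibility: interquartile range of richness within a group (type-7
linear-interpolation quantiles) and coefficients of variation of richness
within and across sequencing runs (sample SD with n-1, as percent of the
mean; across-run CVs act on per-run replicate means).

Beta-diversity: unweighted UniFrac (presence/absence of branch
descendants) and generalized UniFrac with parameter alpha in [0, 1]
(alpha = 1 is weighted-normalized UniFrac; alpha = 0.5 the usual
compromise). Branch masses are computed per sample as the fraction of the
sample's reads descending from each branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .errors import ValidationError
from .filtering import DEFAULT_CUTOFF, relative_abundances

# ---------------------------------------------------------------------------
# alpha diversity


def richness(table: pd.DataFrame, sample: str) -> int:
    """Number of taxa with count > 0 in the sample."""
    if sample not in table.columns:
        raise ValidationError(f"unknown sample: {sample!r}")
    return int((table[sample] > 0).sum())


def effective_richness(
    table: pd.DataFrame, sample: str, emr_cutoff: float = DEFAULT_CUTOFF
) -> int:
    """Count of taxa with per-sample proportion strictly above the cutoff."""
    if sample not in table.columns:
        raise ValidationError(f"unknown sample: {sample!r}")
    col = table[sample]
    total = col.sum()
    if total <= 0:
        raise ValidationError(f"sample {sample!r} has zero total count")
    return int((col / total > emr_cutoff).sum())


def shannon_effective(table: pd.DataFrame, sample: str) -> float:
    """exp(Shannon entropy, natural log) of the sample's proportions."""
    if sample not in table.columns:
        raise ValidationError(f"unknown sample: {sample!r}")
    col = table[sample].to_numpy(dtype=float)
    total = col.sum()
    if total <= 0:
        raise ValidationError(f"sample {sample!r} has zero total count")
    p = col[col > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))


def diversity_profile(
    table: pd.DataFrame, emr_cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Richness, EMR and Shannon effective count for every sample."""
    rows = {
        s: {
            "richness": richness(table, s),
            "effective_richness": effective_richness(table, s, emr_cutoff),
            "shannon_effective": shannon_effective(table, s),
        }
        for s in table.columns
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# reproducibility


def richness_iqr(values) -> float:
    """Q3 - Q1 of a group of richness values (linear-interpolation quantiles)."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValidationError("IQR needs at least two values per group")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def richness_cv(values) -> float:
    """Coefficient of variation in percent (sample SD / mean * 100)."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValidationError("CV needs at least two values")
    mean = values.mean()
    if mean == 0:
        raise ValidationError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def cv_report(richness_values: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Within-run and across-run CVs of richness per replicate group.

    ``richness_values`` is indexed by sample id; ``meta`` supplies
    ``run_id`` and ``replicate_group``. Within-run CVs are computed over
    the replicates of a group inside each run; the across-run CV of a
    group is computed over its per-run replicate means.
    """
    missing = [s for s in richness_values.index if s not in meta.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing[:5]}")
    joined = pd.DataFrame(
        {
            "richness": richness_values,
            "run_id": meta.loc[richness_values.index, "run_id"],
            "replicate_group": meta.loc[richness_values.index, "replicate_group"],
        }
    )
    records = []
    for group, gdf in joined.groupby("replicate_group"):
        run_means = {}
        for run, rdf in gdf.groupby("run_id"):
            run_means[run] = rdf["richness"].mean()
            if len(rdf) >= 2:
                records.append(
                    {
                        "replicate_group": group,
                        "run_id": run,
                        "scope": "within_run",
                        "cv": richness_cv(rdf["richness"]),
                    }
                )
        if len(run_means) >= 2:
            records.append(
                {
                    "replicate_group": group,
                    "run_id": None,
                    "scope": "across_runs",
                    "cv": richness_cv(list(run_means.values())),
                }
            )
    if not records:
        raise ValidationError("no group had enough replicates for a CV")
    return pd.DataFrame(records)


def iqr_report(richness_values: pd.Series, meta: pd.DataFrame, by: str = "subject_id") -> pd.Series:
    """Per-group IQR of richness (groups with >= 2 samples)."""
    groups = meta.loc[richness_values.index, by]
    out = {}
    for group, vals in richness_values.groupby(groups):
        if len(vals) >= 2:
            out[group] = richness_iqr(vals)
    if not out:
        raise ValidationError(f"no {by} group had >= 2 samples")
    return pd.Series(out, name="iqr").rename_axis(by)


# ---------------------------------------------------------------------------
# UniFrac


@dataclass(frozen=True)
class DistanceSpec:
    """Beta-diversity metric choice: unweighted or generalized UniFrac."""

    metric: str = "generalized_unifrac"
    alpha: float = 0.5

    def __post_init__(self):
        if self.metric not in ("unweighted_unifrac", "generalized_unifrac"):
            raise ValidationError(f"unknown metric: {self.metric!r}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")


def _branch_masses(tree: skbio.TreeNode, table: pd.DataFrame):
    """Per-branch descendant mass for every sample.

    Returns (lengths, masses) where ``lengths`` is the branch length of
    every non-root node (postorder) and ``masses[b, j]`` is the fraction
    of sample j's reads descending from branch b.
    """
    props = relative_abundances(table).to_numpy()
    taxon_pos = {t: i for i, t in enumerate(table.index)}
    present = table.index[(table.to_numpy() > 0).any(axis=1)]
    tips = {tip.name for tip in tree.tips()}
    absent = [t for t in present if t not in tips]
    if absent:
        raise ValidationError(f"taxa with nonzero counts missing from tree: {absent[:5]}")
    n_samples = table.shape[1]
    lengths, masses = [], []
    node_mass: dict = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            idx = taxon_pos.get(node.name)
            mass = props[idx] if idx is not None else np.zeros(n_samples)
        else:
            mass = np.zeros(n_samples)
            for child in node.children:
                mass = mass + node_mass[id(child)]
        node_mass[id(node)] = mass
        if not node.is_root():
            lengths.append(node.length or 0.0)
            masses.append(mass)
    return np.asarray(lengths, dtype=float), np.asarray(masses, dtype=float)


def _unweighted_from_masses(lengths, pa, pb) -> float:
    in_a, in_b = pa > 0, pb > 0
    union = lengths[in_a | in_b].sum()
    if union == 0:
        raise ValidationError("no tree branch carries reads from either sample")
    unique = lengths[in_a ^ in_b].sum()
    return float(unique / union)


def _generalized_from_masses(lengths, pa, pb, alpha: float) -> float:
    total = pa + pb
    nz = total > 0
    if not nz.any():
        raise ValidationError("no tree branch carries reads from either sample")
    w = lengths[nz] * total[nz] ** alpha
    denom = w.sum()
    if denom == 0:
        raise ValidationError("generalized UniFrac denominator is zero")
    num = (w * np.abs(pa[nz] - pb[nz]) / total[nz]).sum()
    return float(num / denom)


def unweighted_unifrac(
    tree: skbio.TreeNode, table: pd.DataFrame, sample_a: str, sample_b: str
) -> float:
    """Fraction of covered branch length unique to one of the two samples."""
    for s in (sample_a, sample_b):
        if s not in table.columns:
            raise ValidationError(f"unknown sample: {s!r}")
    lengths, masses = _branch_masses(tree, table[[sample_a, sample_b]])
    return _unweighted_from_masses(lengths, masses[:, 0], masses[:, 1])


def generalized_unifrac(
    tree: skbio.TreeNode,
    table: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    alpha: float = 0.5,
) -> float:
    """Generalized UniFrac: branches weighted by (pA+pB)^alpha."""
    for s in (sample_a, sample_b):
        if s not in table.columns:
            raise ValidationError(f"unknown sample: {s!r}")
    lengths, masses = _branch_masses(tree, table[[sample_a, sample_b]])
    return _generalized_from_masses(lengths, masses[:, 0], masses[:, 1], alpha)


def distance_matrix(
    tree: skbio.TreeNode, table: pd.DataFrame, spec: DistanceSpec
) -> pd.DataFrame:
    """Symmetric pairwise distance matrix over all samples of the table."""
    if table.shape[1] < 2:
        raise ValidationError("distance matrix needs at least two samples")
    lengths, masses = _branch_masses(tree, table)
    samples = list(table.columns)
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if spec.metric == "unweighted_unifrac":
                d = _unweighted_from_masses(lengths, masses[:, i], masses[:, j])
            else:
                d = _generalized_from_masses(lengths, masses[:, i], masses[:, j], spec.alpha)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=samples, columns=samples)


def median_within_group_distance(
    dm: pd.DataFrame, meta: pd.DataFrame, by: str = "subject_id", consecutive: bool = False
) -> pd.Series:
    """Median within-group pairwise distance (e.g. per subject over time).

    With ``consecutive=True`` only pairs of adjacent timepoints (by the
    metadata ``timepoint`` ordering) are used; default is all within-group
    pairs.
    """
    groups = meta.loc[dm.index, by]
    out = {}
    for group, samples in dm.index.to_series().groupby(groups):
        ids = list(samples)
        if len(ids) < 2:
            continue
        if consecutive:
            ordered = sorted(ids, key=lambda s: meta.loc[s, "timepoint"])
            vals = [dm.loc[a, b] for a, b in zip(ordered, ordered[1:])]
        else:
            vals = [dm.loc[a, b] for k, a in enumerate(ids) for b in ids[k + 1 :]]
        out[group] = float(np.median(vals))
    if not out:
        raise ValidationError(f"no {by} group had >= 2 samples")
    return pd.Series(out, name="median_distance").rename_axis(by)
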