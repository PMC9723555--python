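"""Synthetic amplicon datasets with ground-truth true/spurious labels.

The generator emulates the statistical structure of reference-community
sequencing experiments:

* a defined community of ``n_true_taxa`` members with an even,
  log-distributed (successive 10-fold dilutions) or exponential
  rank-abundance profile;
* run-specific contaminant pools — each sequencing run carries its own
  pool of contaminant sequences, occasionally shared between runs
  (``pool_overlap_prob``), so most contaminants occur in one run only;
  per-sample presence is Bernoulli with a probability calibrated so the
  expected cumulative spurious relative abundance equals
  ``cumulative_spurious_target`` (default 1%); individual contaminant
  abundances are log-uniform within ``contaminant_abundance_range``
  (default 0.01%-0.2%, i.e. strictly below the 0.25% consensus cutoff);
* satellite taxa — low-abundance copies of true members carrying 1-3
  substitutions (sequencing-error variants that still match the
  reference at >97% identity);
* singleton artifacts — per-sample unique taxa injected with a total
  count of exactly 1;
* variable sequencing depth (truncated normal, floor 1000 reads).

Every random draw derives from one master seed through
``numpy.random.SeedSequence`` spawn keys, one stream per structural
element and per (run, group, replicate) sample, so adding samples or runs
never perturbs previously generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ValidationError
from .matching import ReferenceCommunity, pairwise_identity

BASES = np.array(list("ACGT"))

PROFILES = ("even", "log", "exponential")


@dataclass(frozen=True)
class SyntheticDesign:
    """Study conditions for the generator (defaults: an 8-member even mock
    sequenced in triplicate, one run)."""

    n_true_taxa: int = 8
    profile: str = "even"
    rank_ratio: float = 0.5  # geometric ratio for the exponential profile
    n_runs: int = 1
    n_replicate_groups: int = 1
    replicates_per_group: int = 3
    depth_mean: float = 25_000.0
    depth_sd: float = 7_000.0
    depth_floor: int = 1_000
    sequence_length: int = 250
    contaminant_pool_size: int = 32
    contaminant_abundance_range: tuple = (1e-4, 2e-3)
    pool_overlap_prob: float = 0.1
    cumulative_spurious_target: float = 0.01
    satellite_rate: float = 0.5  # expected satellites per true taxon
    satellite_abundance_range: tuple = (5e-5, 1.5e-3)
    satellite_substitutions: tuple = (1, 3)
    singleton_rate: float = 5.0  # expected singleton artifacts per sample
    group_profile_noise: float = 0.0  # lognormal sd of group-specific profiles
    seed: int = 0

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValidationError(f"unknown profile: {self.profile!r}")
        if not (0 < self.rank_ratio <= 1):
            raise ValidationError("rank_ratio must be in (0, 1]")
        if self.n_true_taxa < 1 or self.n_runs < 1:
            raise ValidationError("n_true_taxa and n_runs must be >= 1")
        if not (0 <= self.cumulative_spurious_target < 0.5):
            raise ValidationError("cumulative_spurious_target must be in [0, 0.5)")
        lo, hi = self.contaminant_abundance_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("contaminant abundance range must satisfy 0 < lo <= hi < 1")


def hard_case(design: SyntheticDesign) -> SyntheticDesign:
    """Variant where the largest contaminants reach 0.44% relative abundance
    (the outlier regime in which the 0.25% cutoff no longer removes
    everything)."""
    lo, _ = design.contaminant_abundance_range
    return replace(design, contaminant_abundance_range=(lo, 0.0044))


def fecal_study_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """Multi-run reproducibility design: replicate groups ("subjects")
    with exponential rank-abundance profiles re-sequenced in triplicate
    across several runs, each run with its own contaminant pool."""
    params = dict(
        n_true_taxa=40,
        profile="exponential",
        rank_ratio=0.85,
        n_runs=7,
        n_replicate_groups=6,
        replicates_per_group=3,
        group_profile_noise=0.3,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticDesign(**params)


# ---------------------------------------------------------------------------
# low-level helpers


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def mutate(sequence: str, n_substitutions: int, rng: np.random.Generator) -> str:
    """Introduce exactly n distinct substitutions (never silent)."""
    seq = list(sequence)
    positions = rng.choice(len(seq), size=n_substitutions, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def expected_profile(design: SyntheticDesign) -> np.ndarray:
    n = design.n_true_taxa
    if design.profile == "even":
        weights = np.ones(n)
    elif design.profile == "log":
        weights = 10.0 ** -np.arange(n, dtype=float)
    else:
        weights = design.rank_ratio ** np.arange(n, dtype=float)
    return weights / weights.sum()


def make_reference(design: SyntheticDesign) -> ReferenceCommunity:
    """Reference community with mutually <90%-identical member sequences."""
    rng = _rng(design.seed, 0, 0)
    members = {}
    ids = [f"ref{i + 1:02d}" for i in range(design.n_true_taxa)]
    for member_id in ids:
        while True:
            seq = random_sequence(rng, design.sequence_length)
            # dissimilar = no near-full-length high-identity alignment
            # (short overlap alignments can reach identity 1 at tiny coverage)
            if all(
                not (ident >= 0.90 and cov >= 0.90)
                for ident, cov in (
                    pairwise_identity(seq, other) for other in members.values()
                )
            ):
                members[member_id] = seq
                break
    profile = pd.Series(expected_profile(design), index=ids)
    return ReferenceCommunity(
        members=members, expected_profile=profile, distribution_label=design.profile
    )


def _contaminant_presence_prob(design: SyntheticDesign) -> float:
    lo, hi = design.contaminant_abundance_range
    mean_ab = (hi - lo) / np.log(hi / lo) if hi > lo else lo
    expected_total = design.contaminant_pool_size * mean_ab
    if expected_total <= 0:
        return 0.0
    return min(1.0, design.cumulative_spurious_target / expected_total)


def expected_spurious_abundance(design: SyntheticDesign) -> float:
    """Analytic expectation of the realized cumulative spurious relative
    abundance per sample (contaminants + singleton artifacts)."""
    lo, hi = design.contaminant_abundance_range
    mean_ab = (hi - lo) / np.log(hi / lo) if hi > lo else lo
    contaminant = (
        _contaminant_presence_prob(design) * design.contaminant_pool_size * mean_ab
    )
    singleton = design.singleton_rate / design.depth_mean
    return contaminant + singleton


# ---------------------------------------------------------------------------
# study simulation


@dataclass
class SyntheticStudy:
    """A complete simulated experiment.

    ``table`` spans all runs/groups/replicates over the union taxon space;
    per-run or per-group tables are column subsets via ``metadata``.
    """

    design: SyntheticDesign
    table: pd.DataFrame
    metadata: pd.DataFrame
    ground_truth: pd.DataFrame
    reference: ReferenceCommunity
    sequences: dict
    tree: TreeNode

    def per_run_tables(self) -> dict:
        out = {}
        for run, meta in self.metadata.groupby("run_id"):
            sub = self.table[meta.index]
            out[run] = sub.loc[(sub > 0).any(axis=1)]
        return out

    def spurious_sequences_by_run(self) -> dict:
        """Per run, the sequences of spurious taxa with nonzero counts."""
        spurious = self.ground_truth.index[
            self.ground_truth["label"].isin(["contaminant", "singleton_artifact"])
        ]
        out = {}
        for run, sub in self.per_run_tables().items():
            ids = [t for t in sub.index if t in set(spurious)]
            out[run] = {t: self.sequences[t] for t in ids}
        return out


def _build_contaminant_pools(design: SyntheticDesign):
    """Run-specific pools; sequences occasionally shared between runs."""
    rng = _rng(design.seed, 0, 1)
    library: list = []  # (taxon_id, sequence)
    pools = []
    counter = 0
    for run_idx in range(design.n_runs):
        pool_ids = []
        seen = set()
        for _ in range(design.contaminant_pool_size):
            if library and rng.random() < design.pool_overlap_prob:
                taxon_id, seq = library[rng.integers(len(library))]
                if taxon_id in seen:
                    continue  # a pool lists each contaminant once
            else:
                counter += 1
                taxon_id = f"cont{counter:04d}"
                seq = random_sequence(rng, design.sequence_length)
                library.append((taxon_id, seq))
            seen.add(taxon_id)
            pool_ids.append(taxon_id)
        lo, hi = design.contaminant_abundance_range
        abundances = _log_uniform(rng, lo, hi, size=len(pool_ids))
        pools.append({"ids": pool_ids, "abundances": abundances})
    sequences = dict(library)
    return pools, sequences


def _build_satellites(design: SyntheticDesign, reference: ReferenceCommunity):
    rng = _rng(design.seed, 0, 2)
    lo, hi = design.satellite_abundance_range
    smin, smax = design.satellite_substitutions
    ids, seqs, parents, abundances = [], {}, {}, []
    counter = 0
    for member_id in reference.member_ids:
        for _ in range(rng.poisson(design.satellite_rate)):
            counter += 1
            taxon_id = f"sat{counter:04d}"
            n_subs = int(rng.integers(smin, smax + 1))
            seqs[taxon_id] = mutate(reference.members[member_id], n_subs, rng)
            parents[taxon_id] = member_id
            ids.append(taxon_id)
            abundances.append(_log_uniform(rng, lo, hi))
    return ids, seqs, parents, np.asarray(abundances, dtype=float)


def _group_profiles(design: SyntheticDesign, base: np.ndarray) -> list:
    profiles = []
    for g in range(design.n_replicate_groups):
        rng = _rng(design.seed, 0, 4, g)
        if design.group_profile_noise > 0:
            perturbed = base * np.exp(
                rng.normal(0.0, design.group_profile_noise, size=base.size)
            )
            profiles.append(perturbed / perturbed.sum())
        else:
            profiles.append(base.copy())
    return profiles


def random_bifurcating_tree(taxa, seed: int, mean_branch_length: float = 0.1) -> TreeNode:
    """Random topology over the given leaves; exponential branch lengths."""
    rng = _rng(seed, 0, 3)
    nodes = [TreeNode(name=t, length=float(rng.exponential(mean_branch_length))) for t in taxa]
    if len(nodes) == 1:
        root = TreeNode(children=nodes)
        root.length = 0.0
        return root
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]])
        merged.length = float(rng.exponential(mean_branch_length))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = nodes[0]
    root.length = 0.0
    return root


def simulate_study(design: SyntheticDesign) -> SyntheticStudy:
    """Simulate the full multi-run study defined by ``design``."""
    reference = make_reference(design)
    base_profile = expected_profile(design)
    group_profiles = _group_profiles(design, base_profile)
    pools, contaminant_seqs = _build_contaminant_pools(design)
    sat_ids, sat_seqs, sat_parents, sat_abund = _build_satellites(design, reference)
    presence_prob = _contaminant_presence_prob(design)

    true_ids = [f"otu{i + 1:04d}" for i in range(design.n_true_taxa)]
    sequences = {t: reference.members[m] for t, m in zip(true_ids, reference.member_ids)}
    sequences.update({t: contaminant_seqs[t] for p in pools for t in p["ids"]})
    sequences.update(sat_seqs)

    labels = {t: ("true", None, m) for t, m in zip(true_ids, reference.member_ids)}
    for t in sat_ids:
        labels[t] = ("satellite", None, sat_parents[t])
    contaminant_first_run = {}
    for run_idx, pool in enumerate(pools):
        for t in pool["ids"]:
            contaminant_first_run.setdefault(t, f"run{run_idx + 1}")
    for t, run in contaminant_first_run.items():
        labels[t] = ("contaminant", run, None)

    columns = {}
    meta_rows = {}
    singleton_entries = []  # (taxon_id, sample_id, run)
    for run_idx in range(design.n_runs):
        run_id = f"run{run_idx + 1}"
        pool = pools[run_idx]
        for group_idx in range(design.n_replicate_groups):
            group_id = f"group{group_idx + 1}"
            profile = group_profiles[group_idx]
            for rep_idx in range(design.replicates_per_group):
                sample_id = f"{run_id}_{group_id}_rep{rep_idx + 1}"
                rng = _rng(design.seed, 1, run_idx, group_idx, rep_idx)
                depth = int(max(design.depth_floor, round(rng.normal(design.depth_mean, design.depth_sd))))
                present = rng.random(len(pool["ids"])) < presence_prob
                cont_ids = [t for t, keep in zip(pool["ids"], present) if keep]
                cont_ab = pool["abundances"][present]
                s_total = cont_ab.sum() + sat_abund.sum()
                if s_total >= 0.9:
                    raise ValidationError(
                        "inconsistent design: spurious mass would exceed 90% of a sample"
                    )
                ids = true_ids + cont_ids + sat_ids
                probs = np.concatenate(
                    [profile * (1.0 - s_total), cont_ab, sat_abund]
                )
                counts = rng.multinomial(depth, probs / probs.sum())
                col = dict(zip(ids, counts.astype(float)))
                for j in range(rng.poisson(design.singleton_rate)):
                    taxon_id = f"sgl_{sample_id}_{j + 1}"
                    sequences[taxon_id] = random_sequence(rng, design.sequence_length)
                    labels[taxon_id] = ("singleton_artifact", run_id, None)
                    col[taxon_id] = 1.0
                    singleton_entries.append(taxon_id)
                columns[sample_id] = col
                meta_rows[sample_id] = {
                    "run_id": run_id,
                    "subject_id": group_id,
                    "replicate_group": group_id,
                    "category": "synthetic",
                    "timepoint": rep_idx,
                }

    # deduplicate shared contaminants while preserving order, then satellites/singletons
    seen: set = set()
    ordered_taxa = []
    for t in true_ids + [t for p in pools for t in p["ids"]] + sat_ids + singleton_entries:
        if t not in seen:
            seen.add(t)
            ordered_taxa.append(t)

    table = pd.DataFrame(0.0, index=ordered_taxa, columns=list(columns))
    for sample_id, col in columns.items():
        for taxon_id, count in col.items():
            table.at[taxon_id, sample_id] = count
    table.index.name = "taxon_id"

    # pool members that were never realized in any sample are not observed
    # taxa; drop them so the study's taxon set equals what a pipeline sees
    observed = table.index[(table.to_numpy() > 0).any(axis=1)]
    table = table.loc[observed]
    ordered_taxa = list(observed)
    sequences = {t: sequences[t] for t in ordered_taxa}

    ground_truth = pd.DataFrame(
        {
            "label": [labels[t][0] for t in ordered_taxa],
            "source_run": [labels[t][1] for t in ordered_taxa],
            "parent_taxon": [labels[t][2] for t in ordered_taxa],
        },
        index=pd.Index(ordered_taxa, name="taxon_id"),
    )

    metadata = pd.DataFrame.from_dict(meta_rows, orient="index")
    metadata.index.name = "sample_id"

    tree = random_bifurcating_tree(ordered_taxa, design.seed)

    return SyntheticStudy(
        design=design,
        table=table,
        metadata=metadata,
        ground_truth=ground_truth,
        reference=reference,
        sequences=sequences,
        tree=tree,
    )


def simulate_dataset(design: SyntheticDesign):
    """Single-run convenience wrapper: returns (table, ground_truth,
    reference, sequences) for a one-run design, dropping taxa never seen."""
    study = simulate_study(replace(design, n_runs=1))
    seen = study.table.index[(study.table > 0).any(axis=1)]
    table = study.table.loc[seen]
    return table, study.ground_truth.loc[seen], study.reference, {
        t: study.sequences[t] for t in seen
    }
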