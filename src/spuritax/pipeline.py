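"""End-to-end experiments over synthetic or user-supplied data.

Three experiment designs are orchestrated here, each writing tidy TSV
reports plus a JSON provenance record (full configuration, seed, config
hash) sufficient to re-run bit-identically:

* threshold experiment — benchmark a reference-community dataset under a
  list of filtering strategies and sweep relative-abundance cutoffs;
* reproducibility experiment — within-run and across-run coefficients of
  variation of richness (and per-group IQRs) under each filtering
  strategy, for a multi-run design;
* beta-diversity experiment — UniFrac distance matrices under each
  filter x metric combination, with per-subject median distances.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import pandas as pd

from . import io as sio
from .benchmark import (
    DEFAULT_THRESHOLDS,
    benchmark_sample,
    summarize_benchmark,
    threshold_sweep,
)
from .diversity import (
    DistanceSpec,
    cv_report,
    distance_matrix,
    diversity_profile,
    iqr_report,
    median_within_group_distance,
)
from .errors import ConfigError
from .filtering import DEFAULT_CUTOFF, FilterSpec, apply_filter
from .matching import classify_by_identity, classify_by_label
from .simulate import SyntheticDesign, simulate_study

DEFAULT_FILTERS = (
    FilterSpec(mode="none"),
    FilterSpec(mode="singleton"),
    FilterSpec(mode="relative_abundance", cutoff=DEFAULT_CUTOFF),
)


@dataclass
class ExperimentConfig:
    design: SyntheticDesign
    filters: tuple = DEFAULT_FILTERS
    distance: DistanceSpec = dc_field(default_factory=DistanceSpec)
    emr_cutoff: float = DEFAULT_CUTOFF
    match_mode: str = "label"  # label | identity
    out_dir: str | Path | None = None

    def __post_init__(self):
        if not self.filters:
            raise ConfigError("at least one FilterSpec is required")
        if self.match_mode not in ("label", "identity"):
            raise ConfigError(f"unknown match mode: {self.match_mode!r}")


def load_config(path) -> ExperimentConfig:
    """Read an INI-style experiment configuration.

    Sections: ``[design]`` (SyntheticDesign fields), ``[experiment]``
    (filters = comma-separated ``none|singleton|relabund:<cutoff>``,
    metric, alpha, emr_cutoff, match_mode).
    """
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise ConfigError(f"config file not found: {path}")
    design_kwargs = {}
    if parser.has_section("design"):
        hints = SyntheticDesign.__dataclass_fields__
        for key, raw in parser.items("design"):
            if key not in hints:
                raise ConfigError(f"unknown design key: {key}")
            current = getattr(SyntheticDesign(), key)
            if isinstance(current, bool):
                design_kwargs[key] = parser.getboolean("design", key)
            elif isinstance(current, int):
                design_kwargs[key] = int(raw)
            elif isinstance(current, float):
                design_kwargs[key] = float(raw)
            elif isinstance(current, tuple):
                design_kwargs[key] = tuple(float(x) for x in raw.split(","))
            else:
                design_kwargs[key] = raw
    filters = []
    spec_text = parser.get("experiment", "filters", fallback="none,singleton,relabund:0.0025")
    for token in spec_text.split(","):
        token = token.strip()
        if token in ("none", "singleton"):
            filters.append(FilterSpec(mode=token))
        elif token.startswith("relabund"):
            cutoff = float(token.split(":")[1]) if ":" in token else DEFAULT_CUTOFF
            filters.append(FilterSpec(mode="relative_abundance", cutoff=cutoff))
        else:
            raise ConfigError(f"unknown filter token: {token!r}")
    distance = DistanceSpec(
        metric=parser.get("experiment", "metric", fallback="generalized_unifrac"),
        alpha=parser.getfloat("experiment", "alpha", fallback=0.5),
    )
    return ExperimentConfig(
        design=SyntheticDesign(**design_kwargs),
        filters=tuple(filters),
        distance=distance,
        emr_cutoff=parser.getfloat("experiment", "emr_cutoff", fallback=DEFAULT_CUTOFF),
        match_mode=parser.get("experiment", "match_mode", fallback="label"),
    )


def _provenance(config: ExperimentConfig) -> dict:
    payload = {
        "design": asdict(config.design),
        "filters": [asdict(f) for f in config.filters],
        "distance": asdict(config.distance),
        "emr_cutoff": config.emr_cutoff,
        "match_mode": config.match_mode,
        "seed": config.design.seed,
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload["config_sha256"] = digest
    return payload


def _write(frame: pd.DataFrame, out_dir, name: str) -> None:
    if out_dir is not None:
        frame.to_csv(Path(out_dir) / name, sep="\t")


def _prepare(config: ExperimentConfig):
    study = simulate_study(config.design)
    if config.match_mode == "label":
        matches = classify_by_label(study.ground_truth)
    else:
        matches = classify_by_identity(
            {t: study.sequences[t] for t in study.table.index}, study.reference
        )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "provenance.json", "w") as fh:
            json.dump(_provenance(config), fh, indent=2, default=str)
    return study, matches


def run_threshold_experiment(config: ExperimentConfig) -> dict:
    """Benchmark per filter plus a relative-abundance threshold sweep."""
    study, matches = _prepare(config)
    per_filter = {}
    for spec in config.filters:
        res = benchmark_sample(study.table, matches, spec, study.reference)
        per_filter[spec.label()] = res
        _write(res, config.out_dir, f"benchmark_{spec.label()}.tsv")
        _write(summarize_benchmark(res), config.out_dir, f"benchmark_{spec.label()}_summary.tsv")
    sweep = threshold_sweep([(study.table, matches, study.reference)], DEFAULT_THRESHOLDS)
    _write(sweep.to_frame().set_index("threshold"), config.out_dir, "sweep.tsv")
    first = per_filter[config.filters[0].label()]["first_spurious_abundance"]
    _write(first.to_frame(), config.out_dir, "first_spurious_abundance.tsv")
    return {"study": study, "matches": matches, "per_filter": per_filter, "sweep": sweep}


def run_reproducibility_experiment(config: ExperimentConfig) -> dict:
    """Within/across-run CVs of richness and per-group IQRs per filter."""
    study, matches = _prepare(config)
    results = {}
    for spec in config.filters:
        filtered = apply_filter(study.table, spec)
        profile = diversity_profile(filtered, config.emr_cutoff)
        cvs = cv_report(profile["richness"], study.metadata)
        iqrs = iqr_report(profile["richness"], study.metadata, by="replicate_group")
        results[spec.label()] = {"profile": profile, "cv": cvs, "iqr": iqrs}
        _write(profile, config.out_dir, f"alpha_{spec.label()}.tsv")
        _write(cvs, config.out_dir, f"cv_{spec.label()}.tsv")
        _write(iqrs.to_frame(), config.out_dir, f"iqr_{spec.label()}.tsv")
    return {"study": study, "matches": matches, "results": results}


def run_betadiv_experiment(config: ExperimentConfig) -> dict:
    """UniFrac distance matrices per filter x metric, plus subject medians."""
    study, _ = _prepare(config)
    results = {}
    for spec in config.filters:
        filtered = apply_filter(study.table, spec)
        dm = distance_matrix(study.tree, filtered, config.distance)
        medians = median_within_group_distance(dm, study.metadata, by="replicate_group")
        results[spec.label()] = {"distance_matrix": dm, "medians": medians}
        _write(dm, config.out_dir, f"distances_{config.distance.metric}_{spec.label()}.tsv")
        _write(medians.to_frame(), config.out_dir, f"medians_{spec.label()}.tsv")
    return {"study": study, "results": results}


def write_study(study, out_dir) -> None:
    """Write a synthetic study to disk (table, FASTA, tree, metadata,
    ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_count_table(study.table, out / "counts.tsv")
    sio.write_fasta(study.sequences, out / "sequences.fasta")
    sio.write_fasta(study.reference.members, out / "reference.fasta")
    sio.write_metadata(study.metadata, out / "metadata.tsv")
    sio.write_newick(study.tree, out / "tree.nwk")
    study.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t")
    if study.reference.expected_profile is not None:
        study.reference.expected_profile.rename("expected_abundance").to_csv(
            out / "expected_profile.tsv", sep="\t"
        )
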