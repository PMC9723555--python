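"""Classification of observed taxa as true (matched) or spurious.

Observed representative sequences are compared against the members of a
defined reference community (mock or gnotobiotic). Three criteria are
supported:

* identity/coverage — semi-global alignment of the query against each
  reference; a positive hit requires identity >= 97% and coverage >= 90%
  of the query (BLAST-like closed-reference matching, without e-values,
  which are meaningless against a handful of reference sequences);
* Hamming — for denoised sequence variants, a positive hit requires a
  Hamming distance <= 1 to an equal-length reference;
* label — ground-truth labels from the synthetic generator, which lets
  downstream benchmarking be tested independently of alignment.

Alignment scoring is match +1, mismatch -1, gap -2, with free end gaps on
both sequences. Identity is matches / alignment columns within the mutual
overlap (internal gaps count as mismatches); coverage is query residues
inside the overlap / query length, so a query that overhangs past an end
of the reference loses coverage, not identity. (When both sequences have
leftover tails on the same side the dynamic program aligns them
residue-to-residue — adjacent insertion+deletion columns are not
representable — and the tail is charged to identity instead.) N bases
count as mismatches. Best hits are ranked by identity*coverage (the
matched fraction of the query), then identity, coverage and lexicographic
member id, so results are deterministic and degenerate short-overlap
alignments cannot outrank full-length hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from Bio import Align

from .errors import ValidationError
from .io import validate_sequences

DEFAULT_MIN_IDENTITY = 0.97
DEFAULT_MIN_COVERAGE = 0.90
DEFAULT_MAX_HAMMING = 1

MATCH_COLUMNS = ("status", "best_reference", "identity", "coverage", "hamming")

#: ground-truth labels regarded as spurious under label-mode classification.
#: Satellites (few-substitution error variants) sit within 97% identity of
#: their parent reference and are therefore *matched* by the identity
#: criterion; label mode mirrors that.
SPURIOUS_LABELS = frozenset({"contaminant", "singleton_artifact"})


@dataclass
class ReferenceCommunity:
    """A defined community: member sequences plus an optional expected profile."""

    members: dict
    expected_profile: pd.Series | None = None
    distribution_label: str = "custom"

    def __post_init__(self):
        self.members = validate_sequences(self.members)
        if not self.members:
            raise ValidationError("reference community has no members")
        if self.expected_profile is not None:
            prof = pd.Series(self.expected_profile, dtype=float)
            if set(prof.index) != set(self.members):
                raise ValidationError("expected profile ids do not match members")
            if abs(prof.sum() - 1.0) > 1e-9:
                raise ValidationError("expected profile must sum to 1")
            self.expected_profile = prof

    @property
    def member_ids(self) -> list:
        return list(self.members)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    # free end gaps on both sequences: overhangs are unaligned, not penalized
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(query: str, reference: str) -> tuple:
    """Align ``query`` against ``reference``; return (identity, coverage).

    Identity and coverage are computed over the mutual overlap of the
    best-scoring alignment (first optimum if several tie).
    """
    if not query or not reference:
        raise ValidationError("cannot align empty sequences")
    query = query.upper()
    reference = reference.upper()
    aln = _ALIGNER.align(reference, query)[0]
    ref_row, qry_row = str(aln[0]), str(aln[1])
    # mutual overlap: first..last column where both rows carry a residue
    both = [i for i in range(len(qry_row)) if qry_row[i] != "-" and ref_row[i] != "-"]
    if not both:
        return 0.0, 0.0
    lo, hi = both[0], both[-1] + 1
    span = hi - lo
    matches = sum(
        1
        for i in range(lo, hi)
        if qry_row[i] == ref_row[i] and qry_row[i] != "-" and qry_row[i] != "N"
    )
    query_residues = sum(1 for i in range(lo, hi) if qry_row[i] != "-")
    identity = matches / span
    coverage = query_residues / len(query)
    return identity, coverage


def hamming_distance(a: str, b: str) -> float:
    """Hamming distance between equal-length sequences; inf if lengths differ."""
    if len(a) != len(b):
        return math.inf
    return float(sum(1 for x, y in zip(a, b) if x != y))


def _empty_match_table(index) -> pd.DataFrame:
    return pd.DataFrame(index=pd.Index(index, name="taxon_id"), columns=list(MATCH_COLUMNS))


def classify_by_identity(
    observed: dict,
    ref: ReferenceCommunity,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Assign each observed taxon its best reference; matched iff both criteria hold."""
    observed = validate_sequences(observed)
    if not observed:
        raise ValidationError("no observed sequences to classify")
    rows = []
    for taxon, seq in observed.items():
        best = None
        # best hit ranked by identity*coverage (fraction of the query that
        # matches), then identity, then coverage; a degenerate short-overlap
        # alignment at identity 1 must not outrank a full-length 98% hit.
        # sorted member order + strict improvement => lexicographic tie-break
        for member_id in sorted(ref.member_ids):
            ident, cov = pairwise_identity(seq, ref.members[member_id])
            key = (ident * cov, ident, cov)
            if best is None or key > best[0]:
                best = (key, ident, cov, member_id)
        _, ident, cov, member_id = best
        matched = ident >= min_identity and cov >= min_coverage
        rows.append(
            {
                "taxon_id": taxon,
                "status": "matched" if matched else "spurious",
                "best_reference": member_id if matched else None,
                "identity": ident,
                "coverage": cov,
                "hamming": np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def classify_by_hamming(
    observed: dict, ref: ReferenceCommunity, max_distance: int = DEFAULT_MAX_HAMMING
) -> pd.DataFrame:
    """Matched iff the minimum Hamming distance to an equal-length reference
    is <= max_distance; a query longer or shorter than every reference is
    spurious by the length-mismatch convention (distance = infinity)."""
    observed = validate_sequences(observed)
    if not observed:
        raise ValidationError("no observed sequences to classify")
    rows = []
    for taxon, seq in observed.items():
        best_d, best_member = math.inf, None
        for member_id in sorted(ref.member_ids):
            d = hamming_distance(seq, ref.members[member_id])
            if d < best_d:
                best_d, best_member = d, member_id
        matched = best_d <= max_distance
        rows.append(
            {
                "taxon_id": taxon,
                "status": "matched" if matched else "spurious",
                "best_reference": best_member if matched else None,
                "identity": np.nan,
                "coverage": np.nan,
                "hamming": best_d if math.isfinite(best_d) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def classify_by_label(ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Build a MatchTable directly from generator ground truth.

    ``ground_truth`` must have columns ``label`` and ``parent_taxon``
    (the reference member a true taxon or satellite derives from).
    """
    if "label" not in ground_truth.columns:
        raise ValidationError("ground truth must have a 'label' column")
    rows = []
    for taxon, row in ground_truth.iterrows():
        spurious = row["label"] in SPURIOUS_LABELS
        rows.append(
            {
                "taxon_id": taxon,
                "status": "spurious" if spurious else "matched",
                "best_reference": None if spurious else row.get("parent_taxon"),
                "identity": np.nan,
                "coverage": np.nan,
                "hamming": np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def collapse_redundant(seqs: dict, identity_threshold: float = 0.97) -> pd.DataFrame:
    """Greedy centroid clustering at a fixed identity threshold.

    Sequences are processed in decreasing length order (ties lexicographic
    by id); each joins the earliest-founded centroid reached at
    >= identity_threshold identity and >= 90% coverage, otherwise founds a
    new cluster. Returns a frame with columns ``cluster_id`` (the centroid
    taxon id) and ``is_centroid``.
    """
    seqs = validate_sequences(seqs)
    if not seqs:
        raise ValidationError("no sequences to cluster")
    order = sorted(seqs, key=lambda t: (-len(seqs[t]), t))
    centroids: list = []
    assignment = {}
    for taxon in order:
        home = None
        for centroid in centroids:
            ident, cov = pairwise_identity(seqs[taxon], seqs[centroid])
            if ident >= identity_threshold and cov >= DEFAULT_MIN_COVERAGE:
                home = centroid
                break
        if home is None:
            centroids.append(taxon)
            home = taxon
        assignment[taxon] = home
    return pd.DataFrame(
        {
            "cluster_id": [assignment[t] for t in seqs],
            "is_centroid": [assignment[t] == t for t in seqs],
        },
        index=pd.Index(list(seqs), name="taxon_id"),
    )
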