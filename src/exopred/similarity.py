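"""Global-alignment identity, dataset identity statistics, and
identity-threshold redundancy reduction.

Identity between two proteins is computed from a Needleman–Wunsch global
alignment (BLOSUM62, affine gaps, end gaps penalized) as

    identity% = 100 × identical columns / alignment length (gaps included),

the convention of EMBOSS needle's "Identity" line. Redundancy reduction is
greedy longest-first clustering under a percent-identity ceiling — exact
global identities rather than k-mer pre-filters, which is what the desk
scale of this package calls for.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ProteinRecord

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_MATRIX = "BLOSUM62"

#: full N×(N−1) summaries above this size need an explicit opt-in
LARGE_DATASET_LIMIT = 2000


class SimilarityError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    identity_percent: float
    aligned_length: int
    score: float


@dataclasses.dataclass(frozen=True)
class IdentitySummary:
    n_sequences: int
    n_alignments: int
    mean_identity: float
    sd_identity: float
    histogram: tuple[tuple[float, float, int], ...]  # (bin lo, bin hi, count)


def _make_aligner(gap_open: float, gap_extend: float, matrix_name: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    try:
        aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError:
        raise SimilarityError(f"unknown substitution matrix {matrix_name!r}") from None
    # first gap position costs open, each further position costs extend
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def global_identity(
    a: ProteinRecord,
    b: ProteinRecord,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    matrix_name: str = DEFAULT_MATRIX,
    _aligner: Optional[Align.PairwiseAligner] = None,
) -> AlignmentResult:
    """Percent identity of the optimal global alignment of two proteins."""
    if not a.sequence or not b.sequence:
        raise SimilarityError("cannot align empty sequences")
    aligner = _aligner or _make_aligner(gap_open, gap_extend, matrix_name)
    # co-optimal alignments can differ in identity; canonicalizing the input
    # order makes identity(a, b) == identity(b, a) hold exactly
    first, second = sorted((a, b), key=lambda r: (r.sequence, r.id))
    alignment = aligner.align(first.sequence, second.sequence)[0]
    counts = alignment.counts()
    length = alignment.length
    identity = 100.0 * counts.identities / length
    return AlignmentResult(
        query_id=a.id,
        subject_id=b.id,
        identity_percent=identity,
        aligned_length=length,
        score=float(alignment.score),
    )


def _pairwise_identities(
    records: Sequence[ProteinRecord],
    aligner: Align.PairwiseAligner,
) -> np.ndarray:
    """Upper-triangle identities of all unordered pairs, in (i<j) order."""
    out = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            out.append(
                global_identity(records[i], records[j], _aligner=aligner).identity_percent
            )
    return np.array(out)


def dataset_identity_summary(
    records: Sequence[ProteinRecord],
    subset_a: Optional[set[str]] = None,
    subset_b: Optional[set[str]] = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    matrix_name: str = DEFAULT_MATRIX,
    n_bins: int = 20,
    allow_large: bool = False,
    sample_pairs: Optional[int] = None,
    seed: int = 0,
) -> IdentitySummary:
    """Mean ± sd percent identity over all pairwise global alignments.

    Within-set mode (no subsets, or ``subset_a`` only) covers all ordered
    non-self pairs, N×(N−1) alignments; identity is symmetric so each
    unordered pair is aligned once and counted twice. Between-set mode
    (both subsets) covers the |A|×|B| cross pairs.

    Full quadratic summaries over more than ``LARGE_DATASET_LIMIT`` sequences
    require ``allow_large=True`` or a seeded uniform ``sample_pairs`` budget.
    """
    by_id = {r.id: r for r in records}
    if subset_a is not None and subset_b is not None:
        missing = (subset_a | subset_b) - set(by_id)
        if missing:
            raise SimilarityError(f"unknown ids in subsets: {sorted(missing)[:5]}")
        group_a = [by_id[i] for i in sorted(subset_a)]
        group_b = [by_id[i] for i in sorted(subset_b)]
        if not group_a or not group_b:
            raise SimilarityError("empty subset")
        between = True
    else:
        scope = records if subset_a is None else [by_id[i] for i in sorted(subset_a)]
        if len(scope) < 2:
            raise SimilarityError("need at least 2 sequences")
        between = False

    aligner = _make_aligner(gap_open, gap_extend, matrix_name)
    rng = np.random.default_rng(seed)

    if between:
        n_total = len(group_a) * len(group_b)
        pairs = [(a, b) for a in group_a for b in group_b]
        n_seq = len({r.id for r in group_a} | {r.id for r in group_b})
        if sample_pairs is not None and sample_pairs < len(pairs):
            idx = rng.choice(len(pairs), size=sample_pairs, replace=False)
            pairs = [pairs[i] for i in idx]
            n_total = len(pairs)
        elif len(group_a) + len(group_b) > LARGE_DATASET_LIMIT and not allow_large:
            raise SimilarityError(
                "large between-set summary: pass allow_large=True or sample_pairs"
            )
        identities = np.array(
            [global_identity(a, b, _aligner=aligner).identity_percent for a, b in pairs]
        )
    else:
        n = len(scope)
        n_total = n * (n - 1)
        if sample_pairs is not None:
            n_unordered = n * (n - 1) // 2
            budget = min(sample_pairs, n_unordered)
            flat = rng.choice(n_unordered, size=budget, replace=False)
            iu, ju = np.triu_indices(n, k=1)
            identities = np.array(
                [
                    global_identity(scope[iu[k]], scope[ju[k]], _aligner=aligner).identity_percent
                    for k in flat
                ]
            )
            n_total = budget
        else:
            if n > LARGE_DATASET_LIMIT and not allow_large:
                raise SimilarityError(
                    f"{n} sequences means {n_total} alignments: pass allow_large=True "
                    "or sample_pairs"
                )
            upper = _pairwise_identities(scope, aligner)
            # each unordered pair appears twice among the N×(N−1) ordered pairs
            identities = np.repeat(upper, 2)
        n_seq = n

    edges = np.linspace(0.0, 100.0, n_bins + 1)
    counts, _ = np.histogram(identities, bins=edges)
    histogram = tuple(
        (float(edges[i]), float(edges[i + 1]), int(counts[i])) for i in range(n_bins)
    )
    return IdentitySummary(
        n_sequences=n_seq,
        n_alignments=n_total,
        mean_identity=float(identities.mean()),
        sd_identity=float(identities.std(ddof=0)),
        histogram=histogram,
    )


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold_percent: float = 80.0,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    matrix_name: str = DEFAULT_MATRIX,
) -> tuple[list[ProteinRecord], dict[str, tuple[str, float]]]:
    """Greedy longest-first redundancy reduction.

    Records are visited by decreasing length (ties by id); each record joins
    the first retained representative with which its global identity exceeds
    the threshold, otherwise it founds a new cluster. Returns the retained
    records (in visitation order) and a map member_id -> (representative_id,
    identity%) for every removed record.
    """
    if not records:
        raise SimilarityError("empty input")
    if not 0.0 < identity_threshold_percent <= 100.0:
        raise SimilarityError("identity threshold must be in (0, 100]")
    aligner = _make_aligner(gap_open, gap_extend, matrix_name)
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    retained: list[ProteinRecord] = []
    cluster_map: dict[str, tuple[str, float]] = {}
    for rec in ordered:
        placed = False
        for rep in retained:
            ident = global_identity(rec, rep, _aligner=aligner).identity_percent
            if ident > identity_threshold_percent:
                cluster_map[rec.id] = (rep.id, ident)
                placed = True
                break
        if not placed:
            retained.append(rec)
    return retained, cluster_map


def write_cluster_map(
    cluster_map: dict[str, tuple[str, float]], path
) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\trepresentative_id\tidentity\n")
        for member in sorted(cluster_map):
            rep, ident = cluster_map[member]
            fh.write(f"{member}\t{rep}\t{ident:.2f}\n")
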