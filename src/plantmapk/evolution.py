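"""Distances, trees and molecular-evolution statistics.

This module houses the quantitative half of the analysis: p-distance
matrices under partial deletion, a neighbor-joining tree surrogate,
Tajima's three-sequence relative-rate test, Tajima's D for neutrality,
and a local-alignment duplication z-score against a composition-
preserving shuffled null.

Conventions
-----------
* p-distance: proportion of differing sites over columns surviving
  partial deletion (per-column coverage >= cutoff), with residual gaps
  skipped pairwise.
* Relative-rate test: complete deletion (any column containing a gap or
  'X' is dropped), then the chi-square X2 = (mA - mB)^2 / (mA + mB) with
  one degree of freedom; p = erfc(sqrt(X2 / 2)).
* Tajima's D follows the 1989 variance-coefficient chain (a1, a2, b1,
  b2, c1, c2, e1, e2); pi is the mean pairwise difference per site so
  the numerator is pi * n - S / a1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import erfc
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .constants import GAP, UNKNOWN_RESIDUE
from .core_io import AlignmentMatrix, ProteinRecord


class AnalysisError(ValueError):
    """Raised when an input cannot support the requested statistic."""


# ---------------------------------------------------------------------------
# distances


@dataclass
class PDistanceMatrix:
    labels: list[str]
    d: np.ndarray  # square, symmetric, zero diagonal
    sites_used: int

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def _surviving_columns(alignment: AlignmentMatrix, coverage_cutoff: float) -> np.ndarray:
    coverage = alignment.coverage_mask()
    return np.where(coverage >= coverage_cutoff - 1e-12)[0]


def pdistance_matrix(
    alignment: AlignmentMatrix, coverage_cutoff: float = 0.95
) -> PDistanceMatrix:
    """Pairwise p-distances after partial deletion of low-coverage columns."""
    if len(alignment) < 2:
        raise AnalysisError("p-distance requires at least two sequences")
    arr = alignment.as_array()
    cols = _surviving_columns(alignment, coverage_cutoff)
    sub = arr[:, cols]
    real = (sub != GAP) & (sub != UNKNOWN_RESIDUE)
    m = len(alignment)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both = real[i] & real[j]
            compared = int(both.sum())
            if compared == 0:
                raise AnalysisError(
                    f"no comparable sites for pair ({alignment.labels[i]!r}, "
                    f"{alignment.labels[j]!r})"
                )
            diffs = int((sub[i][both] != sub[j][both]).sum())
            d[i, j] = d[j, i] = diffs / compared
    return PDistanceMatrix(labels=alignment.labels, d=d, sites_used=len(cols))


@dataclass(frozen=True)
class DistanceSummary:
    mean: float
    se: float
    replicates: int


def overall_mean_distance(
    alignment: AlignmentMatrix,
    replicates: int = 2000,
    seed: Optional[int] = None,
    coverage_cutoff: float = 0.95,
) -> DistanceSummary:
    """Mean pairwise p-distance with a site-bootstrap standard error."""
    base = pdistance_matrix(alignment, coverage_cutoff)
    m = len(alignment)
    iu = np.triu_indices(m, k=1)
    mean = float(base.d[iu].mean())

    arr = alignment.as_array()[:, _surviving_columns(alignment, coverage_cutoff)]
    real = (arr != GAP) & (arr != UNKNOWN_RESIDUE)
    n_sites = arr.shape[1]
    rng = np.random.default_rng(seed)
    reps = np.empty(replicates)
    for r in range(replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        sub, subreal = arr[:, cols], real[:, cols]
        total, pairs = 0.0, 0
        for i in range(m):
            for j in range(i + 1, m):
                both = subreal[i] & subreal[j]
                compared = int(both.sum())
                if compared:
                    total += int((sub[i][both] != sub[j][both]).sum()) / compared
                    pairs += 1
        reps[r] = total / pairs if pairs else 0.0
    se = float(reps.std(ddof=1)) if replicates > 1 else 0.0
    return DistanceSummary(mean=mean, se=se, replicates=replicates)


# ---------------------------------------------------------------------------
# trees


def nj_tree(matrix: PDistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero."""
    if not np.allclose(matrix.d, matrix.d.T):
        raise AnalysisError("distance matrix is not symmetric")
    if len(matrix.labels) < 3:
        raise AnalysisError("neighbor joining requires at least three taxa")
    dm = _SkbioDM(matrix.d, ids=matrix.labels)
    return _skbio_nj(dm, neg_as_zero=True)


def assign_group_by_tree(
    tree: TreeNode, reference_labels: dict[str, str], k: int = 3
) -> dict[str, str]:
    """Classify unlabeled leaves by majority group of k nearest references.

    Distance is patristic (path length through the tree).  Ties in the
    majority vote yield "unresolved".
    """
    if not reference_labels:
        raise AnalysisError("no reference labels supplied")
    tips = [t.name for t in tree.tips()]
    missing = set(reference_labels) - set(tips)
    if missing:
        raise AnalysisError(f"reference labels not in tree: {sorted(missing)}")
    dm = tree.tip_tip_distances()
    out: dict[str, str] = {}
    refs = [t for t in tips if t in reference_labels]
    for tip in tips:
        if tip in reference_labels:
            continue
        dists = sorted(refs, key=lambda r: (dm[tip, r], r))
        nearest = dists[: min(k, len(dists))]
        votes: dict[str, int] = {}
        for r in nearest:
            votes[reference_labels[r]] = votes.get(reference_labels[r], 0) + 1
        best = max(votes.values())
        winners = [g for g, v in votes.items() if v == best]
        out[tip] = winners[0] if len(winners) == 1 else "unresolved"
    return out


# ---------------------------------------------------------------------------
# Tajima relative-rate test


@dataclass(frozen=True)
class RelativeRateResult:
    n_identical: int
    n_divergent_all: int
    mA: int
    mB: int
    mC: int
    x2: float
    p: float


def relative_rate_test(
    seq_a: str | ProteinRecord,
    seq_b: str | ProteinRecord,
    outgroup: str | ProteinRecord,
) -> RelativeRateResult:
    """Tajima's relative-rate test on three aligned sequences.

    Columns containing any gap or unknown are eliminated (complete
    deletion); the remaining columns are classified as identical in all
    three, unique to one sequence, or divergent in all three.
    """
    a = seq_a.sequence if isinstance(seq_a, ProteinRecord) else seq_a
    b = seq_b.sequence if isinstance(seq_b, ProteinRecord) else seq_b
    c = outgroup.sequence if isinstance(outgroup, ProteinRecord) else outgroup
    if not (len(a) == len(b) == len(c)):
        raise AnalysisError("relative-rate test requires three equal-length sequences")
    skip = set(GAP + UNKNOWN_RESIDUE)
    n_id = n_div = mA = mB = mC = 0
    for x, y, z in zip(a, b, c):
        if x in skip or y in skip or z in skip:
            continue
        if x == y == z:
            n_id += 1
        elif x != y and y != z and x != z:
            n_div += 1
        elif y == z:  # x differs
            mA += 1
        elif x == z:  # y differs
            mB += 1
        else:  # x == y, z differs
            mC += 1
    if mA + mB == 0:
        x2, p = 0.0, 1.0
    else:
        x2 = (mA - mB) ** 2 / (mA + mB)
        p = float(erfc(math.sqrt(x2 / 2.0)))
    return RelativeRateResult(
        n_identical=n_id, n_divergent_all=n_div, mA=mA, mB=mB, mC=mC, x2=x2, p=p
    )


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass(frozen=True)
class TajimaDResult:
    m: int  # number of sequences
    n: int  # sites analysed
    S: int  # segregating sites
    ps: float  # S / n
    theta: float  # ps / a1 (per site)
    pi: float  # mean pairwise diversity per site
    D: Optional[float]  # None when S == 0 (undefined)
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def _tajima_coefficients(m: int) -> tuple[float, ...]:
    a1 = sum(1.0 / i for i in range(1, m))
    a2 = sum(1.0 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m * m + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajima_d_from_counts(m: int, n: int, S: int, pi: float) -> TajimaDResult:
    """Tajima's D from summary counts (pi is the per-site diversity)."""
    if m < 4:
        raise AnalysisError("Tajima's D requires m >= 4 sequences")
    if not 0 <= S <= n:
        raise AnalysisError(f"segregating sites S={S} outside [0, n={n}]")
    a1, a2, b1, b2, c1, c2, e1, e2 = _tajima_coefficients(m)
    ps = S / n
    theta = ps / a1
    if S == 0:
        D = None
    else:
        D = (pi * n - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return TajimaDResult(
        m=m, n=n, S=S, ps=ps, theta=theta, pi=pi, D=D,
        a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
    )


def tajima_d(
    alignment: AlignmentMatrix, coverage_cutoff: float = 0.95
) -> TajimaDResult:
    """Tajima's D from an alignment, with 95 % partial deletion.

    S counts surviving columns with at least two residue states; pi is
    the mean over pairs of per-site difference fractions (residual gaps
    skipped pairwise) scaled to the surviving-column count.
    """
    m = len(alignment)
    if m < 4:
        raise AnalysisError("Tajima's D requires m >= 4 sequences")
    arr = alignment.as_array()
    cols = _surviving_columns(alignment, coverage_cutoff)
    sub = arr[:, cols]
    n = len(cols)
    if n == 0:
        raise AnalysisError("no columns survive partial deletion")
    real = (sub != GAP) & (sub != UNKNOWN_RESIDUE)

    S = 0
    for j in range(n):
        states = set(sub[real[:, j], j])
        if len(states) >= 2:
            S += 1

    total_diffs = 0.0
    pairs = 0
    for i in range(m):
        for j in range(i + 1, m):
            both = real[i] & real[j]
            compared = int(both.sum())
            if compared == 0:
                continue
            diffs = int((sub[i][both] != sub[j][both]).sum())
            total_diffs += diffs * (n / compared)  # rescale to surviving length
            pairs += 1
    if pairs == 0:
        raise AnalysisError("no comparable pairs for diversity")
    pi = (total_diffs / pairs) / n
    return tajima_d_from_counts(m, n, S, pi)


# ---------------------------------------------------------------------------
# duplication z-score


@dataclass(frozen=True)
class DuplicationResult:
    gene_id: str
    best_partner: str
    observed_score: float
    null_mean: float
    null_sd: float
    z: float
    verdict: str  # duplicated | not-duplicated


DUPLICATION_Z_THRESHOLD = 4.0


def _local_aligner():
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner(scoring="blastp")  # BLOSUM62, affine gaps
    aligner.mode = "local"
    return aligner


def duplication_zscore(
    gene: ProteinRecord,
    proteome: Sequence[ProteinRecord],
    n_null: int = 200,
    seed: Optional[int] = None,
) -> DuplicationResult:
    """Duplication call: best local-alignment score vs a shuffled null.

    The observed score is the best local-alignment score of ``gene``
    against every other proteome member.  The null distribution scores
    ``gene`` against composition-preserving shuffles of those members
    (each replicate shuffles every partner and keeps the best score);
    z = (observed - null mean) / null sd, duplicated when z >= 4.
    """
    others = [r for r in proteome if r.id != gene.id]
    if not others:
        raise AnalysisError("duplication z-score requires a proteome with >= 2 members")
    aligner = _local_aligner()
    scores = [(float(aligner.score(gene.sequence, r.sequence)), r.id) for r in others]
    observed, best_partner = max(scores)

    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    seqs = [np.array(list(r.sequence)) for r in others]
    for i in range(n_null):
        best = -math.inf
        for s in seqs:
            shuffled = "".join(rng.permutation(s))
            best = max(best, float(aligner.score(gene.sequence, shuffled)))
        null[i] = best
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0:
        raise AnalysisError("degenerate null: shuffled-score variance is zero")
    z = (observed - null_mean) / null_sd
    verdict = "duplicated" if z >= DUPLICATION_Z_THRESHOLD else "not-duplicated"
    return DuplicationResult(
        gene_id=gene.id,
        best_partner=best_partner,
        observed_score=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        verdict=verdict,
    )
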