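"""Orthology-based naming of MAPKs.

Each accepted query inherits the ortholog number of its most similar
reference (rice-style numbering for monocots, Arabidopsis-style for
everything else); queries of one species sharing a number become
hyphen-suffixed paralogs ranked by similarity.  Similarity is the global
alignment score (BLOSUM62, affine gaps) normalised by the query's
self-score, a deterministic offline surrogate for reciprocal BLASTP
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import ProteinRecord


class NomenclatureError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceSet:
    """Named reference MAPKs: record id -> ortholog number."""

    records: tuple[ProteinRecord, ...]
    numbers: dict[str, int] = field(default_factory=dict)
    lineage: str = "other"  # "monocot" (rice-style) or "other"

    def __post_init__(self) -> None:
        if not self.records:
            raise NomenclatureError("empty reference set")
        missing = [r.id for r in self.records if r.id not in self.numbers]
        if missing:
            raise NomenclatureError(f"references without ortholog numbers: {missing}")
        if len(set(self.numbers.values())) != len(self.numbers):
            raise NomenclatureError("ortholog numbers must be unique within a reference set")


@dataclass(frozen=True)
class NomenclatureAssignment:
    query_id: str
    species_prefix: str
    ortholog_number: int
    paralog_rank: Optional[int]
    final_name: str
    best_reference: str
    similarity: float


def species_prefix(
    genus: str,
    species_epithet: str,
    taken_prefixes: set[str] | None = None,
    override: Optional[str] = None,
) -> str:
    """Genus initial plus the shortest epithet prefix unique among taken ones.

    An explicit override wins outright, reproducing irregular published
    abbreviations (e.g. Crein, Csub, Pper).
    """
    if not genus or not species_epithet:
        raise NomenclatureError("genus and species epithet must be non-empty")
    taken = taken_prefixes or set()
    if override is not None:
        if override in taken:
            raise NomenclatureError(f"override prefix {override!r} already taken")
        return override
    initial = genus[0].upper()
    epithet = species_epithet.lower()
    for k in range(1, len(epithet) + 1):
        candidate = initial + epithet[:k]
        if candidate not in taken:
            return candidate
    raise NomenclatureError(
        f"cannot build a unique prefix for {genus} {species_epithet} "
        f"(all candidates taken)"
    )


def _global_aligner():
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner(scoring="blastp")
    aligner.mode = "global"
    return aligner


def similarity_score(query: ProteinRecord, reference: ProteinRecord, aligner=None) -> float:
    """Global alignment score normalised by the query self-score."""
    aligner = aligner or _global_aligner()
    self_score = float(aligner.score(query.sequence, query.sequence))
    return float(aligner.score(query.sequence, reference.sequence)) / self_score


def assign_names(
    queries: Sequence[ProteinRecord],
    reference_set: ReferenceSet,
    prefix: str,
) -> list[NomenclatureAssignment]:
    """Name queries of one species against a reference set.

    Score ties break by reference ortholog number (ascending); paralog
    ranks break similarity ties by query id, so re-runs are stable.
    """
    if not queries:
        return []
    aligner = _global_aligner()
    best: dict[str, tuple[int, str, float]] = {}
    for q in queries:
        scored = []
        for ref in reference_set.records:
            s = similarity_score(q, ref, aligner)
            scored.append((-s, reference_set.numbers[ref.id], ref.id, s))
        scored.sort()
        _, number, ref_id, sim = scored[0]
        best[q.id] = (number, ref_id, sim)

    by_number: dict[int, list[ProteinRecord]] = {}
    for q in queries:
        by_number.setdefault(best[q.id][0], []).append(q)

    out = []
    for number, members in sorted(by_number.items()):
        members = sorted(members, key=lambda q: (-best[q.id][2], q.id))
        lone = len(members) == 1
        for rank, q in enumerate(members, start=1):
            _, ref_id, sim = best[q.id]
            name = f"{prefix}MPK{number}" + ("" if lone else f"-{rank}")
            out.append(
                NomenclatureAssignment(
                    query_id=q.id,
                    species_prefix=prefix,
                    ortholog_number=number,
                    paralog_rank=None if lone else rank,
                    final_name=name,
                    best_reference=ref_id,
                    similarity=sim,
                )
            )
    out.sort(key=lambda a: a.query_id)
    return out


def names_table(assignments: list[NomenclatureAssignment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "final_name": a.final_name,
                "best_reference": a.best_reference,
                "similarity": round(a.similarity, 6),
            }
            for a in assignments
        ],
        columns=["query_id", "final_name", "best_reference", "similarity"],
    )
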