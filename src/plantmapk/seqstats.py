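"""Protein physicochemistry and gene-structure statistics.

Molecular weights use average residue masses (proteomics summary
convention).  The isoelectric point is the pH at which the
Henderson-Hasselbalch net charge over the termini and the K/R/H (basic)
and D/E/C/Y (acidic) side chains vanishes, found by bisection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .constants import (
    ACIDIC_RESIDUES,
    AMINO_ACIDS,
    BASIC_RESIDUES,
    DEFAULT_PKA,
    RESIDUE_MASS,
    UNKNOWN_RESIDUE,
    WATER_MASS,
)
from .core_io import GeneModel, ProteinRecord


@dataclass(frozen=True)
class ProteinStats:
    record_id: str
    mw_da: float
    pi: float
    composition: dict[str, float]


@dataclass(frozen=True)
class GeneStats:
    gene_id: str
    orf_length_nt: int
    intron_count: int
    intron_bin: str
    group_d_range: bool  # 7-14 introns, the range typical of group D genes


def molecular_weight(sequence: str, allow_unknown: bool = False) -> float:
    """Average molecular mass in Daltons: residue masses plus one water."""
    total = WATER_MASS
    for ch in sequence:
        if ch == UNKNOWN_RESIDUE:
            if not allow_unknown:
                raise ValueError("sequence contains 'X'; pass allow_unknown=True to treat as mass 0")
            continue
        try:
            total += RESIDUE_MASS[ch]
        except KeyError:
            raise ValueError(f"invalid residue {ch!r}") from None
    return total


def net_charge(sequence: str, ph: float, pka: dict[str, float] | None = None) -> float:
    """Net charge Q(pH) over termini and ionisable side chains."""
    pka = pka or DEFAULT_PKA
    counts = Counter(sequence)
    q = 1.0 / (1.0 + 10 ** (ph - pka["nterm"]))
    q -= 1.0 / (1.0 + 10 ** (pka["cterm"] - ph))
    for res in BASIC_RESIDUES:
        q += counts[res] / (1.0 + 10 ** (ph - pka[res]))
    for res in ACIDIC_RESIDUES:
        q -= counts[res] / (1.0 + 10 ** (pka[res] - ph))
    return q


def isoelectric_point(
    sequence: str,
    pka: dict[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def aa_composition(sequence: str) -> dict[str, float]:
    """Residue -> percentage over the 20 standard residues ('X' ignored)."""
    if not sequence:
        raise ValueError("empty sequence")
    counted = [ch for ch in sequence if ch != UNKNOWN_RESIDUE]
    n = len(counted)
    counts = Counter(counted)
    return {aa: 100.0 * counts[aa] / n for aa in AMINO_ACIDS}


def protein_stats(record: ProteinRecord, allow_unknown: bool = True) -> ProteinStats:
    return ProteinStats(
        record_id=record.id,
        mw_da=molecular_weight(record.sequence, allow_unknown=allow_unknown),
        pi=isoelectric_point(record.sequence),
        composition=aa_composition(record.sequence),
    )


def intron_bin_label(count: int) -> str:
    if count == 0:
        return "intronless"
    if count == 1:
        return "single intron"
    return f"{count} introns"


def gene_structure_stats(models: list[GeneModel]) -> tuple[list[GeneStats], dict[int, int]]:
    """Per-gene intron statistics and a histogram of intron counts."""
    stats = []
    histogram: dict[int, int] = {}
    for model in models:
        c = model.intron_count
        histogram[c] = histogram.get(c, 0) + 1
        stats.append(
            GeneStats(
                gene_id=model.gene_id,
                orf_length_nt=model.orf_length_nt,
                intron_count=c,
                intron_bin=intron_bin_label(c),
                group_d_range=7 <= c <= 14,
            )
        )
    return stats, dict(sorted(histogram.items()))


def stats_table(stats: list[ProteinStats]):
    """Summary DataFrame: id, MW, pI and the three most abundant residues."""
    import pandas as pd

    rows = []
    for s in stats:
        top3 = sorted(s.composition.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
        rows.append(
            {
                "record_id": s.record_id,
                "mw_da": round(s.mw_da, 4),
                "pi": round(s.pi, 2),
                "top_residues": ",".join(f"{aa}:{pct:.2f}" for aa, pct in top3),
            }
        )
    return pd.DataFrame(rows, columns=["record_id", "mw_da", "pi", "top_residues"])
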