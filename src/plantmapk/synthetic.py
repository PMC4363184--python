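"""Synthetic MAPK-like data with planted ground truth.

Every generator is a pure function of its configuration and RNG, so a
fixed seed reproduces outputs byte for byte.  Proteins are assembled
from the real consensus architecture — N-terminal motif block, the nine
N-terminal signature anchors in canonical order, an activation loop
carrying a planted variant, the T-R-W-Y-R-A-P-E-L anchor, the two
post-loop consensuses, a group-specific common-docking site and a tail —
with random spacers between anchors.  The planted attributes of every
sequence (group, loop variant, verdict, ortholog label, intron count,
duplication status) are recorded in a TruthRecord, the oracle for every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .constants import AMINO_ACIDS, GROUP_LOOP_VARIANTS, LOOP_VARIANTS
from .core_io import AlignmentMatrix, GeneModel, ProteinRecord, write_fasta
from .motifs import Alternative, ConsensusPattern, Residue, Wildcard, default_library
from .nomenclature import ReferenceSet

#: Spacer alphabet for the activation-loop region: excludes Y/M/C so no
#: *recognised* loop variant can arise downstream of the planted one.
_LOOP_SAFE = "".join(ch for ch in AMINO_ACIDS if ch not in "YMC")

#: Intron-count distribution of the published census (589 genes):
#: intronless 7, single 41, two 39, three 18, four 15, five 161, six 32,
#: seven 20, eight 39, nine 126, ten 72, eleven 18, fourteen 1.
INTRON_COUNT_WEIGHTS = {
    0: 7, 1: 41, 2: 39, 3: 18, 4: 15, 5: 161, 6: 32,
    7: 20, 8: 39, 9: 126, 10: 72, 11: 18, 14: 1,
}

#: Published group sizes (A..F) used as default mixture weights.
GROUP_WEIGHTS = {"A": 89, "B": 128, "C": 100, "D": 258, "E": 10, "F": 4}

#: Post-loop C-terminal motifs safe to plant inside the inter-anchor
#: region (none is itself a recognised loop variant).
_POSTLOOP_BY_GROUP = {
    "A": ("SDY", "SEY"),
    "B": ("SDY", "SEY"),
    "C": ("DNY", "SQY"),
    "D": ("SKY", "SRY", "SNY"),
    "E": ("SEY",),
    "F": ("SEY",),
}

_NTERM_SECONDARY_D = ("SQY", "NRY", "SRY")
_NTERM_TXY_D = ("TEY", "TDY", "SEY", "SDY")


@dataclass(frozen=True)
class TruthRecord:
    record_id: str
    verdict: str  # MAPK | MAPK-like | rejected
    planted_group: str  # A..F or ""
    loop_variant: str  # variant or ""
    ortholog_label: str = ""
    paralog_of: Optional[str] = None
    mutation_rate: float = 0.0
    intron_count: int = 0
    duplicated: bool = False


@dataclass
class GeneratorConfig:
    seed: int
    n_sequences: int = 50
    mutation_rate: float = 0.0
    group_weights: dict[str, float] = field(default_factory=lambda: dict(GROUP_WEIGHTS))
    #: weight of the canonical variant within each group; the remainder is
    #: split over that group's novel variants (the published novel motifs
    #: are rare, one to a few genes each).
    canonical_variant_weight: float = 0.9
    fraction_mapk_like: float = 0.1
    fraction_random_decoy: float = 0.1
    fraction_paralog: float = 0.2
    intron_weights: dict[int, float] = field(
        default_factory=lambda: dict(INTRON_COUNT_WEIGHTS)
    )
    background_freqs: Optional[dict[str, float]] = None  # None -> uniform
    protect_motifs: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must lie in [0, 0.5]")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in {"seed", "n_sequences"}:
                kwargs[key] = int(value)
            elif key in {
                "mutation_rate",
                "canonical_variant_weight",
                "fraction_mapk_like",
                "fraction_random_decoy",
                "fraction_paralog",
            }:
                kwargs[key] = float(value)
            elif key == "protect_motifs":
                kwargs[key] = value.lower() in {"1", "true", "yes", "on"}
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class Proteome:
    records: list[ProteinRecord]
    models: list[GeneModel]
    truth: dict[str, TruthRecord]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "proteome.fasta"
        gff3 = out_dir / "genes.gff3"
        truth = out_dir / "truth.tsv"
        write_fasta(self.records, fasta)
        write_gff3(self.models, gff3)
        with open(truth, "w") as fh:
            fh.write(
                "record_id\tverdict\tplanted_group\tloop_variant\tortholog_label\t"
                "paralog_of\tmutation_rate\tintron_count\tduplicated\n"
            )
            for rec in self.records:
                t = self.truth[rec.id]
                fh.write(
                    f"{t.record_id}\t{t.verdict}\t{t.planted_group}\t{t.loop_variant}\t"
                    f"{t.ortholog_label}\t{t.paralog_of or ''}\t{t.mutation_rate}\t"
                    f"{t.intron_count}\t{int(t.duplicated)}\n"
                )
        return {"fasta": fasta, "gff3": gff3, "truth": truth}


# ---------------------------------------------------------------------------
# sequence assembly


def _letters(rng: np.random.Generator, n: int, alphabet: str = AMINO_ACIDS,
             freqs: Optional[dict[str, float]] = None) -> str:
    if freqs is None:
        idx = rng.integers(0, len(alphabet), size=n)
        return "".join(alphabet[i] for i in idx)
    letters = list(freqs)
    p = np.array([freqs[l] for l in letters], dtype=float)
    p /= p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


def instantiate_pattern(pattern: ConsensusPattern, rng: np.random.Generator) -> str:
    """A concrete string accepted by ``pattern`` (random free choices)."""
    out = []
    for el in pattern.elements:
        if isinstance(el, Residue):
            out.append(el.letter)
        elif isinstance(el, Alternative):
            out.append(sorted(el.letters)[rng.integers(0, len(el.letters))])
        elif isinstance(el, Wildcard):
            out.append(_letters(rng, el.repeat))
    return "".join(out)


class _Builder:
    """Accumulates sequence segments and tracks protected positions."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.protected: list[tuple[int, int]] = []
        self.length = 0

    def add(self, text: str, protect: bool = False) -> int:
        start = self.length
        self.parts.append(text)
        self.length += len(text)
        if protect:
            self.protected.append((start, self.length))
        return start

    def build(self) -> tuple[str, set[int]]:
        protected = set()
        for lo, hi in self.protected:
            protected.update(range(lo, hi))
        return "".join(self.parts), protected


def _signature_texts(rng: np.random.Generator) -> dict[str, str]:
    lib = default_library()
    by_slot: dict[str, list] = {}
    for entry in lib.category("kinase_signature"):
        by_slot.setdefault(entry.tag, []).append(entry.pattern)
    out = {}
    for slot, patterns in by_slot.items():
        pattern = patterns[rng.integers(0, len(patterns))]
        out[slot] = instantiate_pattern(pattern, rng)
    return out


def _cd_text(group: str, rng: np.random.Generator) -> str:
    lib = default_library()
    for entry in lib.category("cd_site"):
        if entry.tag == group:
            return instantiate_pattern(entry.pattern, rng)
    raise ValueError(f"no CD-site pattern for group {group!r}")


def make_mapk_protein(
    group: str,
    loop_variant: str,
    rng: np.random.Generator,
    record_id: str = "syn",
    with_loop: bool = True,
    background_freqs: Optional[dict[str, float]] = None,
) -> tuple[ProteinRecord, TruthRecord, set[int]]:
    """Assemble one MAPK (or MAPK-like when ``with_loop`` is false).

    Returns the record, its truth entry, and the set of protected
    (planted-motif) positions used by the mutation step.
    """
    if group not in GROUP_LOOP_VARIANTS:
        raise ValueError(f"unknown group {group!r}")
    if with_loop and loop_variant not in GROUP_LOOP_VARIANTS[group]:
        raise ValueError(
            f"loop variant {loop_variant!r} is not legal for group {group!r} "
            f"(allowed: {GROUP_LOOP_VARIANTS[group]})"
        )
    b = _Builder()
    bg = background_freqs

    # N-terminal block; group D carries the diagnostic TxY + secondary motif.
    b.add(_letters(rng, int(rng.integers(8, 25)), freqs=bg))
    if group == "D":
        txy = _NTERM_TXY_D[rng.integers(0, len(_NTERM_TXY_D))]
        b.add(txy, protect=True)
        b.add(_letters(rng, int(rng.integers(2, 12)), freqs=bg))
        sec = _NTERM_SECONDARY_D[rng.integers(0, len(_NTERM_SECONDARY_D))]
        b.add(sec, protect=True)
    b.add(_letters(rng, int(rng.integers(5, 20)), freqs=bg))

    # Kinase-domain anchors N1..N9 with random spacers.
    sigs = _signature_texts(rng)
    for slot in ("N1", "N2", "N3", "N4", "N5", "N6", "N7", "N8", "N9"):
        b.add(sigs[slot], protect=True)
        b.add(_letters(rng, int(rng.integers(3, 14)), freqs=bg))

    # Activation loop between the D-F-G anchor and T-R-W-Y-R-A-P-E-L.
    b.add(_letters(rng, int(rng.integers(2, 7)), alphabet=_LOOP_SAFE))
    if with_loop:
        b.add(loop_variant, protect=True)
        b.add(_letters(rng, int(rng.integers(1, 8)), alphabet=_LOOP_SAFE))
        post = _POSTLOOP_BY_GROUP[group]
        b.add(post[rng.integers(0, len(post))], protect=True)
    b.add(_letters(rng, int(rng.integers(2, 7)), alphabet=_LOOP_SAFE))

    # C-terminal anchors and the group-specific CD site.
    b.add(sigs["C1"], protect=True)
    b.add(_letters(rng, int(rng.integers(3, 10)), freqs=bg))
    b.add(sigs["C2"], protect=True)
    b.add(_letters(rng, int(rng.integers(3, 10)), freqs=bg))
    b.add(sigs["C3"], protect=True)
    b.add(_letters(rng, int(rng.integers(4, 12)), freqs=bg))
    if group in "ABCD":
        b.add(_cd_text(group, rng), protect=True)
    b.add(_letters(rng, int(rng.integers(10, 40)), freqs=bg))
    if b.length < 300:
        b.add(_letters(rng, 300 - b.length, freqs=bg))

    sequence, protected = b.build()
    record = ProteinRecord(id=record_id, sequence=sequence)
    truth = TruthRecord(
        record_id=record_id,
        verdict="MAPK" if with_loop else "MAPK-like",
        planted_group=group,
        loop_variant=loop_variant if with_loop else "",
    )
    return record, truth, protected


def mutate_sequence(
    sequence: str,
    rate: float,
    rng: np.random.Generator,
    protected: set[int] = frozenset(),
) -> str:
    """Point-mutate each unprotected position with probability ``rate``."""
    if rate == 0:
        return sequence
    chars = list(sequence)
    for i in range(len(chars)):
        if i in protected:
            continue
        if rng.random() < rate:
            current = chars[i]
            options = [c for c in AMINO_ACIDS if c != current]
            chars[i] = options[rng.integers(0, len(options))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# proteome generator


def _choose_weighted(rng: np.random.Generator, weights: dict) -> object:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    p /= p.sum()
    return keys[rng.choice(len(keys), p=p)]


def _choose_variant(group: str, cfg: GeneratorConfig, rng: np.random.Generator) -> str:
    legal = GROUP_LOOP_VARIANTS[group]
    if len(legal) == 1:
        return legal[0]
    canonical, novel = legal[0], legal[1:]
    if rng.random() < cfg.canonical_variant_weight:
        return canonical
    return novel[rng.integers(0, len(novel))]


def _sample_introns(group: str, cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    weights = cfg.intron_weights
    if group == "D":  # group D genes carry seven to fourteen introns
        weights = {k: v for k, v in weights.items() if 7 <= k <= 14} or {9: 1}
    return int(_choose_weighted(rng, weights))


def make_proteome(config: GeneratorConfig) -> Proteome:
    """A mixture of MAPKs, MAPK-like decoys and random decoys, with paralogs."""
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    models: list[GeneModel] = []
    truth: dict[str, TruthRecord] = {}
    parents: list[tuple[ProteinRecord, TruthRecord, set[int]]] = []

    n = config.n_sequences
    n_random = int(round(n * config.fraction_random_decoy))
    n_like = int(round(n * config.fraction_mapk_like))
    n_mapk = n - n_random - n_like
    n_paralog = int(round(n_mapk * config.fraction_paralog))
    n_parent = n_mapk - n_paralog

    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"SYN{idx:04d}"

    for _ in range(n_parent):
        group = _choose_weighted(rng, config.group_weights)
        variant = _choose_variant(group, config, rng)
        rid = next_id()
        rec, tr, protected = make_mapk_protein(
            group, variant, rng, record_id=rid, background_freqs=config.background_freqs
        )
        seq = mutate_sequence(
            rec.sequence,
            config.mutation_rate,
            rng,
            protected if config.protect_motifs else frozenset(),
        )
        rec = ProteinRecord(id=rid, sequence=seq)
        tr = replace(tr, mutation_rate=config.mutation_rate,
                     ortholog_label=f"MPK{1 + len(parents) % 21}")
        parents.append((rec, tr, protected))
        records.append(rec)
        truth[rid] = tr

    for _ in range(n_paralog):
        if not parents:
            break
        parent_rec, parent_tr, protected = parents[rng.integers(0, len(parents))]
        rid = next_id()
        # paralog: duplicate the parent, then drift a little
        seq = mutate_sequence(parent_rec.sequence, 0.02, rng,
                              protected if config.protect_motifs else frozenset())
        seq = mutate_sequence(seq, config.mutation_rate, rng,
                              protected if config.protect_motifs else frozenset())
        records.append(ProteinRecord(id=rid, sequence=seq))
        truth[rid] = replace(
            parent_tr,
            record_id=rid,
            paralog_of=parent_rec.id,
            duplicated=True,
            mutation_rate=config.mutation_rate,
        )
        truth[parent_rec.id] = replace(truth[parent_rec.id], duplicated=True)

    for _ in range(n_like):
        group = _choose_weighted(rng, config.group_weights)
        rid = next_id()
        rec, tr, protected = make_mapk_protein(
            group, GROUP_LOOP_VARIANTS[group][0], rng, record_id=rid,
            with_loop=False, background_freqs=config.background_freqs,
        )
        seq = mutate_sequence(rec.sequence, config.mutation_rate, rng,
                              protected if config.protect_motifs else frozenset())
        records.append(ProteinRecord(id=rid, sequence=seq))
        truth[rid] = replace(tr, mutation_rate=config.mutation_rate)

    for _ in range(n_random):
        rid = next_id()
        seq = _letters(rng, int(rng.integers(300, 601)), freqs=config.background_freqs)
        records.append(ProteinRecord(id=rid, sequence=seq))
        truth[rid] = TruthRecord(record_id=rid, verdict="rejected",
                                 planted_group="", loop_variant="")

    offset = 1000
    for rec in records:
        t = truth[rec.id]
        intron_count = _sample_introns(t.planted_group or "A", config, rng) \
            if t.verdict != "rejected" else int(_choose_weighted(rng, config.intron_weights))
        orf = 3 * (len(rec.sequence) + 1)
        model, offset = _make_gene_model(rec.id, orf, intron_count, offset, rng)
        models.append(model)
        truth[rec.id] = replace(t, intron_count=intron_count)

    return Proteome(records=records, models=models, truth=truth)


def _make_gene_model(
    rid: str, orf_nt: int, intron_count: int, offset: int, rng: np.random.Generator
) -> tuple[GeneModel, int]:
    k = intron_count + 1
    cuts = sorted(rng.choice(np.arange(1, orf_nt), size=k - 1, replace=False)) if k > 1 else []
    pieces = np.diff([0, *cuts, orf_nt])
    exons = []
    pos = offset
    for i, length in enumerate(pieces):
        exons.append((pos, pos + int(length)))
        pos += int(length)
        if i < len(pieces) - 1:
            pos += int(rng.integers(80, 300))  # intron
    model = GeneModel(
        gene_id=f"{rid}.g",
        mrna_id=f"{rid}.m",
        exons=tuple(exons),
        strand="+",
        orf_length_nt=orf_nt,
    )
    return model, pos + 500


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(
                f"chr1\tplantmapk\tgene\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"chr1\tplantmapk\tmRNA\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.mrna_id};Parent={m.gene_id}\n"
            )
            for i, (start, end) in enumerate(m.exons, start=1):
                fh.write(
                    f"chr1\tplantmapk\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                    f"ID={m.mrna_id}.e{i};Parent={m.mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# reference sets for nomenclature


def make_reference_set(
    n_refs: int, rng: np.random.Generator, lineage: str = "other"
) -> ReferenceSet:
    """Random labelled reference MAPKs MPK1..MPKn (distinct scaffolds)."""
    records = []
    numbers = {}
    groups = list(GROUP_LOOP_VARIANTS)
    for i in range(1, n_refs + 1):
        group = groups[rng.integers(0, 4)]  # A..D
        variant = GROUP_LOOP_VARIANTS[group][0]
        rec, _, _ = make_mapk_protein(group, variant, rng, record_id=f"REF_MPK{i}")
        records.append(rec)
        numbers[rec.id] = i
    return ReferenceSet(records=tuple(records), numbers=numbers, lineage=lineage)


def make_queries_from_references(
    refset: ReferenceSet,
    n_queries: int,
    rate: float,
    rng: np.random.Generator,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Queries mutated off references; returns records + true ortholog numbers."""
    queries = []
    true_numbers = {}
    for i in range(n_queries):
        ref = refset.records[rng.integers(0, len(refset.records))]
        qid = f"Q{i:03d}"
        queries.append(
            ProteinRecord(id=qid, sequence=mutate_sequence(ref.sequence, rate, rng))
        )
        true_numbers[qid] = refset.numbers[ref.id]
    return queries, true_numbers


# ---------------------------------------------------------------------------
# alignments with controlled statistics


def make_triplet_alignment(
    n_identical: int,
    n_divergent_all: int,
    mA: int,
    mB: int,
    mC: int,
    rng: np.random.Generator,
) -> AlignmentMatrix:
    """Three-row alignment realising exact relative-rate site-class counts."""
    for name, v in [("n_identical", n_identical), ("n_divergent_all", n_divergent_all),
                    ("mA", mA), ("mB", mB), ("mC", mC)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    columns: list[tuple[str, str, str]] = []

    def two_letters() -> tuple[str, str]:
        i = int(rng.integers(0, 20))
        j = int((i + 1 + rng.integers(0, 19)) % 20)
        return AMINO_ACIDS[i], AMINO_ACIDS[j]

    for _ in range(n_identical):
        ch = AMINO_ACIDS[rng.integers(0, 20)]
        columns.append((ch, ch, ch))
    for _ in range(n_divergent_all):
        i, j, k = rng.choice(20, size=3, replace=False)
        columns.append((AMINO_ACIDS[i], AMINO_ACIDS[j], AMINO_ACIDS[k]))
    for _ in range(mA):
        x, y = two_letters()
        columns.append((x, y, y))
    for _ in range(mB):
        x, y = two_letters()
        columns.append((y, x, y))
    for _ in range(mC):
        x, y = two_letters()
        columns.append((y, y, x))
    order = rng.permutation(len(columns))
    rows = ["".join(columns[i][r] for i in order) for r in range(3)]
    return AlignmentMatrix(
        [ProteinRecord(id=name, sequence=seq) for name, seq in zip("ABC", rows)]
    )


def polymorphism_pi_range(m: int, S: int, n: int) -> tuple[float, float]:
    """Feasible per-site diversity for S segregating biallelic columns."""
    pairs = m * (m - 1) / 2
    lo = S * (m - 1) / pairs / n
    hi = S * (m // 2) * (m - m // 2) / pairs / n
    return lo, hi


def make_polymorphism_alignment(
    m: int,
    n: int,
    S_target: int,
    pi_target: float,
    rng: np.random.Generator,
) -> tuple[AlignmentMatrix, int, float]:
    """Ancestral row plus derived alleles at exactly S_target columns.

    Derived-allele counts are chosen greedily so the realised per-site
    diversity approaches ``pi_target``.  Returns (alignment, realised S,
    realised pi); realised S is exact.
    """
    if S_target > n:
        raise ValueError("S_target cannot exceed the number of sites")
    if m < 2:
        raise ValueError("need at least two sequences")
    pairs = m * (m - 1) / 2
    if S_target > 0:
        lo, hi = polymorphism_pi_range(m, S_target, n)
        if not lo - 1e-12 <= pi_target <= hi + 1e-12:
            raise ValueError(
                f"pi_target {pi_target} infeasible for m={m}, n={n}, "
                f"S={S_target}; feasible range [{lo:.6g}, {hi:.6g}]"
            )
    target_total = pi_target * pairs * n  # total pairwise differences
    counts = [1] * S_target
    current = sum(k * (m - k) for k in counts)
    # increasing k by 1 adds m - 2k - 1 pairwise differences
    improved = True
    while improved and current < target_total:
        improved = False
        for i in range(S_target):
            gain = m - 2 * counts[i] - 1
            if gain <= 0:
                continue
            if abs(current + gain - target_total) < abs(current - target_total):
                counts[i] += 1
                current += gain
                improved = True
            if current >= target_total:
                break

    arr = np.empty((m, n), dtype="<U1")
    for j in range(n):
        arr[:, j] = AMINO_ACIDS[rng.integers(0, 20)]
    seg_cols = rng.choice(n, size=S_target, replace=False)
    for col, k in zip(seg_cols, counts):
        ancestral = arr[0, col]
        derived = AMINO_ACIDS[(AMINO_ACIDS.index(ancestral) + 1 + rng.integers(0, 19)) % 20]
        carriers = rng.choice(np.arange(1, m), size=k, replace=False)
        arr[carriers, col] = derived
    records = [
        ProteinRecord(id=f"seq{i:03d}", sequence="".join(arr[i])) for i in range(m)
    ]
    alignment = AlignmentMatrix(records)
    realized_total = sum(k * (m - k) for k in counts)
    realized_pi = realized_total / pairs / n
    return alignment, S_target, realized_pi
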