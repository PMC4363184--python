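"""Kinase-domain annotation, activation-loop calling and group assignment.

A MAPK is recognised by an ordered chain of short signature consensuses:
nine N-terminal anchors (the glycine-rich loop through the catalytic
H-R-D-L-K-P-x-N and the D-F-G signature) and three C-terminal anchors
(T-R-W-Y-R-A-P-E-L and two post-loop consensuses).  A sequence is
"ordered-valid" when at least 6 of the 9 N-terminal and 2 of the 3
C-terminal anchors occur left-to-right with positive gaps.  The
activation loop is the stretch between the D-F-G signature and
T-R-W-Y-R-A-P-E-L; its phospho-acceptor triplet (T-x-Y canonically, ten
recognised variants in total) decides the MAPK verdict and, with the
common-docking site and N-terminal motifs, the group A-F call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .constants import LOOP_VARIANTS
from .core_io import ProteinRecord
from .motifs import PatternLibrary, PatternMatch, default_library, scan

N_SLOTS = ("N1", "N2", "N3", "N4", "N5", "N6", "N7", "N8", "N9")
C_SLOTS = ("C1", "C2", "C3")
MIN_N_ANCHORS = 6
MIN_C_ANCHORS = 2

#: Triplet shape accepted as "T-x-Y-like": first and last residues drawn
#: from the residues the ten variants actually use.
_TRIPLET_FIRST = frozenset("TMS")
_TRIPLET_LAST = frozenset("YMC")

NTERM_SECONDARY_WINDOW = 30  # residues after an N-terminal TxY hit
CTERM_POSTLOOP_WINDOW = 40  # residues after the activation-loop end


@dataclass(frozen=True)
class LoopCall:
    start: int
    end: int
    variant: str  # one of LOOP_VARIANTS or "other"


@dataclass
class KinaseAnnotation:
    record_id: str
    signature_hits: dict[str, PatternMatch] = field(default_factory=dict)
    ordered_valid: bool = False
    domain_start: Optional[int] = None
    loop: Optional[LoopCall] = None
    nterm_txy: list[PatternMatch] = field(default_factory=list)
    nterm_secondary: list[PatternMatch] = field(default_factory=list)
    cterm_postloop: list[PatternMatch] = field(default_factory=list)
    cd_site: Optional[tuple[str, int, int]] = None  # (group, score, position)
    reasons: list[str] = field(default_factory=list)

    @property
    def n_anchor_count(self) -> int:
        return sum(1 for slot in N_SLOTS if slot in self.signature_hits)

    @property
    def c_anchor_count(self) -> int:
        return sum(1 for slot in C_SLOTS if slot in self.signature_hits)


@dataclass(frozen=True)
class MapkCall:
    record_id: str
    verdict: str  # MAPK | MAPK-like | rejected
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class GroupAssignment:
    record_id: str
    group: str  # A..F or "unresolved"
    evidence: dict[str, str]


def locate_kinase_domain(
    record: ProteinRecord, library: PatternLibrary | None = None
) -> KinaseAnnotation:
    """Chain the signature anchors left-to-right and test ordered validity.

    For each anchor slot in canonical order the leftmost match starting
    strictly after the previous matched anchor's end is taken; slots with
    no such match are skipped without advancing the cursor.
    """
    library = library or default_library()
    ann = KinaseAnnotation(record_id=record.id)
    seq = record.sequence
    if len(seq) < 50:
        ann.reasons.append("sequence shorter than 50 residues")
        return ann

    by_slot: dict[str, list] = {}
    for entry in library.category("kinase_signature"):
        by_slot.setdefault(entry.tag, []).append(entry.pattern)

    cursor = 0
    for slot in N_SLOTS + C_SLOTS:
        best: Optional[PatternMatch] = None
        for pattern in by_slot.get(slot, []):
            for match in scan(pattern, seq):
                if match.start >= cursor and (best is None or match.start < best.start):
                    best = match
        if best is not None:
            ann.signature_hits[slot] = best
            cursor = best.end
    ann.ordered_valid = (
        ann.n_anchor_count >= MIN_N_ANCHORS and ann.c_anchor_count >= MIN_C_ANCHORS
    )
    if ann.signature_hits:
        ann.domain_start = min(m.start for m in ann.signature_hits.values())
    if not ann.ordered_valid:
        ann.reasons.append(
            f"kinase signature incomplete: {ann.n_anchor_count}/9 N-terminal, "
            f"{ann.c_anchor_count}/3 C-terminal anchors in order"
        )
    return ann


def _split_variant(region: str) -> Optional[tuple[int, int, str]]:
    """Last insertion-split variant: (first-residue pos, pair pos, variant)."""
    pairs = {v[1:] for v in LOOP_VARIANTS}
    for j in range(len(region) - 2, -1, -1):
        if region[j : j + 2] not in pairs:
            continue
        for i in range(j - 1, -1, -1):
            triplet = region[i] + region[j : j + 2]
            if triplet in LOOP_VARIANTS:
                return i, j, triplet
    return None


def locate_activation_loop(ann: KinaseAnnotation, record: ProteinRecord) -> KinaseAnnotation:
    """Call the activation-loop triplet between the D-F-G and A-P-E anchors.

    Within the inter-anchor region the *last* T-x-Y-like triplet whose
    letters form a recognised variant wins, which tolerates insertions
    between T and the D-Y/E-Y pair; failing that, the T-x-Y-like triplet
    closest to the downstream anchor is recorded with variant "other".
    """
    dfg = ann.signature_hits.get("N9")
    apel = ann.signature_hits.get("C1")
    if dfg is None or apel is None:
        ann.reasons.append("activation loop not searchable: D-F-G or A-P-E anchor missing")
        return ann
    lo, hi = dfg.end, apel.start
    region = record.sequence[lo:hi]
    candidates = []
    for i in range(len(region) - 2):
        triplet = region[i : i + 3]
        if triplet[0] in _TRIPLET_FIRST and triplet[2] in _TRIPLET_LAST and "X" not in triplet:
            candidates.append((i, triplet))
    recognised = [(i, t) for i, t in candidates if t in LOOP_VARIANTS]
    split = _split_variant(region)
    if recognised:
        i, triplet = recognised[-1]
        ann.loop = LoopCall(start=lo + i, end=lo + i + 3, variant=triplet)
    elif split is not None:
        # insertion between the phospho-acceptor T and the x-Y pair
        # (the MdMPK9/PtMPK17-1 situation): the terminal pair plus the
        # nearest compatible upstream T/M/S still names the variant
        i, j, triplet = split
        ann.loop = LoopCall(start=lo + i, end=lo + j + 2, variant=triplet)
        ann.reasons.append(f"activation-loop variant {triplet} split by an insertion")
    elif candidates:
        i, triplet = candidates[-1]
        ann.loop = LoopCall(start=lo + i, end=lo + i + 3, variant="other")
        ann.reasons.append(f"activation-loop triplet {triplet} not a recognised variant")
    else:
        ann.reasons.append("no T-x-Y-like triplet in the activation-loop region")
    return ann


def detect_terminal_motifs(
    ann: KinaseAnnotation, record: ProteinRecord, library: PatternLibrary | None = None
) -> KinaseAnnotation:
    """Find N-terminal TxY/secondary motifs and post-loop C-terminal motifs."""
    library = library or default_library()
    seq = record.sequence
    domain_start = ann.domain_start if ann.domain_start is not None else len(seq)

    txy_hits: list[PatternMatch] = []
    for entry in library.category("nterm_txy"):
        txy_hits.extend(m for m in scan(entry.pattern, seq) if m.end <= domain_start)
    txy_hits.sort(key=lambda m: m.start)
    ann.nterm_txy = txy_hits

    secondary: list[PatternMatch] = []
    if txy_hits:
        for entry in library.category("nterm_secondary"):
            for m in scan(entry.pattern, seq):
                if any(0 <= m.start - t.end <= NTERM_SECONDARY_WINDOW for t in txy_hits):
                    secondary.append(m)
    secondary.sort(key=lambda m: m.start)
    ann.nterm_secondary = secondary

    postloop: list[PatternMatch] = []
    if ann.loop is not None:
        for entry in library.category("cterm_postloop"):
            for m in scan(entry.pattern, seq):
                if 0 <= m.start - ann.loop.end <= CTERM_POSTLOOP_WINDOW:
                    postloop.append(m)
    postloop.sort(key=lambda m: m.start)
    ann.cterm_postloop = postloop
    return ann


def match_cd_site(
    ann: KinaseAnnotation, record: ProteinRecord, library: PatternLibrary | None = None
) -> KinaseAnnotation:
    """Best group-tagged common-docking hit downstream of the loop."""
    library = library or default_library()
    if ann.loop is None:
        ann.reasons.append("CD site not searched: no activation loop")
        return ann
    tail = record.sequence[ann.loop.end :]
    best: list[tuple[str, int, int]] = []  # (group, score, absolute position)
    for entry in library.category("cd_site"):
        hits = scan(entry.pattern, tail)
        if hits:
            first = hits[0]
            best.append((entry.tag, entry.pattern.length, ann.loop.end + first.start))
    if not best:
        return ann
    top = max(s for _, s, _ in best)
    winners = [b for b in best if b[1] == top]
    if len(winners) > 1:
        ann.reasons.append(
            "ambiguous CD site: groups " + "/".join(sorted(w[0] for w in winners))
        )
        return ann
    ann.cd_site = winners[0]
    return ann


def annotate_record(
    record: ProteinRecord, library: PatternLibrary | None = None
) -> KinaseAnnotation:
    """Full annotation: domain chain, loop, terminal motifs, CD site."""
    library = library or default_library()
    ann = locate_kinase_domain(record, library)
    ann = locate_activation_loop(ann, record)
    ann = detect_terminal_motifs(ann, record, library)
    ann = match_cd_site(ann, record, library)
    return ann


def call_mapk(ann: KinaseAnnotation) -> MapkCall:
    """Apply the identification filter: kinase domain plus recognised loop."""
    reasons = list(ann.reasons)
    if ann.ordered_valid and ann.loop is not None and ann.loop.variant in LOOP_VARIANTS:
        reasons.append(f"kinase signature complete; activation loop {ann.loop.variant}")
        verdict = "MAPK"
    elif ann.ordered_valid:
        reasons.append("kinase signature complete but no recognised activation-loop variant")
        verdict = "MAPK-like"
    else:
        reasons.append("kinase signature not satisfied")
        verdict = "rejected"
    return MapkCall(record_id=ann.record_id, verdict=verdict, reasons=tuple(reasons))


_VARIANT_GROUP = {
    "TDY": "D",
    "TSY": "E",
    "TEM": "E",
    "TQM": "E",
    "TRM": "E",
    "TQY": "A",
    "MEY": "B",
    "TEC": "B",
    "TVY": "B",
}

_SECONDARY_GROUP = {"AKY": "A", "NKY": "A", "SKY": "B", "RKY": "B", "TKY": "C"}


def assign_group(
    ann: KinaseAnnotation,
    call: MapkCall,
    tree_placement: Optional[str] = None,
) -> GroupAssignment:
    """Motif-based group call, overridable by tree placement.

    Rule order: TDY -> D; the four basal variants -> E; TQY -> A;
    MEY/TEC/TVY -> B; TEY disambiguated by CD-site group, then by
    secondary N-terminal motif, else unresolved.  Tree placement, when
    given, overrides any motif call and is the only route to group F.
    """
    if call.verdict != "MAPK":
        raise ValueError(f"group assignment requires a MAPK call, got {call.verdict!r}")
    evidence: dict[str, str] = {}
    group = "unresolved"
    variant = ann.loop.variant if ann.loop else "other"
    evidence["loop_variant"] = variant

    if variant in _VARIANT_GROUP:
        group = _VARIANT_GROUP[variant]
        evidence["rule"] = f"loop variant {variant} -> group {group}"
    elif variant == "TEY":
        if ann.cd_site is not None:
            group = ann.cd_site[0]
            evidence["rule"] = f"TEY loop disambiguated by CD-site group {group}"
            evidence["cd_group"] = group
        else:
            sec_groups = {
                _SECONDARY_GROUP[m.matched]
                for m in ann.nterm_secondary
                if m.matched in _SECONDARY_GROUP
            }
            if len(sec_groups) == 1:
                group = sec_groups.pop()
                evidence["rule"] = f"TEY loop disambiguated by secondary N-terminal motif -> {group}"
            else:
                evidence["rule"] = "TEY loop: no CD site, no unambiguous secondary motif"
    if ann.nterm_txy:
        evidence["nterm_txy"] = ",".join(m.matched for m in ann.nterm_txy)
    if tree_placement is not None:
        evidence["tree_placement"] = tree_placement
        evidence["rule"] = f"tree placement overrides motif call -> {tree_placement}"
        group = tree_placement
    return GroupAssignment(record_id=ann.record_id, group=group, evidence=evidence)


def annotation_table(
    annotations: list[KinaseAnnotation],
    calls: dict[str, MapkCall],
    groups: dict[str, GroupAssignment] | None = None,
):
    """Flatten annotations into a DataFrame matching the report layout."""
    import pandas as pd

    rows = []
    for ann in annotations:
        call = calls[ann.record_id]
        grp = groups.get(ann.record_id) if groups else None
        rows.append(
            {
                "record_id": ann.record_id,
                "verdict": call.verdict,
                "loop_variant": ann.loop.variant if ann.loop else "",
                "loop_start": ann.loop.start if ann.loop else -1,
                "loop_end": ann.loop.end if ann.loop else -1,
                "group": grp.group if grp else "",
                "cd_group": ann.cd_site[0] if ann.cd_site else "",
                "nterm_motifs": ",".join(m.matched for m in ann.nterm_txy),
                "nterm_secondary": ",".join(m.matched for m in ann.nterm_secondary),
                "cterm_motifs": ",".join(m.matched for m in ann.cterm_postloop),
                "reasons": ";".join(call.reasons),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "record_id",
            "verdict",
            "loop_variant",
            "loop_start",
            "loop_end",
            "group",
            "cd_group",
            "nterm_motifs",
            "nterm_secondary",
            "cterm_motifs",
            "reasons",
        ],
    )
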