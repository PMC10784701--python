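"""Active-site motif classification and sequence similarity networks.

COMT-type (caffeic acid O-methyltransferase-like) small-molecule
methyltransferases line their substrate cavity with two helix faces carrying
hydrophobic residues at reference positions 153/157 (interdomain helix) and
297/301 (alpha-15), in RedM numbering. This module maps those positions onto
arbitrary family sequences by global alignment, classifies each sequence
into nested motif-stringency tiers and catalytic-residue classes
(His at 253, Tyr at 140), and builds a thresholded all-vs-all sequence
similarity network whose connected components are the family subclusters.

The edge weight is an "alignment score" in the SSN tradition: a BLOSUM62
local-alignment bit-score-like transform, AS = (lambda*S - ln(K*m*n))/ln(10)
with ungapped Karlin-Altschul constants (lambda = 0.267, K = 0.041). It has
the same ordering behaviour as E-value-derived scores from network services
but absolute cluster membership of any database-scale network is not a
reproduction target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "PositionMap",
    "MotifTier",
    "SsnGraph",
    "REFERENCE_POSITIONS",
    "read_fasta",
    "write_fasta",
    "map_positions",
    "classify_motif_tier",
    "classify_catalytic",
    "pairwise_score",
    "build_ssn",
    "motif_fraction",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS + "X")

#: reference (RedM-numbered) positions of interest: catalytic tyrosine 140,
#: motif slots 153/157 and 297/301, cofactor-binding 250, catalytic-histidine
#: position 253, gatekeeper 297, and 301/305 on the alpha-15 face
REFERENCE_POSITIONS = (140, 153, 157, 250, 253, 297, 301, 305)

#: nested stringency tiers, most stringent first; each tier is a pair of
#: allowed-residue sets for (pos153, pos157) and (pos297, pos301), where
#: None means "any residue"
MOTIF_TIERS: dict[str, tuple[tuple, tuple]] = {
    # FxxxM / MxxxM
    "yellow": (({"F"}, {"M"}), ({"M"}, {"M"})),
    # FxxxM / [FYML]xxxM
    "orange": (({"F"}, {"M"}), ({"F", "Y", "M", "L"}, {"M"})),
    # [FL]xxx[ML] / [FYML]xxx[FML]
    "maroon": (({"F", "L"}, {"M", "L"}), ({"F", "Y", "M", "L"}, {"F", "M", "L"})),
    # [FL]xxx[ML] / xxxx[FML]
    "purple": (({"F", "L"}, {"M", "L"}), (None, {"F", "M", "L"})),
}
TIER_ORDER = ("yellow", "orange", "maroon", "purple")  # most to least stringent


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if not seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} has non-amino-acid letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# position mapping


@dataclass
class PositionMap:
    """Reference position (1-based) -> target position (1-based) or None."""

    mapping: dict[int, int | None]
    score: float

    def __getitem__(self, ref_pos: int) -> int | None:
        return self.mapping[ref_pos]

    def is_gapped(self, ref_pos: int) -> bool:
        return self.mapping.get(ref_pos) is None


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def map_positions(
    target: SequenceRecord,
    reference: SequenceRecord,
    ref_positions: Sequence[int] = REFERENCE_POSITIONS,
) -> PositionMap:
    """Map reference positions onto a target via BLOSUM62 global alignment.

    Positions falling in a deletion of the target are reported as gapped
    (None). Returned positions are 1-based.
    """
    alignment = _aligner("global").align(reference.seq, target.seq)[0]
    ref_to_target: dict[int, int] = {}
    for (r0, r1), (t0, _t1) in zip(*alignment.aligned):
        for offset in range(r1 - r0):
            ref_to_target[r0 + offset + 1] = t0 + offset + 1
    mapping = {pos: ref_to_target.get(pos) for pos in ref_positions}
    return PositionMap(mapping=mapping, score=float(alignment.score))


# ---------------------------------------------------------------------------
# classification


@dataclass
class MotifTier:
    tier: str  # yellow | orange | maroon | purple | none
    matched_patterns: tuple[str | None, str | None] = (None, None)
    reason: str = ""

    def satisfies(self, tier: str) -> bool:
        """Whether this classification meets the named tier (nesting aware)."""
        if self.tier == "none":
            return False
        return TIER_ORDER.index(self.tier) <= TIER_ORDER.index(tier)


def _tier_matches(tier: str, residues: dict[int, str | None]) -> bool:
    (slot1, slot2) = MOTIF_TIERS[tier]
    for (allowed_a, allowed_b), (pos_a, pos_b) in zip(
        (slot1, slot2), ((153, 157), (297, 301))
    ):
        for allowed, pos in ((allowed_a, pos_a), (allowed_b, pos_b)):
            residue = residues[pos]
            if residue is None:
                return False  # gapped position fails every pattern
            if allowed is not None and residue not in allowed:
                return False
    return True


def _residue_at(target: SequenceRecord, position_map: PositionMap, ref_pos: int) -> str | None:
    pos = position_map.mapping.get(ref_pos)
    if pos is None or not 1 <= pos <= len(target.seq):
        return None
    return target.seq[pos - 1]


def classify_motif_tier(target: SequenceRecord, position_map: PositionMap) -> MotifTier:
    """Most stringent motif tier whose both pattern slots match the target."""
    residues = {pos: _residue_at(target, position_map, pos) for pos in (153, 157, 297, 301)}
    if all(r is None for r in residues.values()):
        return MotifTier("none", reason="all motif positions gapped")
    for tier in TIER_ORDER:
        if _tier_matches(tier, residues):
            slot1, slot2 = MOTIF_TIERS[tier]
            return MotifTier(tier, matched_patterns=(_fmt(slot1), _fmt(slot2)))
    return MotifTier("none", reason="no pattern pair satisfied")


def _fmt(slot: tuple) -> str:
    def one(allowed):
        if allowed is None:
            return "x"
        return allowed.copy().pop() if len(allowed) == 1 else "[" + "".join(sorted(allowed)) + "]"

    return f"{one(slot[0])}xxx{one(slot[1])}"


def classify_catalytic(
    target: SequenceRecord, position_map: PositionMap
) -> dict[str, bool | str]:
    """Catalytic-residue flags: His at mapped 253, Tyr at mapped 140."""
    res_253 = _residue_at(target, position_map, 253)
    res_140 = _residue_at(target, position_map, 140)
    return {
        "his_253_equivalent": res_253 == "H",
        "tyr_140_equivalent": res_140 == "Y",
        "residue_253": res_253 if res_253 is not None else "gapped",
        "residue_140": res_140 if res_140 is not None else "gapped",
    }


# ---------------------------------------------------------------------------
# sequence similarity network

KARLIN_ALTSCHUL_LAMBDA = 0.267  # ungapped BLOSUM62
KARLIN_ALTSCHUL_K = 0.041


def pairwise_score(a: SequenceRecord, b: SequenceRecord) -> float:
    """Alignment score AS = (lambda*S - ln(K*m*n)) / ln(10).

    S is the BLOSUM62 local (Smith-Waterman) alignment score; the transform
    is the -log10 E-value of the Karlin-Altschul statistics for a search of
    size m*n, making AS comparable across sequence lengths. Symmetric.
    """
    score = float(_aligner("local").score(a.seq, b.seq))
    m, n = len(a), len(b)
    return (KARLIN_ALTSCHUL_LAMBDA * score - math.log(KARLIN_ALTSCHUL_K * m * n)) / math.log(10.0)


@dataclass
class SsnGraph:
    graph: nx.Graph
    threshold: float

    @property
    def clusters(self) -> list[set[str]]:
        """Connected components, largest first (singletons included)."""
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))

    def edges_tsv(self) -> str:
        lines = ["node_1\tnode_2\talignment_score"]
        for u, v, data in sorted(self.graph.edges(data=True)):
            lines.append(f"{u}\t{v}\t{data['score']:.2f}")
        return "\n".join(lines) + "\n"

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_ssn(records: Sequence[SequenceRecord], threshold: float) -> SsnGraph:
    """All-vs-all network; edges kept where pairwise_score >= threshold."""
    if len(records) < 2:
        raise ValueError("build_ssn: need at least 2 sequences")
    graph = nx.Graph()
    graph.add_nodes_from(r.id for r in records)
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            score = pairwise_score(a, b)
            if score >= threshold:
                graph.add_edge(a.id, b.id, score=score)
    return SsnGraph(graph=graph, threshold=threshold)


def motif_fraction(
    cluster: Iterable[str],
    classifications: dict[str, MotifTier],
    catalytic: dict[str, dict] | None = None,
    cumulative: bool = True,
) -> dict[str, float]:
    """Percent of cluster members per tier (and catalytic class).

    With ``cumulative=True`` (the default) tier nesting is respected: a
    yellow sequence also counts toward orange, maroon and purple, so the
    fractions are monotone non-decreasing from yellow to purple.
    """
    members = list(cluster)
    if not members:
        raise ValueError("motif_fraction: empty cluster")
    total = len(members)
    out: dict[str, float] = {}
    for tier in TIER_ORDER:
        if cumulative:
            count = sum(1 for m in members if classifications[m].satisfies(tier))
        else:
            count = sum(1 for m in members if classifications[m].tier == tier)
        out[tier] = 100.0 * count / total
    out["none"] = 100.0 * sum(1 for m in members if classifications[m].tier == "none") / total
    if catalytic is not None:
        out["his_253"] = 100.0 * sum(
            1 for m in members if catalytic[m]["his_253_equivalent"]
        ) / total
        out["tyr_140"] = 100.0 * sum(
            1 for m in members if catalytic[m]["tyr_140_equivalent"]
        ) / total
    return out
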