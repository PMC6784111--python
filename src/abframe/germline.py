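"""Germline V-gene assignment and combinatorial framework-variant design.

Given a Kabat-numbered query V domain and a reference set of germline V
genes, this module finds the closest germline by framework identity, lists
the framework mismatches, groups neighbouring mismatches into mutation
regions, and enumerates the full 2^k panel of parental/germline framework
combinations with signature-based variant names (e.g. DIQMAQ vs EIVLGE).

Framework identity is computed over Kabat FR1-FR3 only (70 positions for an
insertion-free kappa light chain): germline V genes do not encode FR4, and
this denominator reproduces the 65/70 = 92.86% arithmetic of a five-mismatch
kappa framework. Total V-region identity uses every Kabat position the
germline covers (V genes end within CDR3).
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .kabat import (
    KabatPosition,
    NumberedSequence,
    assign_kabat_numbering,
    region_of_position,
)

FRAMEWORK_REGIONS = ("FR1", "FR2", "FR3")
ALL_REGIONS = "all"
MAX_REGIONS = 12
# mismatches whose Kabat numbers differ by at most this merge into one region
# (allows a single matching position inside a region, as in L1-4 where
# position 2 is identical in parental and germline)
REGION_MERGE_GAP = 2

Mismatch = Tuple[KabatPosition, str, str]  # position, query residue, germline residue


@dataclass
class GermlineMatch:
    germline_id: str
    framework_identity: float  # percent over FR1-FR3
    total_identity: float      # percent over germline-covered positions
    mismatches: List[Mismatch] # FR1-FR3 only

    def __post_init__(self):
        for v in (self.framework_identity, self.total_identity):
            if not 0.0 <= v <= 100.0:
                raise ValueError("identity must be a percentage in [0, 100]")


@dataclass
class MutationRegion:
    """A contiguous framework stretch where the query deviates from germline."""

    label: str
    positions: List[KabatPosition]
    parental_residues: str
    germline_residues: str

    def __post_init__(self):
        if self.parental_residues == self.germline_residues:
            raise ValueError("a mutation region must differ at >=1 position")
        if len(self.parental_residues) != len(self.positions):
            raise ValueError("residue string length must match positions")


@dataclass
class VariantRecord:
    id: int
    name: str
    germline_regions: Tuple[str, ...]  # labels of regions set to germline
    c_terminal_lysine: bool
    sequence: NumberedSequence


@dataclass
class VariantPanel:
    parental_name: str
    regions: List[MutationRegion]
    variants: List[VariantRecord]

    def __post_init__(self):
        names = [v.name for v in self.variants]
        if len(set(names)) != len(names):
            raise ValueError("variant names must be unique")

    def names(self) -> List[str]:
        return [v.name for v in self.variants]

    def full_names(self) -> List[str]:
        return [f"{v.id}-{v.name}" for v in self.variants]

    def get(self, name: str) -> VariantRecord:
        for v in self.variants:
            if v.name == name or f"{v.id}-{v.name}" == name:
                return v
        raise KeyError(name)


class FrequencyProfile:
    """Per-position residue frequencies from a reference sequence set."""

    def __init__(self, counts: Dict[KabatPosition, Counter]):
        self.counts = counts

    @classmethod
    def from_sequences(cls, sequences: Iterable[NumberedSequence]) -> "FrequencyProfile":
        counts: Dict[KabatPosition, Counter] = {}
        for ns in sequences:
            for pos, res in ns.residues.items():
                counts.setdefault(pos, Counter())[res] += 1
        return cls(counts)

    def frequency(self, pos: KabatPosition, residue: str) -> float:
        """Relative frequency of `residue` at `pos` (fraction, sums to 1)."""
        if pos not in self.counts:
            raise KeyError(f"position {pos} not covered by the profile")
        total = sum(self.counts[pos].values())
        return self.counts[pos].get(residue, 0) / total


def positional_frequency(profile: FrequencyProfile, pos: KabatPosition, residue: str) -> float:
    """Frequency of `residue` at Kabat position `pos`, in percent."""
    return 100.0 * profile.frequency(pos, residue)


def _select_positions(ns: NumberedSequence, regions) -> set:
    if regions == ALL_REGIONS:
        return set(ns.residues)
    wanted = set(FRAMEWORK_REGIONS) if regions == "framework" else set(regions)
    return {p for p in ns.residues if region_of_position(ns.chain, p.number) in wanted}


def percent_identity(a: NumberedSequence, b: NumberedSequence, regions="framework") -> float:
    """Percent identity over the Kabat positions shared by both sequences.

    `regions` is "framework" (FR1-FR3), "all", or an iterable of region names.
    Positions absent from either sequence are excluded from the denominator;
    X never counts as a match.
    """
    if a.chain != b.chain:
        raise ValueError("sequences must be of the same chain")
    shared = _select_positions(a, regions) & _select_positions(b, regions)
    if not shared:
        raise ValueError("no overlapping positions in the selected regions")
    matches = sum(
        1 for p in shared
        if a.residues[p] == b.residues[p] and a.residues[p] != "X"
    )
    return 100.0 * matches / len(shared)


def find_closest_germline(
    query: NumberedSequence, reference: Sequence[NumberedSequence]
) -> GermlineMatch:
    """Scan a germline set and return the best framework-identity match.

    Ties on framework identity are broken by total V-region identity, then by
    germline id (lexicographic) for determinism. The mismatch list is
    restricted to FR1-FR3.
    """
    if not reference:
        raise ValueError("reference germline set is empty")
    best = None
    for germ in reference:
        fw = percent_identity(query, germ, regions="framework")
        total = percent_identity(query, germ, regions=ALL_REGIONS)
        key = (-fw, -total, germ.source_id)
        if best is None or key < best[0]:
            best = (key, germ, fw, total)
    _, germ, fw, total = best
    fw_pos = sorted(_select_positions(query, "framework") & _select_positions(germ, "framework"))
    mismatches = [
        (p, query.residues[p], germ.residues[p])
        for p in fw_pos
        if query.residues[p] != germ.residues[p]
    ]
    return GermlineMatch(
        germline_id=germ.source_id,
        framework_identity=fw,
        total_identity=total,
        mismatches=mismatches,
    )


def group_mismatches(
    mismatches: Sequence[Mismatch],
    query: Optional[NumberedSequence] = None,
    germline: Optional[NumberedSequence] = None,
    max_gap: int = REGION_MERGE_GAP,
) -> List[MutationRegion]:
    """Merge neighbouring framework mismatches into mutation regions.

    Mismatches whose Kabat numbers differ by at most `max_gap` join one
    region, so a run like 1, 3, 4 becomes the single region "1-4" spanning the
    intervening matched position. When `query`/`germline` are supplied, the
    residues at matched in-span positions are filled from them; otherwise only
    the mismatch positions themselves enter the region.
    """
    if not mismatches:
        return []
    ordered = sorted(mismatches, key=lambda m: m[0])
    clusters: List[List[Mismatch]] = [[ordered[0]]]
    for mm in ordered[1:]:
        if mm[0].number - clusters[-1][-1][0].number <= max_gap:
            clusters[-1].append(mm)
        else:
            clusters.append([mm])

    regions = []
    for cluster in clusters:
        first, last = cluster[0][0], cluster[-1][0]
        if query is not None and first.number != last.number:
            chain = query.chain
            span = [p for p in query.residues
                    if first.number <= p.number <= last.number]
            mm_map = {p: (q, g) for p, q, g in cluster}
            parental = "".join(query.residues[p] for p in span)
            germ = "".join(
                mm_map[p][1] if p in mm_map
                else (germline.residues[p] if germline is not None else query.residues[p])
                for p in span
            )
            positions = span
        else:
            positions = [p for p, _, _ in cluster]
            parental = "".join(q for _, q, _ in cluster)
            germ = "".join(g for _, _, g in cluster)
        label = (str(first.number) if first.number == last.number
                 else f"{first.number}-{last.number}")
        regions.append(MutationRegion(label, positions, parental, germ))
    return regions


def enumerate_variants(
    parental: NumberedSequence,
    regions: Sequence[MutationRegion],
    include_lysine_parental: bool = False,
    parental_name: Optional[str] = None,
) -> VariantPanel:
    """Enumerate all 2^k parental/germline framework combinations.

    Variant names concatenate the residues at the signature positions of each
    region in order (a 4-position region contributes 4 letters, singletons
    one); a "-K" suffix marks the heavy-chain C-terminal-lysine-bearing
    duplicate of the parental, inserted right after the parental when
    requested. Combinations are ordered by the number of germlined regions,
    then by region order, matching the conventional panel layout.
    """
    k = len(regions)
    if not 1 <= k <= MAX_REGIONS:
        raise ValueError(f"number of regions must be in [1, {MAX_REGIONS}], got {k}")

    combos: List[Tuple[int, ...]] = []
    for size in range(k + 1):
        combos.extend(itertools.combinations(range(k), size))

    variants: List[VariantRecord] = []
    next_id = 1
    for combo in combos:
        residues = dict(parental.residues)
        for ridx in combo:
            region = regions[ridx]
            for pos, germ_res in zip(region.positions, region.germline_residues):
                residues[pos] = germ_res
        seq = NumberedSequence(chain=parental.chain, residues=residues,
                               source_id=parental.source_id)
        name = "".join(
            "".join(seq.residues[p] for p in region.positions) for region in regions
        )
        labels = tuple(regions[i].label for i in combo)
        variants.append(VariantRecord(next_id, name, labels, False, seq))
        next_id += 1
        if not combo and include_lysine_parental:
            variants.append(VariantRecord(next_id, f"{name}-K", labels, True, seq))
            next_id += 1

    return VariantPanel(
        parental_name=parental_name or variants[0].name,
        regions=list(regions),
        variants=variants,
    )


def load_toy_germlines(chain: Optional[str] = None) -> List[NumberedSequence]:
    """Load and number the bundled toy germline V-gene set.

    The set contains six synthetic kappa V genes (including an IGKV3-20-like
    entry) and one VH3-23-like heavy entry; it stands in for the public
    germline databases, which are not fetched.
    """
    out = []
    with resources.files("abframe").joinpath("data/germlines_toy.fasta").open() as fh:
        for record in SeqIO.parse(fh, "fasta"):
            rec_chain = "H" if record.id.startswith("HV") else "L"
            if chain is not None and rec_chain != chain:
                continue
            ns = assign_kabat_numbering(str(record.seq), rec_chain)
            ns.source_id = record.id
            out.append(ns)
    return out


def scan_report(query: NumberedSequence, match: GermlineMatch) -> str:
    """JSON report of a germline scan."""
    payload = {
        "query": query.source_id,
        "chain": query.chain,
        "germline": match.germline_id,
        "framework_identity_pct": round(match.framework_identity, 2),
        "total_identity_pct": round(match.total_identity, 2),
        "framework_mismatches": [
            {"kabat": str(p), "query": q, "germline": g} for p, q, g in match.mismatches
        ],
    }
    return json.dumps(payload, indent=2)
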