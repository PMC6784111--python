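"""Kabat numbering of antibody V domains.

Positions are assigned by global alignment of the query against a per-chain
consensus template, followed by region-wise renumbering: each framework or CDR
segment of the query is mapped onto its canonical Kabat span, with length
excess expressed as lettered insertions at the canonical insertion site of
that region and length deficits expressed as absent positions.

The templates are synthetic consensus-like sequences (kappa-I flavoured light
chain, VH3-flavoured heavy chain) constructed insertion-free, so the canonical
spans (e.g. the 70-position kappa FR1-FR3 framework) hold exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import total_ordering
from string import ascii_lowercase
from typing import Dict, List, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_ALPHABET = AMINO_ACIDS | {"X"}

# region name -> (start, end) in Kabat coordinates, per chain
REGION_SPANS: Dict[str, List[Tuple[str, int, int]]] = {
    "L": [
        ("FR1", 1, 23),
        ("CDR-L1", 24, 34),
        ("FR2", 35, 49),
        ("CDR-L2", 50, 56),
        ("FR3", 57, 88),
        ("CDR-L3", 89, 97),
        ("FR4", 98, 107),
    ],
    "H": [
        ("FR1", 1, 30),
        ("CDR-H1", 31, 35),
        ("FR2", 36, 49),
        ("CDR-H2", 50, 65),
        ("FR3", 66, 94),
        ("CDR-H3", 95, 102),
        ("FR4", 103, 113),
    ],
}

# canonical insertion anchors: region -> (anchor position, max insertion letters)
INSERTION_SITES: Dict[str, Dict[str, Tuple[int, int]]] = {
    "L": {"CDR-L1": (27, 6), "CDR-L3": (95, 6), "FR4": (106, 1)},
    "H": {"CDR-H1": (35, 2), "CDR-H2": (52, 3), "FR3": (82, 3), "CDR-H3": (100, 11)},
}

# Insertion-free consensus templates; concatenation of the region segments.
_L_SEGMENTS = {
    "FR1": "DIQMTQSPSSLSASVGDRVTITC",
    "CDR-L1": "RASQSVSSYLA",
    "FR2": "WYQQKPGKAPKLLIY",
    "CDR-L2": "GASSRAT",
    "FR3": "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC",
    "CDR-L3": "QQYGSSPRT",
    "FR4": "FGQGTKVEIK",
}
_H_SEGMENTS = {
    "FR1": "EVQLLESGGGLVQPGGSLRLSCAASGFTFS",
    "CDR-H1": "SYAMS",
    "FR2": "WVRQAPGKGLEWVS",
    "CDR-H2": "AISGSGGSTYYADSVK",
    "FR3": "GRFTISRDNSKNTLYLQMNSLRAEDTAVY",
    "CDR-H3": "DRGGYFDY",
    "FR4": "WGQGTLVTVSS",
}
CONSENSUS_TEMPLATES: Dict[str, str] = {
    "L": "".join(_L_SEGMENTS[name] for name, _, _ in REGION_SPANS["L"]),
    "H": "".join(_H_SEGMENTS[name] for name, _, _ in REGION_SPANS["H"]),
}

MIN_LENGTH, MAX_LENGTH = 80, 140
MIN_TEMPLATE_IDENTITY = 0.40


class InputError(ValueError):
    """Raised for malformed sequence input."""


class NumberingError(ValueError):
    """Raised when a query cannot be mapped onto the Kabat template."""


@total_ordering
@dataclass(frozen=True)
class KabatPosition:
    chain: str
    number: int
    insertion_code: str = ""

    def __post_init__(self):
        if self.chain not in ("L", "H"):
            raise InputError(f"chain must be 'L' or 'H', got {self.chain!r}")
        if not 1 <= self.number <= 113:
            raise InputError(f"Kabat number out of range: {self.number}")
        if self.insertion_code and self.insertion_code not in ascii_lowercase[:11]:
            raise InputError(f"invalid insertion code {self.insertion_code!r}")

    def _key(self):
        return (self.number, self.insertion_code)

    def __lt__(self, other: "KabatPosition"):
        if self.chain != other.chain:
            raise ValueError("cannot order positions of different chains")
        return self._key() < other._key()

    def __str__(self):
        return f"{self.chain}{self.number}{self.insertion_code}"


@dataclass
class NumberedSequence:
    """A V-domain sequence with residues keyed by Kabat position (ordered)."""

    chain: str
    residues: Dict[KabatPosition, str]
    source_id: str = ""

    def __post_init__(self):
        positions = list(self.residues)
        for prev, cur in zip(positions, positions[1:]):
            if not prev < cur:
                raise InputError("Kabat positions must be strictly increasing")
        for res in self.residues.values():
            if res not in EXTENDED_ALPHABET:
                raise InputError(f"invalid residue {res!r}")

    @property
    def sequence(self) -> str:
        return "".join(self.residues.values())

    @property
    def positions(self) -> List[KabatPosition]:
        return list(self.residues)

    def __len__(self):
        return len(self.residues)

    def region_of(self, pos: KabatPosition) -> str:
        return region_of_position(self.chain, pos.number)

    def to_table(self) -> List[Tuple[str, str]]:
        return [(str(p), r) for p, r in self.residues.items()]


def region_of_position(chain: str, number: int) -> str:
    for name, start, end in REGION_SPANS[chain]:
        if start <= number <= end:
            return name
    raise KeyError(f"position {number} outside chain {chain} numbering range")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # tolerate leading/trailing truncation of the query (e.g. germline V genes
    # that end within CDR3) without punishing terminal gaps
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNERS: Dict[str, Align.PairwiseAligner] = {}


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    bad = set(seq) - EXTENDED_ALPHABET
    if bad:
        raise InputError(f"non-amino-acid characters in input: {sorted(bad)}")
    if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
        raise InputError(
            f"sequence length {len(seq)} outside supported V-domain range "
            f"[{MIN_LENGTH}, {MAX_LENGTH}]"
        )
    return seq


def _region_counts(chain: str, seq: str) -> List[int]:
    """Count query residues falling into each template region.

    Uses the best global alignment against the chain consensus. Residues
    aligned to a template column inherit that column's region; unaligned
    (inserted) residues join the adjacent region, preferring a CDR neighbour.
    """
    if chain not in _ALIGNERS:
        _ALIGNERS[chain] = _make_aligner()
    template = CONSENSUS_TEMPLATES[chain]
    alignment = _ALIGNERS[chain].align(template, seq)[0]

    spans = REGION_SPANS[chain]
    # template index -> region index
    tmpl_region = []
    for ridx, (_, start, end) in enumerate(spans):
        tmpl_region.extend([ridx] * (end - start + 1))

    aligned_t, aligned_q = alignment[0], alignment[1]
    ti = qi = 0
    matches = aligned_cols = 0
    query_region = [-1] * len(seq)  # region index per query residue
    for tc, qc in zip(aligned_t, aligned_q):
        if tc != "-" and qc != "-":
            query_region[qi] = tmpl_region[ti]
            aligned_cols += 1
            if tc == qc:
                matches += 1
            ti += 1
            qi += 1
        elif qc == "-":
            ti += 1
        else:
            qi += 1  # insertion; region filled below

    if aligned_cols == 0 or matches / aligned_cols < MIN_TEMPLATE_IDENTITY:
        raise NumberingError(
            f"chain {chain}: query identity to the Kabat consensus template is "
            f"below {MIN_TEMPLATE_IDENTITY:.0%}; cannot number"
        )

    cdr_regions = {i for i, (name, _, _) in enumerate(spans) if name.startswith("CDR")}
    for i, ridx in enumerate(query_region):
        if ridx >= 0:
            continue
        prev_r = next((query_region[j] for j in range(i - 1, -1, -1) if query_region[j] >= 0), None)
        next_r = next((query_region[j] for j in range(i + 1, len(seq)) if query_region[j] >= 0), None)
        if prev_r is None and next_r is None:
            raise NumberingError(f"chain {chain}: no residues align to the template")
        if prev_r is None:
            query_region[i] = next_r
        elif next_r is None or prev_r == next_r:
            query_region[i] = prev_r
        elif next_r in cdr_regions and prev_r not in cdr_regions:
            query_region[i] = next_r
        else:
            query_region[i] = prev_r

    counts = [0] * len(spans)
    for ridx in query_region:
        counts[ridx] += 1
    return counts


def _number_region(
    chain: str, region: str, start: int, end: int, count: int,
    leading_partial: bool, trailing_partial: bool,
) -> List[KabatPosition]:
    """Assign Kabat positions to `count` residues of one region."""
    span = end - start + 1
    anchor = INSERTION_SITES[chain].get(region)
    if count == span:
        return [KabatPosition(chain, n) for n in range(start, end + 1)]
    if count > span:
        if anchor is None:
            raise NumberingError(
                f"chain {chain}: {count - span} insertion(s) required in region "
                f"{region}, which has no canonical insertion site"
            )
        site, max_letters = anchor
        extra = count - span
        if extra > max_letters:
            raise NumberingError(
                f"chain {chain}: {extra} insertions at Kabat {site} exceed the "
                f"canonical maximum of {max_letters}"
            )
        positions = [KabatPosition(chain, n) for n in range(start, site + 1)]
        positions += [KabatPosition(chain, site, ascii_lowercase[i]) for i in range(extra)]
        positions += [KabatPosition(chain, n) for n in range(site + 1, end + 1)]
        return positions
    # count < span: positions absent
    missing = span - count
    if trailing_partial:          # C-terminal truncation: keep the leading run
        numbers = range(start, start + count)
    elif leading_partial:         # N-terminal truncation: keep the trailing run
        numbers = range(end - count + 1, end + 1)
    else:
        # internal deletion: omit the run just after the canonical anchor,
        # or at the region end when the region has no anchor
        if anchor is not None:
            site = anchor[0]
            omit_start = min(site + 1, end - missing + 1)
        else:
            omit_start = end - missing + 1
        omitted = set(range(omit_start, omit_start + missing))
        numbers = [n for n in range(start, end + 1) if n not in omitted]
    return [KabatPosition(chain, n) for n in numbers]


def assign_kabat_numbering(sequence: str, chain: str) -> NumberedSequence:
    """Map a V-domain amino-acid sequence onto Kabat positions.

    Parameters
    ----------
    sequence : str
        Amino-acid sequence (20 standard letters plus X), length 80-140.
    chain : {"L", "H"}
        Light or heavy chain.

    Returns
    -------
    NumberedSequence
        Residues keyed by strictly increasing Kabat positions; lettered
        insertion codes appear only at canonical sites.
    """
    if chain not in REGION_SPANS:
        raise InputError(f"chain must be 'L' or 'H', got {chain!r}")
    seq = _validate_sequence(sequence)
    counts = _region_counts(chain, seq)

    nonempty = [i for i, c in enumerate(counts) if c > 0]
    first_r, last_r = nonempty[0], nonempty[-1]

    residues: Dict[KabatPosition, str] = {}
    offset = 0
    for ridx, (name, start, end) in enumerate(REGION_SPANS[chain]):
        count = counts[ridx]
        if count == 0:
            continue
        positions = _number_region(
            chain, name, start, end, count,
            leading_partial=(ridx == first_r),
            trailing_partial=(ridx == last_r),
        )
        for pos, res in zip(positions, seq[offset:offset + count]):
            residues[pos] = res
        offset += count
    return NumberedSequence(chain=chain, residues=residues)


def delineate_regions(ns: NumberedSequence) -> Dict[str, str]:
    """Split a numbered sequence into its framework and CDR segments.

    The concatenation of the returned segments, in span order, reproduces the
    input sequence exactly.
    """
    out = {name: "" for name, _, _ in REGION_SPANS[ns.chain]}
    for pos, res in ns.residues.items():
        out[region_of_position(ns.chain, pos.number)] += res
    return out


def region_report(ns: NumberedSequence) -> str:
    """JSON report of region boundaries, lengths and sequences."""
    regions = delineate_regions(ns)
    payload = {
        "chain": ns.chain,
        "length": len(ns),
        "regions": [
            {"name": name, "kabat_span": f"{start}-{end}", "length": len(regions[name]),
             "sequence": regions[name]}
            for name, start, end in REGION_SPANS[ns.chain]
        ],
    }
    return json.dumps(payload, indent=2)
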