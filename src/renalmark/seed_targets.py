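"""miRNA seed-site detection in 3'UTRs and per-family target indexing.

Canonical seed sites are short Watson-Crick matches in the UTR to the
miRNA seed (bases 2-8 of the mature sequence, 5'->3'). On the UTR
sense strand the four canonical site types are:

    7mer-m8 : reverse complement of mature[1:8)   (7 nt)
    8mer    : 7mer-m8 followed by an A            (8 nt)
    6mer    : reverse complement of mature[1:7)   (6 nt)
    7mer-A1 : 6mer followed by an A               (7 nt)

ordered by strength 8mer > 7mer-m8 > 7mer-A1 > 6mer. The trailing A
opposite mature position 1 is a literal adenosine in the UTR (not a
complementarity requirement). U and T are interchangeable; N never
matches. Positions are 0-based, half-open on the sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MirnaFamily",
    "SeedSite",
    "TargetIndex",
    "SITE_TYPES_BY_STRENGTH",
    "reverse_complement",
    "seed_match_patterns",
    "find_sites",
    "build_target_index",
    "read_families",
    "write_families",
]

#: strongest first
SITE_TYPES_BY_STRENGTH = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the DNA alphabet (U mapped to T first)."""
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


@dataclass
class MirnaFamily:
    """A miRNA family named by its shared seed.

    mature: representative mature sequence, 5'->3', length >= 8,
    over {A,C,G,U} (T accepted). The seed is mature[1:8).
    """

    name: str
    mature: str

    def __post_init__(self) -> None:
        self.mature = self.mature.upper().replace("T", "U")
        if len(self.mature) < 8:
            raise ValueError(f"family {self.name!r}: mature sequence shorter than 8 nt")
        bad = set(self.mature) - set("ACGU")
        if bad:
            raise ValueError(f"family {self.name!r}: invalid bases {sorted(bad)}")

    @property
    def seed(self) -> str:
        return self.mature[1:8]


@dataclass(frozen=True)
class SeedSite:
    """One seed-site occurrence on a UTR sense strand, [start, end)."""

    gene: str
    family: str
    site_type: str
    start: int
    end: int


def seed_match_patterns(family: MirnaFamily) -> dict[str, str]:
    """DNA patterns (UTR sense strand) for the four canonical site types."""
    m8 = reverse_complement(family.mature[1:8])
    six = reverse_complement(family.mature[1:7])
    # identities: 6mer == m8[1:], 7mer-A1 == 6mer + "A", 8mer == m8 + "A"
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": six + "A", "6mer": six}


def _occurrences(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def find_sites(utr: str, family: MirnaFamily, gene: str = "") -> list[SeedSite]:
    """All seed-site occurrences for one family in one UTR.

    Overlapping occurrences are each reported, but longest-match
    precedence applies at a locus: a weaker-type match wholly
    contained within a reported stronger-type site is suppressed, so
    one physical site is never double-counted (an 8mer swallows the
    7mer-m8/7mer-A1/6mer it contains, a 7mer its 6mer). N never
    matches. Returned sites are sorted by start, strongest first on
    ties.
    """
    utr = utr.upper().replace("U", "T")
    patterns = seed_match_patterns(family)
    kept: list[SeedSite] = []
    intervals: list[tuple[int, int]] = []  # of stronger sites already kept
    for st in SITE_TYPES_BY_STRENGTH:
        pat = patterns[st]
        new_iv = []
        for start in _occurrences(utr, pat):
            end = start + len(pat)
            if any(a <= start and end <= b for a, b in intervals):
                continue
            kept.append(SeedSite(gene=gene, family=family.name, site_type=st,
                                 start=start, end=end))
            new_iv.append((start, end))
        intervals.extend(new_iv)
    order = {st: i for i, st in enumerate(SITE_TYPES_BY_STRENGTH)}
    kept.sort(key=lambda s: (s.start, order[s.site_type]))
    return kept


@dataclass
class TargetIndex:
    """family -> target gene set, with per-gene site evidence."""

    min_site_type: str
    targets: dict = field(default_factory=dict)   # family -> set of genes
    sites: dict = field(default_factory=dict)     # (family, gene) -> list[SeedSite]
    families: list = field(default_factory=list)

    def genes_for(self, family: str) -> set:
        return set(self.targets.get(family, set()))

    def count(self, family: str) -> int:
        return len(self.targets.get(family, set()))


def build_target_index(
    utrs: list[tuple[str, str]],
    families: list[MirnaFamily],
    min_site_type: str = "7mer-A1",
) -> TargetIndex:
    """Scan every UTR for every family; index genes with a qualifying site.

    A gene enters a family's target set iff it has at least one site
    of at least `min_site_type` strength. Duplicate gene ids in the
    UTR collection are rejected.
    """
    if min_site_type not in SITE_TYPES_BY_STRENGTH:
        raise ValueError(f"unknown site type {min_site_type!r}")
    seen = set()
    for gid, _ in utrs:
        if gid in seen:
            raise ValueError(f"duplicate gene id in UTR collection: {gid!r}")
        seen.add(gid)
    cutoff_rank = SITE_TYPES_BY_STRENGTH.index(min_site_type)
    index = TargetIndex(min_site_type=min_site_type, families=[f.name for f in families])
    for fam in families:
        index.targets[fam.name] = set()
    for gid, seq in utrs:
        for fam in families:
            sites = find_sites(seq, fam, gene=gid)
            if sites:
                index.sites[(fam.name, gid)] = sites
            if any(SITE_TYPES_BY_STRENGTH.index(s.site_type) <= cutoff_rank for s in sites):
                index.targets[fam.name].add(gid)
    return index


def read_families(path) -> list[MirnaFamily]:
    """Read a families TSV: family name TAB mature sequence (5'->3')."""
    fams = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>mature sequence'")
            fams.append(MirnaFamily(name=parts[0], mature=parts[1]))
    return fams


def write_families(families: list[MirnaFamily], path) -> None:
    with open(path, "w") as fh:
        for fam in families:
            fh.write(f"{fam.name}\t{fam.mature}\n")
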