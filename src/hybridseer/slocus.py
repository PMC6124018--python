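"""S-locus haplotype classification and self-incompatibility analysis.

In *Prunus*, gametophytic self-incompatibility (GSI) is controlled by the
S-locus: a pistil-expressed S-RNase completely linked to a pollen-expressed
S-haplotype-specific F-box (SFB). Pollen is rejected whenever its single S
haplotype matches either S haplotype of the pistil, which enforces S-locus
heterozygosity and out-crossing — and leaves inter-specific crosses that
share no S haplotype fully compatible. This module clusters S-allele
sequences into haplotype classes, verifies per-accession heterozygosity and
parent-offspring haplotype transmission under GSI, predicts cross
compatibility, and builds the shared-haplotype network of a population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from Bio import Align

from hybridseer.io import read_fasta, write_tsv

logger = logging.getLogger(__name__)

GENES = ("S-RNase", "SFB")


class SLocusError(ValueError):
    pass


@dataclass
class SAllele:
    accession: str
    gene: str  # "S-RNase" | "SFB"
    locus_copy: int  # 1 | 2
    sequence: str

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise SLocusError(f"unknown S gene {self.gene!r}")
        if self.locus_copy not in (1, 2):
            raise SLocusError(f"locus_copy must be 1 or 2, got {self.locus_copy}")
        if not self.sequence:
            raise SLocusError(f"{self.accession}|{self.gene}: empty sequence")


def parse_allele_fasta(path) -> list[SAllele]:
    """Read S alleles from FASTA with ``accession|gene|copy`` headers."""
    alleles = []
    for name, seq in read_fasta(path).items():
        parts = name.split("|")
        if len(parts) != 3:
            raise SLocusError(f"{path}: header {name!r} is not accession|gene|copy")
        acc, gene, copy = parts
        alleles.append(SAllele(acc, gene, int(copy), seq))
    return alleles


# ---------------------------------------------------------------------------
# Pairwise identity

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2
try:
    _aligner.end_insertion_score = 0
    _aligner.end_deletion_score = 0
except AttributeError:  # Biopython < 1.86 naming
    _aligner.target_end_gap_score = 0
    _aligner.query_end_gap_score = 0


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity with free end gaps.

    Scoring: match +1, mismatch -1, gap -2; identity is matches over
    alignment columns excluding terminal gap columns (alleles of one class
    may differ modestly in length).
    """
    aln = _aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    lo = 0
    hi = len(s1)
    while lo < hi and (s1[lo] == "-" or s2[lo] == "-"):
        lo += 1
    while hi > lo and (s1[hi - 1] == "-" or s2[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    matches = sum(1 for x, y in zip(s1[lo:hi], s2[lo:hi]) if x == y and x != "-")
    return matches / (hi - lo)


# ---------------------------------------------------------------------------
# Clustering into haplotype classes


@dataclass
class SHaplotypeAssignment:
    """Accession -> unordered pair of S haplotype class labels."""

    assignments: dict[str, tuple[str, str]]
    classes: dict[str, list[tuple[str, int]]]  # label -> [(accession, copy)]
    flags: dict[str, list[str]] = field(default_factory=dict)
    identity_threshold: float = 0.99

    def pair(self, accession: str) -> tuple[str, str]:
        return self.assignments[accession]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (acc, c1, c2, ";".join(self.flags.get(acc, [])))
            for acc, (c1, c2) in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["accession", "class1", "class2", "flags"])

    def to_tsv(self, path) -> None:
        write_tsv(
            path,
            self.to_frame(),
            comments=[f"identity_threshold={self.identity_threshold}"],
        )


def cluster_alleles(
    alleles: list[SAllele], identity_threshold: float = 0.99
) -> SHaplotypeAssignment:
    """Single-linkage clustering of linked S-RNase/SFB pairs into classes.

    The clustered unit is a haplotype: the S-RNase and SFB carried by one
    locus copy of one accession. Two haplotypes join one class only when
    BOTH genes reach *identity_threshold*; a pair concordant at one gene but
    not the other is logged as a putative recombinant S-locus. Labels
    ``S1..Sn`` are ordered by descending class size, then first appearance.
    An accession whose two copies land in one class is flagged a putative
    homozygote (a GSI violation) but kept.
    """
    units: dict[tuple[str, int], dict[str, str]] = {}
    for al in alleles:
        units.setdefault((al.accession, al.locus_copy), {})[al.gene] = al.sequence
    keys = list(units)
    for key, genes in units.items():
        missing = set(GENES) - set(genes)
        if missing:
            raise SLocusError(f"{key[0]} copy {key[1]}: missing {sorted(missing)}")
    accessions: dict[str, list[tuple[str, int]]] = {}
    for acc, copy in keys:
        accessions.setdefault(acc, []).append((acc, copy))
    for acc, copies in accessions.items():
        if len(copies) != 2:
            raise SLocusError(f"{acc}: expected 2 locus copies, found {len(copies)}")

    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, ki in enumerate(keys):
        for kj in keys[i + 1 :]:
            id_rnase = pairwise_identity(units[ki]["S-RNase"], units[kj]["S-RNase"])
            id_sfb = pairwise_identity(units[ki]["SFB"], units[kj]["SFB"])
            hit_r = id_rnase >= identity_threshold
            hit_f = id_sfb >= identity_threshold
            if hit_r and hit_f:
                parent[find(ki)] = find(kj)
            elif hit_r != hit_f:
                logger.warning(
                    "putative recombinant S-locus: %s ~ %s concordant at one gene only",
                    ki, kj,
                )

    members: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for k in keys:  # first-seen order preserved
        members.setdefault(find(k), []).append(k)
    roots = sorted(
        members,
        key=lambda r: (-len(members[r]), keys.index(members[r][0])),
    )
    labels = {r: f"S{i + 1}" for i, r in enumerate(roots)}
    classes = {labels[r]: members[r] for r in roots}

    assignments: dict[str, tuple[str, str]] = {}
    flags: dict[str, list[str]] = {}
    for acc, copies in accessions.items():
        copies = sorted(copies, key=lambda k: k[1])
        pair = tuple(labels[find(k)] for k in copies)
        assignments[acc] = pair
        if pair[0] == pair[1]:
            flags.setdefault(acc, []).append("putative_homozygote")
            logger.warning("%s: both S-locus copies in class %s", acc, pair[0])
    return SHaplotypeAssignment(
        assignments=assignments,
        classes=classes,
        flags=flags,
        identity_threshold=identity_threshold,
    )


# ---------------------------------------------------------------------------
# Trio consistency and cross compatibility


@dataclass
class TrioResult:
    consistent: bool
    donors: dict[str, str] | None  # {"mother": class, "father": class}


def check_trio(
    child: tuple[str, str], mother: tuple[str, str], father: tuple[str, str]
) -> TrioResult:
    """Test parent-offspring S-haplotype transmission under GSI.

    Consistent iff the child's pair consists of one maternal and one
    paternal class AND the paternally donated class is absent from the seed
    parent (rejected pollen cannot fertilise). Both donor assignments are
    enumerated; the first consistent one is reported.
    """
    mother_set, father_set = set(mother), set(father)
    for maternal_donation, paternal_donation in (child, child[::-1]):
        if (
            maternal_donation in mother_set
            and paternal_donation in father_set
            and paternal_donation not in mother_set
        ):
            return TrioResult(
                consistent=True,
                donors={"mother": maternal_donation, "father": paternal_donation},
            )
    return TrioResult(consistent=False, donors=None)


def predict_cross(
    seed_parent: tuple[str, str], pollen_parent: tuple[str, str]
) -> str:
    """GSI compatibility of a cross, from the pollen parent's two S classes.

    Pollen carrying a class present in the seed parent is rejected:
    0 transmittable pollen classes -> incompatible, 1 -> semi_compatible,
    2 -> fully_compatible.
    """
    transmittable = sum(1 for c in pollen_parent if c not in set(seed_parent))
    return ("incompatible", "semi_compatible", "fully_compatible")[transmittable]


# ---------------------------------------------------------------------------
# Shared-haplotype network


def build_network(
    assignment: SHaplotypeAssignment,
    metadata: pd.DataFrame | None = None,
) -> nx.Graph:
    """Connect accessions that share an S haplotype class.

    Nodes are accessions (with taxon/location attributes when *metadata*
    provides ``accession`` plus extra columns); an edge exists iff two
    accessions' class sets intersect, labeled with the comma-joined shared
    classes. Node and edge orders are deterministic.
    """
    g = nx.Graph()
    meta = (
        metadata.set_index("accession").to_dict("index") if metadata is not None else {}
    )
    for acc in sorted(assignment.assignments):
        g.add_node(acc, **{k: str(v) for k, v in meta.get(acc, {}).items()})
    accs = sorted(assignment.assignments)
    for i, a in enumerate(accs):
        for b in accs[i + 1 :]:
            shared = sorted(set(assignment.pair(a)) & set(assignment.pair(b)))
            if shared:
                g.add_edge(a, b, shared=",".join(shared))
    return g


def write_edges_tsv(path, g: nx.Graph) -> None:
    rows = [
        (a, b, data["shared"]) for a, b, data in sorted(g.edges(data=True))
    ]
    write_tsv(path, pd.DataFrame(rows, columns=["accession1", "accession2", "shared"]))


def write_graphml(path, g: nx.Graph) -> None:
    nx.write_graphml(g, path)
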