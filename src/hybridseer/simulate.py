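"""Ground-truthed simulator of an inter-specific hybrid cross.

The generator emulates the statistical structure the downstream analyses
assume: a shared ancestral chromosome, two parental species diverged by
i.i.d. substitutions/short InDels, within-species heterozygosity between each
parent's two haplotypes, an F1 offspring carrying exactly one haplotype from
each parent (or a BC1 backcross carrying a recombined F1 gamete plus a
recurrent maternal haplotype), non-overlapping gene models, and uniform-start
error-bearing single-end short reads.

Everything is represented in the shared ancestral coordinate frame: variants
are recorded against the ancestral sequence, gene annotations and pileup
sites use ancestral positions, and reads are mapped back through per-
haplotype InDel offset maps. A read-origin sidecar (true haplotype + start
per read) replaces an aligner on the synthetic path; real data enters the
downstream modules through VCF/pileup files instead.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hybridseer.config import SimulationConfig
from hybridseer.io import write_fasta, write_gff3, write_tsv

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Sequence codes

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_seq(seq: str | bytes) -> np.ndarray:
    """Encode A/C/G/T (case-insensitive) to uint8 codes 0-3 (other bases 4)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _ENC[np.frombuffer(seq, dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode()


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Variant sets and haplotypes


@dataclass
class VariantSet:
    """Variants of one haplotype relative to the ancestral sequence.

    ``pos`` (ancestral, 0-based, sorted), ``ref_len`` (ancestral bases
    consumed) and ``alts`` (replacement code arrays) fully determine the
    haplotype. Variant footprints never overlap.
    """

    pos: np.ndarray
    ref_len: np.ndarray
    alts: list

    @classmethod
    def empty(cls) -> "VariantSet":
        return cls(np.empty(0, np.int64), np.empty(0, np.int64), [])

    @property
    def n(self) -> int:
        return len(self.pos)

    @property
    def is_snp(self) -> np.ndarray:
        alt_len = np.fromiter((len(a) for a in self.alts), np.int64, self.n)
        return (self.ref_len == 1) & (alt_len == 1)

    def snp_alt_codes(self) -> np.ndarray:
        """Alt code per variant; -1 for non-SNP rows."""
        out = np.full(self.n, -1, np.int64)
        for i, a in enumerate(self.alts):
            if self.ref_len[i] == 1 and len(a) == 1:
                out[i] = int(a[0])
        return out

    def realize(self, ancestral: np.ndarray) -> np.ndarray:
        """Apply the variants to the ancestral sequence."""
        pieces = []
        prev = 0
        for p, rl, alt in zip(self.pos, self.ref_len, self.alts):
            pieces.append(ancestral[prev:p])
            pieces.append(alt)
            prev = p + rl
        pieces.append(ancestral[prev:])
        return np.concatenate(pieces) if pieces else ancestral.copy()

    # -- InDel offset maps ---------------------------------------------------

    def _indel_map(self) -> tuple[np.ndarray, np.ndarray]:
        alt_len = np.fromiter((len(a) for a in self.alts), np.int64, self.n)
        indel = alt_len != self.ref_len
        delta = alt_len[indel] - self.ref_len[indel]
        anc_break = self.pos[indel] + self.ref_len[indel]
        cum = np.concatenate([[0], np.cumsum(delta)])
        return anc_break, cum

    def anc_to_hap(self, anc_pos: np.ndarray) -> np.ndarray:
        """Map ancestral positions (outside InDel footprints) to haplotype."""
        anc_break, cum = self._indel_map()
        idx = np.searchsorted(anc_break, anc_pos, side="right")
        return np.asarray(anc_pos) + cum[idx]

    def hap_to_anc(self, hap_pos: np.ndarray) -> np.ndarray:
        """Map haplotype positions back to ancestral (exact between InDels)."""
        anc_break, cum = self._indel_map()
        hap_break = anc_break + cum[1:]
        idx = np.searchsorted(hap_break, hap_pos, side="right")
        return np.asarray(hap_pos) - cum[idx]

    def allele_at(self, ancestral: np.ndarray, sites: np.ndarray) -> np.ndarray:
        """Base code of this haplotype at ancestral substitution positions."""
        sites = np.asarray(sites, dtype=np.int64)
        out = ancestral[sites].astype(np.int64)
        if self.n == 0 or sites.size == 0:
            return out
        j = np.searchsorted(self.pos, sites)
        j_c = np.minimum(j, self.n - 1)
        snp_alt = self.snp_alt_codes()
        hit = (self.pos[j_c] == sites) & (snp_alt[j_c] >= 0)
        out[hit] = snp_alt[j_c[hit]]
        return out

    def restrict(self, lo: int, hi: int) -> "VariantSet":
        m = (self.pos >= lo) & (self.pos < hi)
        return VariantSet(self.pos[m], self.ref_len[m],
                          [a for a, keep in zip(self.alts, m) if keep])

    @staticmethod
    def merge(*sets: "VariantSet") -> "VariantSet":
        pos = np.concatenate([s.pos for s in sets])
        ref_len = np.concatenate([s.ref_len for s in sets])
        alts = [a for s in sets for a in s.alts]
        order = np.argsort(pos, kind="stable")
        return VariantSet(pos[order], ref_len[order], [alts[i] for i in order])


@dataclass
class DiploidGenome:
    """A diploid accession: two haplotypes over a shared ancestral frame."""

    label: str
    ancestral: np.ndarray
    hap: dict[str, VariantSet]
    seq_name: str = "chr1"
    _seq_cache: dict = field(default_factory=dict, repr=False)

    def sequence(self, which: str) -> np.ndarray:
        if which not in self._seq_cache:
            self._seq_cache[which] = self.hap[which].realize(self.ancestral)
        return self._seq_cache[which]

    def hap_length(self, which: str) -> int:
        return len(self.sequence(which))

    def same_frame(self, other: "DiploidGenome") -> bool:
        return self.ancestral is other.ancestral or np.array_equal(
            self.ancestral, other.ancestral
        )

    def variant_list(self) -> pd.DataFrame:
        """Differences between the haplotypes, in haplotype-a coordinates.

        Columns ``pos_a, ref, alt``: replacing ``ref`` by ``alt`` at ``pos_a``
        in haplotype a (applied right to left) reconstructs haplotype b.
        """
        a, b = self.hap["a"], self.hap["b"]
        positions = np.union1d(a.pos, b.pos)
        rows = []
        a_alt = {int(p): (int(r), alt) for p, r, alt in zip(a.pos, a.ref_len, a.alts)}
        b_alt = {int(p): (int(r), alt) for p, r, alt in zip(b.pos, b.ref_len, b.alts)}
        anc = self.ancestral
        for p in positions:
            p = int(p)
            rl_a, alt_a = a_alt.get(p, (1, anc[p : p + 1]))
            rl_b, alt_b = b_alt.get(p, (1, anc[p : p + 1]))
            w = max(rl_a, rl_b, 1)
            ref = decode_seq(np.concatenate([alt_a, anc[p + rl_a : p + w]]))
            alt = decode_seq(np.concatenate([alt_b, anc[p + rl_b : p + w]]))
            if ref == alt:
                continue
            pos_a = int(a.anc_to_hap(np.array([p]))[0])
            rows.append((pos_a, ref, alt))
        return pd.DataFrame(rows, columns=["pos_a", "ref", "alt"])

    def reconstruct_b_from_a(self) -> np.ndarray:
        """Apply :meth:`variant_list` to haplotype a; used by recovery tests."""
        seq = decode_seq(self.sequence("a"))
        for row in self.variant_list().sort_values("pos_a", ascending=False).itertuples():
            seq = seq[: row.pos_a] + row.alt + seq[row.pos_a + len(row.ref):]
        return encode_seq(seq)

    def write_fasta(self, path) -> None:
        write_fasta(
            path,
            [
                (f"{self.label}_hap_a {self.seq_name}", decode_seq(self.sequence("a"))),
                (f"{self.label}_hap_b {self.seq_name}", decode_seq(self.sequence("b"))),
            ],
        )


@dataclass
class TruthTable:
    """Simulator-emitted ground truth consumed by recovery tests."""

    genes: pd.DataFrame  # gene_id, donor_hap_a, donor_hap_b, diagnostic_snps
    true_haploid_size: int
    donor_breaks: np.ndarray  # hap-a donor switch positions (BC1)
    donor_start: str  # donor of hap a at position 0
    true_s_haplotypes: dict = field(default_factory=dict)

    def donor_at(self, pos: np.ndarray) -> np.ndarray:
        """Donor of haplotype a at ancestral positions."""
        k = np.searchsorted(self.donor_breaks, np.asarray(pos), side="right")
        other = "paternal" if self.donor_start == "maternal" else "maternal"
        return np.where(k % 2 == 0, self.donor_start, other)

    def n_donor_switches(self) -> int:
        return len(self.donor_breaks)

    def to_tsv(self, path) -> None:
        df = self.genes.rename(
            columns={"donor_hap_a": "donor_hapA", "donor_hap_b": "donor_hapB"}
        )
        write_tsv(path, df, comments=[f"true_haploid_size={self.true_haploid_size}"])


# ---------------------------------------------------------------------------
# Parents

_INDEL_MAX = 10


def simulate_parents(
    config: SimulationConfig,
) -> tuple[DiploidGenome, DiploidGenome, np.ndarray]:
    """Simulate the two parental diploids and their shared ancestor.

    Divergence, maternal-het and paternal-het variant positions are drawn
    jointly without replacement so realized per-category counts are exactly
    binomial and no two variants share a position. A variant is promoted to a
    1-10 bp InDel (probability ``indel_fraction``) only if the next variant
    site is more than 10 bp away, so footprints never overlap.
    """
    G = config.genome_length
    anc = config.rng("ancestral").integers(0, 4, G, dtype=np.uint8)
    rng = config.rng("variants")
    d, h = config.interspecies_divergence, config.intraspecies_heterozygosity

    n_div = rng.binomial(G, d)
    n_het_m = rng.binomial(G, h)
    n_het_p = rng.binomial(G, h)
    total = n_div + n_het_m + n_het_p
    all_pos = rng.choice(G, size=total, replace=False)
    div_pos = all_pos[:n_div]
    het_m_pos = all_pos[n_div : n_div + n_het_m]
    het_p_pos = all_pos[n_div + n_het_m :]

    order = np.argsort(all_pos)
    sorted_pos = all_pos[order]
    gap_next = np.diff(np.concatenate([sorted_pos, [G]]))
    eligible_sorted = (gap_next > _INDEL_MAX) & (sorted_pos + _INDEL_MAX < G)
    eligible = np.empty(total, dtype=bool)
    eligible[order] = eligible_sorted
    is_indel = eligible & (rng.random(total) < config.indel_fraction)

    def make_variants(pos_subset: np.ndarray, indel_subset: np.ndarray) -> VariantSet:
        order = np.argsort(pos_subset)
        pos_s = pos_subset[order]
        indel_s = indel_subset[order]
        ref_len = np.ones(len(pos_s), np.int64)
        alts: list = [None] * len(pos_s)
        for i, (p, ind) in enumerate(zip(pos_s, indel_s)):
            if ind:
                length = int(rng.integers(1, _INDEL_MAX + 1))
                if rng.integers(2) == 0:  # deletion
                    ref_len[i] = length
                    alts[i] = np.empty(0, np.uint8)
                else:  # insertion before the ancestral base at p
                    ref_len[i] = 0
                    alts[i] = rng.integers(0, 4, length, dtype=np.uint8)
            else:
                alts[i] = np.array(
                    [(int(anc[p]) + int(rng.integers(1, 4))) % 4], dtype=np.uint8
                )
        return VariantSet(pos_s, ref_len, alts)

    # which species deviates at each divergence site (50/50)
    dev_maternal = rng.integers(2, size=n_div).astype(bool)
    div_idx = np.arange(n_div)
    div_m = make_variants(div_pos[dev_maternal], is_indel[div_idx][dev_maternal])
    div_p = make_variants(div_pos[~dev_maternal], is_indel[div_idx][~dev_maternal])
    het_m = make_variants(het_m_pos, is_indel[n_div : n_div + n_het_m])
    het_p = make_variants(het_p_pos, is_indel[n_div + n_het_m :])

    maternal = DiploidGenome(
        "maternal", anc, {"a": div_m, "b": VariantSet.merge(div_m, het_m)}
    )
    paternal = DiploidGenome(
        "paternal", anc, {"a": div_p, "b": VariantSet.merge(div_p, het_p)}
    )
    return maternal, paternal, anc


def diagnostic_sites(
    maternal: DiploidGenome, paternal: DiploidGenome
) -> pd.DataFrame:
    """Substitution sites where the two species consensus sequences differ.

    Returns columns ``pos, allele_m, allele_p`` (base codes). Haplotype a of
    each parent is the species consensus (heterozygous variants ride on
    haplotype b), so diagnostic sites are the SNP-type divergence variants.
    """
    if not maternal.same_frame(paternal):
        raise SimulationError("parents do not share a coordinate system")
    vs_m, vs_p = maternal.hap["a"], paternal.hap["a"]
    pos = np.union1d(vs_m.pos[vs_m.is_snp], vs_p.pos[vs_p.is_snp])
    allele_m = vs_m.allele_at(maternal.ancestral, pos)
    allele_p = vs_p.allele_at(paternal.ancestral, pos)
    keep = allele_m != allele_p
    return pd.DataFrame(
        {"pos": pos[keep], "allele_m": allele_m[keep], "allele_p": allele_p[keep]}
    )


# ---------------------------------------------------------------------------
# Offspring


def simulate_offspring(
    maternal: DiploidGenome,
    paternal: DiploidGenome,
    config: SimulationConfig,
    genes: pd.DataFrame | None = None,
) -> tuple[DiploidGenome, TruthTable]:
    """Simulate an F1 or BC1 offspring and its truth table.

    F1: haplotype a is one randomly chosen maternal haplotype, haplotype b
    one paternal haplotype. BC1: haplotype a is a recombined F1 gamete
    (crossovers ~ Poisson(``bc_recomb_rate``)), haplotype b a recurrent
    maternal haplotype. When *genes* is given the truth table records each
    gene's donor (at the gene midpoint) and diagnostic-SNP count.
    """
    if not maternal.same_frame(paternal):
        raise SimulationError("parents do not share a coordinate system")
    rng = config.rng("offspring")
    G = len(maternal.ancestral)
    m_hap = "ab"[int(rng.integers(2))]
    p_hap = "ab"[int(rng.integers(2))]
    donated_m = maternal.hap[m_hap]
    donated_p = paternal.hap[p_hap]

    if config.offspring_type == "F1":
        child = DiploidGenome(
            "F1", maternal.ancestral, {"a": donated_m, "b": donated_p}
        )
        breaks = np.empty(0, np.int64)
        donor_start = "maternal"
        hap_b_donor = "paternal"
    else:  # BC1 toward the maternal recurrent parent
        n_x = int(rng.poisson(config.bc_recomb_rate))
        breaks = np.sort(rng.integers(1, G, size=n_x))
        donor_start = "maternal" if rng.integers(2) == 0 else "paternal"
        sources = {"maternal": donated_m, "paternal": donated_p}
        bounds = np.concatenate([[0], breaks, [G]])
        segs = []
        cur = donor_start
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            segs.append(sources[cur].restrict(int(lo), int(hi)))
            cur = "paternal" if cur == "maternal" else "maternal"
        gamete = VariantSet.merge(*segs)
        recurrent = maternal.hap["ab"[int(rng.integers(2))]]
        child = DiploidGenome(
            "BC1", maternal.ancestral, {"a": gamete, "b": recurrent}
        )
        hap_b_donor = "maternal"

    truth = TruthTable(
        genes=pd.DataFrame(
            columns=["gene_id", "donor_hap_a", "donor_hap_b", "diagnostic_snps"]
        ),
        true_haploid_size=int(
            round((child.hap_length("a") + child.hap_length("b")) / 2)
        ),
        donor_breaks=breaks,
        donor_start=donor_start,
    )

    if genes is not None and len(genes):
        diag = child_diagnostic_sites(child, maternal, paternal)
        mids = ((genes["start"] + genes["end"]) // 2).to_numpy()
        donors_a = truth.donor_at(mids)
        counts = np.zeros(len(genes), np.int64)
        if len(diag):
            pos_sorted = np.sort(diag["pos"].to_numpy())
            lo = np.searchsorted(pos_sorted, genes["start"].to_numpy())
            hi = np.searchsorted(pos_sorted, genes["end"].to_numpy())
            counts = hi - lo
        truth.genes = pd.DataFrame(
            {
                "gene_id": genes["gene_id"].to_numpy(),
                "donor_hap_a": donors_a,
                "donor_hap_b": hap_b_donor,
                "diagnostic_snps": counts,
            }
        )
    return child, truth


def child_diagnostic_sites(
    child: DiploidGenome, maternal: DiploidGenome, paternal: DiploidGenome
) -> pd.DataFrame:
    """Species-diagnostic substitution sites where the child is heterozygous."""
    diag = diagnostic_sites(maternal, paternal)
    pos = diag["pos"].to_numpy()
    a = child.hap["a"].allele_at(child.ancestral, pos)
    b = child.hap["b"].allele_at(child.ancestral, pos)
    keep = a != b
    out = diag.loc[keep].copy()
    out["allele_a"] = a[keep]
    out["allele_b"] = b[keep]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene annotation


def emit_gene_annotation(
    config: SimulationConfig, seq_name: str = "chr1"
) -> pd.DataFrame:
    """Place ``n_genes`` non-overlapping gene intervals on the ancestral frame.

    Lengths are normal around ``gene_length_mean`` (truncated to +-50%); the
    remaining slack is split into inter-genic gaps multinomially. Returns a
    0-based half-open frame ``gene_id, seq, start, end`` sorted by start.
    """
    rng = config.rng("genes")
    n, G = config.n_genes, config.genome_length
    if n == 0:
        return pd.DataFrame(columns=["gene_id", "seq", "start", "end"])
    mean = config.gene_length_mean
    lengths = np.clip(
        np.round(rng.normal(mean, 0.15 * mean, n)), mean * 0.5, mean * 1.5
    ).astype(np.int64)
    slack = G - int(lengths.sum())
    if slack < 0:
        raise SimulationError(
            f"cannot place {n} non-overlapping genes of mean {mean} in {G} bp"
        )
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    width = len(str(n))
    return pd.DataFrame(
        {
            "gene_id": [f"gene{str(i + 1).zfill(width)}" for i in range(n)],
            "seq": seq_name,
            "start": starts,
            "end": starts + lengths,
        }
    )


# ---------------------------------------------------------------------------
# Short reads


@dataclass
class ReadSet:
    """Simulated single-end reads with their true origins.

    ``seqs`` holds the sequenced bases (reverse-complemented for minus-strand
    reads); ``hap`` (0=a, 1=b), ``start`` (0-based haplotype coordinate) and
    ``strand`` (0=+, 1=-) form the read-origin sidecar.
    """

    genome: DiploidGenome
    read_length: int
    hap: np.ndarray
    start: np.ndarray
    strand: np.ndarray
    seqs: np.ndarray  # (n_reads, read_length) uint8 codes

    @property
    def n_reads(self) -> int:
        return len(self.start)

    @property
    def total_bases(self) -> int:
        return self.n_reads * self.read_length

    def read_ids(self) -> list[str]:
        w = max(len(str(self.n_reads - 1)), 1)
        return [f"read_{str(i).zfill(w)}" for i in range(self.n_reads)]

    def iter_seq_bytes(self, chunk: int = 200_000):
        """Yield read sequences as bytes, for k-mer counting."""
        for lo in range(0, self.n_reads, chunk):
            ascii_block = _DEC[self.seqs[lo : lo + chunk]]
            flat = ascii_block.tobytes()
            L = self.read_length
            for i in range(ascii_block.shape[0]):
                yield flat[i * L : (i + 1) * L]

    def anc_spans(self) -> tuple[np.ndarray, np.ndarray]:
        """Approximate ancestral [start, end) span of each read."""
        G = len(self.genome.ancestral)
        anc_start = np.empty(self.n_reads, np.int64)
        for h, which in enumerate("ab"):
            m = self.hap == h
            anc_start[m] = self.genome.hap[which].hap_to_anc(self.start[m])
        anc_start = np.clip(anc_start, 0, G)
        return anc_start, np.minimum(anc_start + self.read_length, G)

    def write_fastq(self, path) -> None:
        qual = "I" * self.read_length
        ids = self.read_ids()
        L = self.read_length
        with open(path, "w") as fh:
            for lo in range(0, self.n_reads, 200_000):
                block = _DEC[self.seqs[lo : lo + 200_000]].tobytes()
                out = []
                for i in range(min(200_000, self.n_reads - lo)):
                    seq = block[i * L : (i + 1) * L].decode()
                    out.append(f"@{ids[lo + i]}\n{seq}\n+\n{qual}\n")
                fh.write("".join(out))

    def write_sidecar(self, path) -> None:
        df = pd.DataFrame(
            {
                "read_id": self.read_ids(),
                "hap": np.where(self.hap == 0, "a", "b"),
                "start": self.start,
                "strand": np.where(self.strand == 0, "+", "-"),
                "length": self.read_length,
            }
        )
        write_tsv(path, df, comments=[f"genome={self.genome.label}"])

    @classmethod
    def from_files(cls, fastq_path, sidecar_path, genome: DiploidGenome) -> "ReadSet":
        from hybridseer.io import iter_fastq, read_tsv

        side = read_tsv(sidecar_path)
        seq_list = [seq for _t, seq, _q in iter_fastq(fastq_path)]
        if len(seq_list) != len(side):
            raise SimulationError("sidecar and FASTQ record counts differ")
        L = len(seq_list[0])
        seqs = np.empty((len(seq_list), L), np.uint8)
        for i, s in enumerate(seq_list):
            seqs[i] = encode_seq(s)
        return cls(
            genome=genome,
            read_length=L,
            hap=(side["hap"].to_numpy() == "b").astype(np.uint8),
            start=side["start"].to_numpy(np.int64),
            strand=(side["strand"].to_numpy() == "-").astype(np.uint8),
            seqs=seqs,
        )


def simulate_reads(genome: DiploidGenome, config: SimulationConfig) -> ReadSet:
    """Draw uniform single-end reads from both haplotypes.

    Per-haplotype fold coverage equals ``config.coverage`` (total emitted
    bases ~ coverage x 2 x haplotype length); strands are sampled 50/50 and
    per-base substitution errors applied at ``config.error_rate``. The RNG
    stream is keyed by the genome label so maternal/paternal/offspring read
    sets are independent under one seed.
    """
    L = config.read_length
    lengths = {h: genome.hap_length(h) for h in "ab"}
    if L > min(lengths.values()):
        raise SimulationError("read_length exceeds haplotype length")
    rng = config.rng("reads", zlib.crc32(genome.label.encode()) & 0x7FFFFFFF)

    n_by_hap = {h: int(round(config.coverage * lengths[h] / L)) for h in "ab"}
    n = n_by_hap["a"] + n_by_hap["b"]
    hap = np.concatenate(
        [np.zeros(n_by_hap["a"], np.uint8), np.ones(n_by_hap["b"], np.uint8)]
    )
    perm = rng.permutation(n)
    hap = hap[perm]
    start = np.empty(n, np.int64)
    for h, which in enumerate("ab"):
        m = hap == h
        start[m] = rng.integers(0, lengths[which] - L + 1, size=int(m.sum()))
    strand = rng.integers(0, 2, size=n, dtype=np.uint8)

    seqs = np.empty((n, L), np.uint8)
    window = np.arange(L)
    for h, which in enumerate("ab"):
        m = np.flatnonzero(hap == h)
        hseq = genome.sequence(which)
        for lo in range(0, len(m), 200_000):
            idx = m[lo : lo + 200_000]
            seqs[idx] = hseq[start[idx][:, None] + window]
    rev = strand == 1
    seqs[rev] = 3 - seqs[rev][:, ::-1]

    if config.error_rate > 0:
        for lo in range(0, n, 200_000):
            block = seqs[lo : lo + 200_000]
            mask = rng.random(block.shape) < config.error_rate
            k = int(mask.sum())
            if k:
                block[mask] = (block[mask] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
    return ReadSet(genome, L, hap, start, strand, seqs)


# ---------------------------------------------------------------------------
# Alignment-free pileups and breadth (synthetic path)


def pileup_match_depth(
    reads: ReadSet, sites: np.ndarray, ref_codes: np.ndarray
) -> np.ndarray:
    """Per-site count of reads whose base matches ``ref_codes``.

    *sites* are ancestral substitution positions; reads are located through
    the haplotype offset maps, and minus-strand reads are complemented back.
    """
    sites = np.asarray(sites, np.int64)
    ref_codes = np.asarray(ref_codes, np.int64)
    L = reads.read_length
    depth = np.zeros(len(sites), np.int64)
    for h, which in enumerate("ab"):
        sel = np.flatnonzero(reads.hap == h)
        if sel.size == 0:
            continue
        vs = reads.genome.hap[which]
        h_sites = vs.anc_to_hap(sites)
        starts = reads.start[sel]
        order = np.argsort(starts, kind="stable")
        starts_sorted = starts[order]
        lo = np.searchsorted(starts_sorted, h_sites - L + 1, side="left")
        hi = np.searchsorted(starts_sorted, h_sites, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        site_of = np.repeat(np.arange(len(sites)), counts)
        base_idx = np.repeat(np.cumsum(counts) - counts, counts)
        srt_pos = np.repeat(lo, counts) + (np.arange(total) - base_idx)
        ridx = sel[order[srt_pos]]
        offs = h_sites[site_of] - starts_sorted[srt_pos]
        fwd = reads.strand[ridx] == 0
        bases = np.where(
            fwd,
            reads.seqs[ridx, offs],
            3 - reads.seqs[ridx, L - 1 - offs],
        )
        match = bases == ref_codes[site_of]
        depth += np.bincount(site_of[match], minlength=len(sites))
    return depth


def gene_breadth(reads: ReadSet, genes: pd.DataFrame) -> np.ndarray:
    """Fraction of each gene interval covered by at least one read."""
    G = len(reads.genome.ancestral)
    anc_start, anc_end = reads.anc_spans()
    delta = np.bincount(anc_start, minlength=G + 1).astype(np.int64)
    delta -= np.bincount(anc_end, minlength=G + 1)
    covered = np.cumsum(delta)[:G] > 0
    prefix = np.concatenate([[0], np.cumsum(covered)])
    s = genes["start"].to_numpy(np.int64)
    e = genes["end"].to_numpy(np.int64)
    return (prefix[e] - prefix[s]) / np.maximum(e - s, 1)


@dataclass
class PhasingInputs:
    """Everything the phase classifier needs, plus the per-gene truth."""

    sites: pd.DataFrame  # seq, pos, allele, depth_m, depth_p
    coverage: pd.DataFrame  # gene_id, cov_m, cov_p
    truth: pd.DataFrame  # gene_id, true_donor, diagnostic_snps


def make_phasing_inputs(
    maternal: DiploidGenome,
    paternal: DiploidGenome,
    child: DiploidGenome,
    truth: TruthTable,
    genes: pd.DataFrame,
    config: SimulationConfig,
    reads_m: ReadSet | None = None,
    reads_p: ReadSet | None = None,
) -> PhasingInputs:
    """Build the per-parent diagnostic pileup for a simulated offspring.

    Emulates the fused-assembly situation: each gene model's reference is a
    randomly chosen child haplotype, the pileup's ``allele`` column is that
    reference allele at each child-heterozygous substitution site, and
    ``depth_m``/``depth_p`` count maternal/paternal reads observing it. The
    truth frame records the donor of the chosen reference haplotype per gene.
    """
    rng = config.rng("assembly")
    het = child_het_substitution_sites(child)
    pos = het["pos"].to_numpy()
    choice_b = rng.integers(0, 2, size=len(genes)).astype(bool)  # True -> hap b

    gs = genes["start"].to_numpy(np.int64)
    ge = genes["end"].to_numpy(np.int64)
    gidx = np.searchsorted(gs, pos, side="right") - 1
    in_gene = (gidx >= 0) & (pos < ge[np.maximum(gidx, 0)])
    site_choice_b = np.zeros(len(pos), dtype=bool)
    site_choice_b[in_gene] = choice_b[gidx[in_gene]]
    ref_allele = np.where(
        site_choice_b, het["allele_b"].to_numpy(), het["allele_a"].to_numpy()
    )

    if reads_m is None:
        reads_m = simulate_reads(maternal, config)
    if reads_p is None:
        reads_p = simulate_reads(paternal, config)
    depth_m = pileup_match_depth(reads_m, pos, ref_allele)
    depth_p = pileup_match_depth(reads_p, pos, ref_allele)

    sites = pd.DataFrame(
        {
            "seq": child.seq_name,
            "pos": pos,
            "allele": [decode_seq(np.array([a], np.uint8)) for a in ref_allele],
            "depth_m": depth_m,
            "depth_p": depth_p,
        }
    )
    coverage = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "cov_m": gene_breadth(reads_m, genes),
            "cov_p": gene_breadth(reads_p, genes),
        }
    )
    tg = truth.genes.set_index("gene_id")
    donors = np.where(
        choice_b,
        tg.loc[genes["gene_id"], "donor_hap_b"].to_numpy(),
        tg.loc[genes["gene_id"], "donor_hap_a"].to_numpy(),
    )
    truth_df = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "true_donor": donors,
            "diagnostic_snps": tg.loc[genes["gene_id"], "diagnostic_snps"].to_numpy(),
        }
    )
    return PhasingInputs(sites=sites, coverage=coverage, truth=truth_df)


def child_het_substitution_sites(child: DiploidGenome) -> pd.DataFrame:
    """Substitution positions where the child's two haplotypes differ."""
    a, b = child.hap["a"], child.hap["b"]
    pos = np.union1d(a.pos[a.is_snp], b.pos[b.is_snp])
    # drop positions that are InDels on the other haplotype
    for vs in (a, b):
        bad = vs.pos[~vs.is_snp]
        if bad.size:
            pos = np.setdiff1d(pos, bad)
    allele_a = a.allele_at(child.ancestral, pos)
    allele_b = b.allele_at(child.ancestral, pos)
    keep = allele_a != allele_b
    return pd.DataFrame(
        {"pos": pos[keep], "allele_a": allele_a[keep], "allele_b": allele_b[keep]}
    )


# ---------------------------------------------------------------------------
# Multi-accession genotype panel (variome input)


def simulate_panel(
    maternal: DiploidGenome,
    paternal: DiploidGenome,
    config: SimulationConfig,
    n_maternal: int = 2,
    n_paternal: int = 2,
    n_f1: int = 2,
    missing_rate: float = 0.02,
) -> tuple[list[str], pd.DataFrame, np.ndarray]:
    """Genotype a panel of accessions at every simulated variant site.

    Maternal/paternal accessions are homozygous for their species consensus
    at divergence sites and segregate (allele frequency 0.5) at their
    species' heterozygous sites; F1 accessions carry one allele drawn from
    each species. Returns ``(samples, sites, genotypes)`` where *sites* has
    columns ``seq, pos, ref, alt, type`` (VCF-style, pos 0-based) and
    *genotypes* is ``(n_samples, n_sites, 2)`` allele indices, -1 missing.
    """
    rng = config.rng("panel")
    anc = maternal.ancestral

    def collect(vs: VariantSet, origin: str):
        rows = []
        for p, rl, alt in zip(vs.pos, vs.ref_len, vs.alts):
            p, rl = int(p), int(rl)
            alt_len = len(alt)
            if rl == 1 and alt_len == 1:
                ref_s = decode_seq(anc[p : p + 1])
                alt_s = decode_seq(alt)
                vpos, vtype = p, "SNP"
            else:
                if p == 0:
                    continue  # VCF anchors InDels on the previous base
                anchor = anc[p - 1 : p]
                ref_s = decode_seq(np.concatenate([anchor, anc[p : p + rl]]))
                alt_s = decode_seq(np.concatenate([anchor, alt]))
                vpos, vtype = p - 1, "InDel"
            rows.append((vpos, ref_s, alt_s, vtype, origin))
        return rows

    rows = (
        collect(maternal.hap["a"], "div_m")
        + collect(paternal.hap["a"], "div_p")
        + collect(
            _difference(maternal.hap["b"], maternal.hap["a"]), "het_m"
        )
        + collect(
            _difference(paternal.hap["b"], paternal.hap["a"]), "het_p"
        )
    )
    rows.sort(key=lambda r: r[0])
    sites = pd.DataFrame(rows, columns=["pos", "ref", "alt", "type", "origin"])
    sites.insert(0, "seq", maternal.seq_name)
    n_sites = len(sites)
    origin = sites["origin"].to_numpy()
    samples = (
        [f"mat{i + 1}" for i in range(n_maternal)]
        + [f"pat{i + 1}" for i in range(n_paternal)]
        + [f"f1_{i + 1}" for i in range(n_f1)]
    )
    gt = np.zeros((len(samples), n_sites, 2), np.int8)

    is_div_m = origin == "div_m"
    is_div_p = origin == "div_p"
    is_het_m = origin == "het_m"
    is_het_p = origin == "het_p"
    for i in range(n_maternal):
        gt[i, is_div_m] = 1
        k = int(is_het_m.sum())
        gt[i, is_het_m] = rng.integers(0, 2, size=(k, 2), dtype=np.int8)
    for j in range(n_paternal):
        i = n_maternal + j
        gt[i, is_div_p] = 1
        k = int(is_het_p.sum())
        gt[i, is_het_p] = rng.integers(0, 2, size=(k, 2), dtype=np.int8)
    for j in range(n_f1):
        i = n_maternal + n_paternal + j
        gt[i, is_div_m, 0] = 1  # maternal allele
        gt[i, is_div_p, 1] = 1  # paternal allele
        gt[i, is_het_m, 0] = rng.integers(0, 2, size=int(is_het_m.sum()), dtype=np.int8)
        gt[i, is_het_p, 1] = rng.integers(0, 2, size=int(is_het_p.sum()), dtype=np.int8)
    if missing_rate > 0:
        miss = rng.random((len(samples), n_sites)) < missing_rate
        gt[miss] = -1
    return samples, sites.drop(columns="origin"), gt


def _difference(vs: VariantSet, minus: VariantSet) -> VariantSet:
    keep = ~np.isin(vs.pos, minus.pos)
    return VariantSet(
        vs.pos[keep], vs.ref_len[keep], [a for a, k in zip(vs.alts, keep) if k]
    )


# ---------------------------------------------------------------------------
# S-locus alleles

_S_GENE_LEN = 600
_CLASS_DIVERGENCE = 0.10  # substitutions from the base gene per class
# each allele carries at most one private substitution (probability below),
# so within-class pairwise divergence is <= 2/600 ~ 0.33%, always under 0.5%
_WITHIN_CLASS_NOISE_P = 0.5


class GSIError(SimulationError):
    """A pedigree cannot be realised under gametophytic self-incompatibility."""


def simulate_s_locus(
    accessions: int,
    pool_size: int,
    pedigree: list[tuple[str, str, str]] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str, int, str]], dict[str, tuple[str, str]]]:
    """Simulate linked S-RNase/SFB allele pairs for a population.

    Accessions are named ``acc01..``; *pedigree* lists ``(child, mother,
    father)`` trios among them. Founders draw two distinct classes from a
    pool of ``pool_size``; trio offspring receive one class from each parent
    with the pollen (paternal) class required to be absent from the seed
    parent — gametophytic self-incompatibility. Within a class, allele
    sequences differ by < 0.5%; between classes by > 5%.

    Returns ``(records, truth)`` where records are ``(accession, gene, copy,
    sequence)`` FASTA-ready tuples and truth maps accession to its unordered
    class-label pair (labels ``C01..``).
    """
    if pool_size < 2:
        raise SimulationError("pool_size must be >= 2")
    rng = np.random.default_rng([seed, 6])
    width = max(2, len(str(accessions)))
    names = [f"acc{str(i + 1).zfill(width)}" for i in range(accessions)]
    pedigree = pedigree or []
    children = {c for c, _m, _f in pedigree}
    for trio in pedigree:
        for name in trio:
            if name not in names:
                raise SimulationError(f"pedigree names unknown accession {name!r}")

    def mutate(seq: np.ndarray, rate: float) -> np.ndarray:
        out = seq.copy()
        k = rng.binomial(len(seq), rate)
        pos = rng.choice(len(seq), size=k, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=k)) % 4
        return out

    base = {g: rng.integers(0, 4, _S_GENE_LEN, dtype=np.uint8) for g in ("S-RNase", "SFB")}
    cw = max(2, len(str(pool_size)))
    class_labels = [f"C{str(i + 1).zfill(cw)}" for i in range(pool_size)]
    archetype = {
        (lab, g): mutate(base[g], _CLASS_DIVERGENCE)
        for lab in class_labels
        for g in ("S-RNase", "SFB")
    }

    truth: dict[str, tuple[str, str]] = {}
    for name in names:
        if name in children:
            continue
        pair = rng.choice(pool_size, size=2, replace=False)
        truth[name] = (class_labels[pair[0]], class_labels[pair[1]])
    # resolve trios (parents may themselves be trio children)
    pending = list(pedigree)
    while pending:
        progressed = False
        for trio in list(pending):
            child, mother, father = trio
            if mother not in truth or father not in truth:
                continue
            pollen_options = [c for c in truth[father] if c not in truth[mother]]
            if not pollen_options:
                raise GSIError(
                    f"trio {trio}: both paternal S classes present in seed parent"
                )
            maternal_class = truth[mother][int(rng.integers(2))]
            paternal_class = pollen_options[int(rng.integers(len(pollen_options)))]
            truth[child] = (maternal_class, paternal_class)
            pending.remove(trio)
            progressed = True
        if not progressed:
            raise SimulationError("pedigree contains a cycle or missing parents")

    records = []
    for name in names:
        pair = list(truth[name])
        rng.shuffle(pair)
        truth[name] = (pair[0], pair[1])
        for copy, lab in enumerate(pair, start=1):
            for g in ("S-RNase", "SFB"):
                seq = archetype[(lab, g)].copy()
                if rng.random() < _WITHIN_CLASS_NOISE_P:
                    p = int(rng.integers(len(seq)))
                    seq[p] = (seq[p] + rng.integers(1, 4)) % 4
                records.append((name, g, copy, decode_seq(seq)))
    return records, truth


def write_s_allele_fasta(path, records: list[tuple[str, str, int, str]]) -> None:
    write_fasta(path, [(f"{acc}|{gene}|{copy}", seq) for acc, gene, copy, seq in records])


# ---------------------------------------------------------------------------
# Convenience writers


def write_genes_gff3(path, genes: pd.DataFrame) -> None:
    write_gff3(path, genes)
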