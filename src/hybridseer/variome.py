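"""Multi-sample variome analysis: summaries, distances, ordination, trees.

From a samples x sites diploid genotype table this module computes the
classical resequencing panel diagnostics: per-sample heterozygous/homozygous
SNP and InDel counts with the transition/transversion ratio, the
identity-by-state allele-sharing distance (per jointly-called site, two
minus the size of the multiset intersection of the two genotypes), a 2-D
classical multidimensional scaling of that matrix (double-centering +
eigendecomposition, the construct behind PLINK ``--mds-plot``), and a
neighbor-joining tree. An F1 hybrid sits midway between its parental
clusters in all three views.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from hybridseer.io import write_tsv

logger = logging.getLogger(__name__)

MISSING = -1

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class VariomeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Samples x variant-sites diploid genotype table.

    ``genotypes[i, j]`` holds the two allele indices of sample *i* at site
    *j* (0 = REF; unordered; ``-1`` marks a missing call). *sites* has
    columns ``seq, pos, ref, alt, type`` with ``alt`` a comma-joined string
    and ``type`` in {SNP, InDel}.
    """

    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray  # (n_samples, n_sites, 2) int8

    def __post_init__(self) -> None:
        n_s, n_v, two = self.genotypes.shape
        if n_s != len(self.samples) or n_v != len(self.sites) or two != 2:
            raise VariomeError("genotype array dimensions inconsistent")
        n_alleles = self.sites["alt"].str.count(",").to_numpy() + 2
        if (self.genotypes.max(axis=(0, 2)) >= n_alleles).any():
            raise VariomeError("allele index outside the site's ref/alt set")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def permuted(self, order: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=[self.samples[i] for i in order],
            sites=self.sites,
            genotypes=self.genotypes[order],
        )

    def snps_only(self) -> "GenotypeMatrix":
        keep = (self.sites["type"] == "SNP").to_numpy()
        return GenotypeMatrix(
            samples=self.samples,
            sites=self.sites.loc[keep].reset_index(drop=True),
            genotypes=self.genotypes[:, keep],
        )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read GT fields from a multi-sample VCF (``./.`` = missing)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        if not samples:
            raise VariomeError(f"{path}: VCF has no samples")
        site_rows = []
        gts = []
        for rec in vcf:
            alts = rec.ALT or []
            vtype = (
                "SNP"
                if len(rec.REF) == 1 and alts and all(len(a) == 1 for a in alts)
                else "InDel"
            )
            site_rows.append((rec.CHROM, rec.POS - 1, rec.REF, ",".join(alts), vtype))
            row = np.array([g[:2] for g in rec.genotypes], dtype=np.int8)
            gts.append(row)
        if not site_rows:
            sites = pd.DataFrame(columns=["seq", "pos", "ref", "alt", "type"])
            return cls(samples, sites, np.empty((len(samples), 0, 2), np.int8))
        sites = pd.DataFrame(site_rows, columns=["seq", "pos", "ref", "alt", "type"])
        genotypes = np.stack(gts, axis=1)  # (n_samples, n_sites, 2)
        return cls(samples, sites, genotypes)

    def allele_counts(self) -> np.ndarray:
        """One-hot allele-copy counts ``(n_samples, n_sites, max_alleles)``.

        Missing genotypes have all-zero rows.
        """
        max_alleles = int(self.sites["alt"].str.count(",").max() + 2) if self.n_sites else 2
        counts = np.zeros((self.n_samples, self.n_sites, max_alleles), np.int8)
        for a in range(max_alleles):
            counts[:, :, a] = (self.genotypes == a).sum(axis=2, dtype=np.int8)
        called = (self.genotypes >= 0).all(axis=2)
        counts[~called] = 0
        return counts


# ---------------------------------------------------------------------------
# Per-sample summaries


def summarize_variome(gm: GenotypeMatrix) -> pd.DataFrame:
    """Het/hom SNP counts, InDel counts and Ti/Tv per sample.

    Transitions (A<->G, C<->T) and transversions are counted per non-REF
    allele copy at biallelic SNPs (a homozygous-alt genotype contributes two
    copies); sites with more than one ALT allele enter the het/hom/InDel
    totals but are excluded from Ti/Tv with a logged count.
    """
    if gm.n_samples == 0:
        raise VariomeError("empty genotype matrix")
    is_snp = (gm.sites["type"] == "SNP").to_numpy()
    biallelic = (gm.sites["alt"].str.count(",") == 0).to_numpy()
    ti_site = np.zeros(gm.n_sites, bool)
    bial_snp = is_snp & biallelic
    if bial_snp.any():
        refs = gm.sites.loc[bial_snp, "ref"].to_numpy()
        alts = gm.sites.loc[bial_snp, "alt"].to_numpy()
        ti_site[bial_snp] = [
            frozenset((r, a)) in TRANSITIONS for r, a in zip(refs, alts)
        ]
    n_multi = int((is_snp & ~biallelic).sum())
    if n_multi:
        logger.info("summarize_variome: %d multiallelic SNP sites excluded from Ti/Tv", n_multi)

    rows = []
    for i, sample in enumerate(gm.samples):
        g = gm.genotypes[i]
        called = (g >= 0).all(axis=1)
        variant = called & (g.max(axis=1) > 0)
        het = variant & (g[:, 0] != g[:, 1])
        hom = variant & (g[:, 0] == g[:, 1])
        het_snps = int((het & is_snp).sum())
        hom_snps = int((hom & is_snp).sum())
        indels = int((variant & ~is_snp).sum())
        copies = (g > 0).sum(axis=1) * (called & bial_snp)
        ti = int(copies[ti_site].sum())
        tv = int(copies[bial_snp & ~ti_site].sum())
        rows.append(
            (
                sample,
                het_snps,
                hom_snps,
                indels,
                het_snps + hom_snps + indels,
                ti,
                tv,
                ti / tv if tv else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "het_snps", "hom_snps", "indels",
            "snps_plus_indels", "ti", "tv", "titv_ratio",
        ],
    )


# ---------------------------------------------------------------------------
# Allele-sharing distance


@dataclass
class DistanceMatrix:
    """Symmetric allele-difference distances with per-pair denominators."""

    samples: list[str]
    d: np.ndarray
    denom: np.ndarray = field(default=None)  # jointly-called site counts

    def __post_init__(self) -> None:
        n = len(self.samples)
        self.d = np.asarray(self.d, float)
        if self.d.shape != (n, n):
            raise VariomeError("distance matrix shape mismatch")
        if self.denom is None:
            self.denom = np.full((n, n), np.inf)
        if not np.allclose(self.d, self.d.T):
            raise VariomeError("distance matrix not symmetric")
        if (np.diag(self.d) != 0).any():
            raise VariomeError("nonzero diagonal")
        if (self.d < 0).any():
            raise VariomeError("negative distances")
        off = ~np.eye(n, dtype=bool)
        if (self.d[off] > 2 * self.denom[off] + 1e-9).any():
            raise VariomeError("distance exceeds 2 x jointly-called sites")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.d, index=self.samples, columns=self.samples)
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(samples=list(df.columns), d=df.to_numpy(float))


def allele_distance(gm: GenotypeMatrix, normalize: bool = False) -> DistanceMatrix:
    """Count differing alleles between every pair of genotypes.

    Per jointly-called site the contribution is ``2 - |multiset intersection
    of the two genotypes|`` (0 identical, 1 one shared allele, 2 none);
    sites missing in either sample are skipped pairwise. ``normalize``
    divides each pair by its jointly-called site count.
    """
    if gm.n_samples < 2:
        raise VariomeError("need at least 2 samples")
    counts = gm.allele_counts()
    called = (gm.genotypes >= 0).all(axis=2)
    n = gm.n_samples
    d = np.zeros((n, n))
    denom = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = called[i] & called[j]
            shared = np.minimum(counts[i], counts[j]).sum(axis=1)
            dij = float((2 - shared)[joint].sum())
            nij = int(joint.sum())
            if nij == 0:
                raise VariomeError(
                    f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no called sites"
                )
            d[i, j] = d[j, i] = dij
            denom[i, j] = denom[j, i] = nij
    np.fill_diagonal(denom, np.inf)
    if normalize:
        off = ~np.eye(n, dtype=bool)
        d[off] = d[off] / denom[off]
    return DistanceMatrix(samples=list(gm.samples), d=d, denom=denom)


# ---------------------------------------------------------------------------
# Classical MDS


def classical_mds(dm: DistanceMatrix, dims: int = 2) -> pd.DataFrame:
    """Embed a distance matrix by double-centering and eigendecomposition.

    ``B = -1/2 J D^2 J``; coordinates are the top-*dims* eigenvectors scaled
    by the square roots of their (positive) eigenvalues, sorted descending.
    Negative eigenvalues beyond the requested dimensions are ignored with a
    logged warning; each axis's sign is fixed so its first nonzero loading is
    positive. All-zero distances embed at the origin.
    """
    n = len(dm.samples)
    if dims > n - 1:
        raise VariomeError(f"dims={dims} exceeds n-1={n - 1}")
    D2 = dm.d**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    w, v = scipy.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if (w[dims:] < -1e-9 * max(abs(w[0]), 1.0)).any():
        logger.warning("classical_mds: negative eigenvalues beyond dims ignored")
    coords = np.zeros((n, dims))
    for axis in range(dims):
        if w[axis] > 1e-12 * max(abs(w[0]), 1.0):
            col = v[:, axis] * np.sqrt(w[axis])
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            if nz.size and col[nz[0]] < 0:
                col = -col
            coords[:, axis] = col
    return pd.DataFrame(
        coords,
        index=pd.Index(dm.samples, name="sample"),
        columns=[f"dim{i + 1}" for i in range(dims)],
    )


def write_mds_tsv(path, coords: pd.DataFrame) -> None:
    write_tsv(path, coords.reset_index())


# ---------------------------------------------------------------------------
# Neighbor-joining


class _Node:
    __slots__ = ("name", "children", "label")

    def __init__(self, name=None, children=None, label=None):
        self.name = name
        self.children = children or []  # list of (node, branch_length)
        self.label = label  # lexicographically smallest leaf under the node

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> str:
    """Build an unrooted neighbor-joining tree (Saitou-Nei) as Newick.

    Ties in the Q criterion break lexicographically on the joined clusters'
    smallest leaf names; negative branch lengths are clamped to zero with
    the excess moved to the sister branch. Exactly recovers additive trees.
    """
    n = len(dm.samples)
    if n < 3:
        raise VariomeError("neighbor-joining needs at least 3 samples")
    for name in dm.samples:
        if any(ch in name for ch in "():;, \t"):
            raise VariomeError(f"sample name {name!r} unsafe for Newick")
    nodes = [_Node(name=s, label=s) for s in dm.samples]
    D = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                li, lj = sorted((nodes[i].label, nodes[j].label))
                key = (q, li, lj)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bj, bi = dij, 0.0
        elif bj < 0:
            bi, bj = dij, 0.0
        new = _Node(
            children=[(nodes[i], bi), (nodes[j], bj)],
            label=min(nodes[i].label, nodes[j].label),
        )
        k = len(nodes)
        nodes.append(new)
        D = np.pad(D, ((0, 1), (0, 1)))
        for other in active:
            if other in (i, j):
                continue
            D[k, other] = D[other, k] = 0.5 * (D[i, other] + D[j, other] - dij)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    children = sorted(
        [(nodes[i], bi), (nodes[j], bj), (nodes[k], bk)],
        key=lambda c: c[0].label,
    )
    children = [(c, max(bl, 0.0)) for c, bl in children]
    root = _Node(children=children)
    return root.newick() + ";"
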