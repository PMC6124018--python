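"""Parent-of-origin classification of genes from parental read evidence.

Each gene model sits on one haplotype of a haplotype-fused assembly. Reads
from the two candidate parental species are examined for (a) alignment
breadth over the gene and (b) allele support at diagnostic SNP sites. A gene
is *unique* to a parent when only that parent's reads align, *phased* to a
parent when that parent supports at least twofold as many SNP sites, and
*common* otherwise; genes never touched by either read set carry no data.
Sites count only when their supporting depth reaches ``min_depth`` (2 reads
by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from hybridseer.io import write_tsv

logger = logging.getLogger(__name__)

UNIQUE_MATERNAL = "UNIQUE_MATERNAL"
PHASED_MATERNAL = "PHASED_MATERNAL"
UNIQUE_PATERNAL = "UNIQUE_PATERNAL"
PHASED_PATERNAL = "PHASED_PATERNAL"
COMMON = "COMMON"
NO_DATA = "NO_DATA"
CALL_CLASSES = (
    UNIQUE_MATERNAL,
    PHASED_MATERNAL,
    UNIQUE_PATERNAL,
    PHASED_PATERNAL,
    COMMON,
    NO_DATA,
)
MATERNAL_CALLS = {UNIQUE_MATERNAL, PHASED_MATERNAL}
PATERNAL_CALLS = {UNIQUE_PATERNAL, PHASED_PATERNAL}


@dataclass
class GeneEvidence:
    """Per-gene parental read evidence.

    ``cov_m``/``cov_p`` are aligned-read breadth fractions of the gene
    interval; ``support_m``/``support_p`` count depth-passing diagnostic-SNP
    sites favoring each parent; ``sites_considered`` counts sites passing the
    depth filter in at least one parent.
    """

    gene_id: str
    seq: str
    start: int
    end: int
    cov_m: float
    cov_p: float
    support_m: int
    support_p: int
    sites_considered: int
    support_unit: str = "sites"

    def __post_init__(self) -> None:
        if not (0 <= self.cov_m <= 1 and 0 <= self.cov_p <= 1):
            raise ValueError(f"{self.gene_id}: coverages must be in [0, 1]")
        if min(self.support_m, self.support_p, self.sites_considered) < 0:
            raise ValueError(f"{self.gene_id}: negative counts")
        if (
            self.support_unit == "sites"
            and max(self.support_m, self.support_p) > self.sites_considered
        ):
            raise ValueError(f"{self.gene_id}: support exceeds sites_considered")


@dataclass
class PhaseCall:
    gene_id: str
    call: str
    evidence: GeneEvidence


def collect_evidence(
    genes: pd.DataFrame,
    sites: pd.DataFrame,
    coverage: pd.DataFrame | None = None,
    min_depth: int = 2,
    support_unit: str = "sites",
) -> list[GeneEvidence]:
    """Aggregate site-level parental support into per-gene evidence.

    *genes* is a 0-based half-open frame ``gene_id, seq, start, end`` (from
    :func:`hybridseer.io.read_gff3` or ``read_bed``); *sites* has columns
    ``seq, pos, allele, depth_m, depth_p`` where the depths count reads of
    each parent observing the assembly allele at that site (0-based ``pos``).
    A site supports a parent only when its depth in that parent is at least
    *min_depth*; sites failing the filter in both parents are excluded from
    ``sites_considered``. *coverage* (``gene_id, cov_m, cov_p``) supplies
    aligned breadth; without it, breadth falls back to a site-based proxy
    (1 if any gene site has nonzero depth for that parent, else 0).

    ``support_unit="sites"`` (default) gives each passing site one vote —
    robust to depth imbalance between the parental read sets;
    ``support_unit="reads"`` counts the supporting reads themselves.
    """
    if support_unit not in ("sites", "reads"):
        raise ValueError(f"support_unit must be 'sites' or 'reads', got {support_unit!r}")
    known = set(genes["seq"])
    unknown = set(sites["seq"]) - known
    if unknown:
        raise ValueError(f"site records on unknown sequence(s): {sorted(unknown)}")
    _warn_if_overlapping(genes)
    cov_map = (
        coverage.set_index("gene_id")[["cov_m", "cov_p"]].to_dict("index")
        if coverage is not None
        else None
    )
    out: list[GeneEvidence] = []
    for seq_name, group in genes.groupby("seq", sort=False):
        s = sites[sites["seq"] == seq_name]
        pos = s["pos"].to_numpy(np.int64)
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        dm = s["depth_m"].to_numpy(np.int64)[order]
        dp = s["depth_p"].to_numpy(np.int64)[order]
        for row in group.itertuples(index=False):
            lo = np.searchsorted(pos_sorted, row.start)
            hi = np.searchsorted(pos_sorted, row.end)
            g_dm, g_dp = dm[lo:hi], dp[lo:hi]
            pass_m = g_dm >= min_depth
            pass_p = g_dp >= min_depth
            if support_unit == "sites":
                support_m = int(pass_m.sum())
                support_p = int(pass_p.sum())
            else:
                support_m = int(g_dm[pass_m].sum())
                support_p = int(g_dp[pass_p].sum())
            considered = int((pass_m | pass_p).sum())
            if cov_map is not None:
                cov = cov_map.get(row.gene_id, {"cov_m": 0.0, "cov_p": 0.0})
                cov_m, cov_p = float(cov["cov_m"]), float(cov["cov_p"])
            else:
                cov_m = 1.0 if (g_dm > 0).any() else 0.0
                cov_p = 1.0 if (g_dp > 0).any() else 0.0
            out.append(
                GeneEvidence(
                    gene_id=row.gene_id,
                    seq=row.seq,
                    start=int(row.start),
                    end=int(row.end),
                    cov_m=cov_m,
                    cov_p=cov_p,
                    support_m=support_m,
                    support_p=support_p,
                    sites_considered=considered,
                    support_unit=support_unit,
                )
            )
    return out


def _warn_if_overlapping(genes: pd.DataFrame) -> None:
    for _seq, group in genes.groupby("seq", sort=False):
        g = group.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            logger.warning("overlapping gene intervals; processing independently")
            return


def classify(
    evidence: GeneEvidence,
    fold: float = 2.0,
    min_support: int = 1,
    min_breadth: float = 0.5,
) -> PhaseCall:
    """Assign a parental phase to one gene (pure function of its evidence).

    Decision ladder: (1) no coverage by either parent — no data; (2) one
    parent covers at least *min_breadth* of the gene and the other none —
    unique to that parent; (3) one parent supports at least *fold* times as
    many diagnostic-SNP sites (and at least *min_support* sites) — phased to
    that parent; (4) otherwise common.
    """
    e = evidence
    if e.cov_m == 0 and e.cov_p == 0:
        call = NO_DATA
    elif e.cov_m >= min_breadth and e.cov_p == 0:
        call = UNIQUE_MATERNAL
    elif e.cov_p >= min_breadth and e.cov_m == 0:
        call = UNIQUE_PATERNAL
    else:
        m_ok = e.support_m >= fold * e.support_p and e.support_m >= min_support
        p_ok = e.support_p >= fold * e.support_m and e.support_p >= min_support
        if m_ok and not p_ok:
            call = PHASED_MATERNAL
        elif p_ok and not m_ok:
            call = PHASED_PATERNAL
        else:
            call = COMMON
    return PhaseCall(gene_id=e.gene_id, call=call, evidence=e)


def classify_all(
    evidence: list[GeneEvidence],
    fold: float = 2.0,
    min_support: int = 1,
    min_breadth: float = 0.5,
) -> list[PhaseCall]:
    return [classify(e, fold, min_support, min_breadth) for e in evidence]


@dataclass
class PhaseSummary:
    """Per-class counts and ratios of a set of phase calls.

    Ratios are percentages of genes with data (no-data genes are reported
    separately and excluded from the denominator).
    """

    counts: dict[str, int]
    total: int

    @property
    def n_with_data(self) -> int:
        return self.total - self.counts[NO_DATA]

    def ratio(self, call: str) -> float:
        if call == NO_DATA or self.n_with_data == 0:
            return float("nan")
        return 100.0 * self.counts[call] / self.n_with_data

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, self.counts[c], self.ratio(c))
            for c in CALL_CLASSES
        ]
        return pd.DataFrame(rows, columns=["call", "number", "ratio_pct"])

    def format_table(self) -> str:
        """Render the classical unique/phased x maternal/paternal/common table."""
        order = [UNIQUE_MATERNAL, PHASED_MATERNAL, UNIQUE_PATERNAL, PHASED_PATERNAL, COMMON]
        header = (
            "Type       Maternal gene       Paternal gene       Common gene\n"
            "           Unique    Phased    Unique    Phased\n"
        )
        nums = "Number  " + "".join(f"{self.counts[c]:>10d}" for c in order) + "\n"
        rats = "Ratio(%)" + "".join(f"{self.ratio(c):>10.1f}" for c in order) + "\n"
        return header + nums + rats


def summarize(calls: list[PhaseCall]) -> PhaseSummary:
    if not calls:
        raise ValueError("no calls to summarize")
    counts = {c: 0 for c in CALL_CLASSES}
    for call in calls:
        counts[call.call] += 1
    return PhaseSummary(counts=counts, total=len(calls))


def paint_chromosomes(calls: list[PhaseCall]) -> pd.DataFrame:
    """Order calls into a per-sequence chromosome track (BED-ready).

    Returns a 0-based half-open frame ``seq, start, end, gene_id, call``
    stably sorted by sequence then start.
    """
    rows = [
        (c.evidence.seq, c.evidence.start, c.evidence.end, c.gene_id, c.call)
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=["seq", "start", "end", "gene_id", "call"])
    return df.sort_values(["seq", "start"], kind="stable").reset_index(drop=True)


def calls_to_frame(calls: list[PhaseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.gene_id,
                c.call,
                c.evidence.cov_m,
                c.evidence.cov_p,
                c.evidence.support_m,
                c.evidence.support_p,
                c.evidence.sites_considered,
            )
            for c in calls
        ],
        columns=[
            "gene_id", "call", "cov_m", "cov_p",
            "support_m", "support_p", "sites_considered",
        ],
    )


def write_calls_tsv(path, calls: list[PhaseCall], params: dict | None = None) -> None:
    comments = [f"{k}={v}" for k, v in (params or {}).items()]
    write_tsv(path, calls_to_frame(calls), comments=comments)


# ---------------------------------------------------------------------------
# Site tables: pileup TSV and per-parent VCF routes


def write_pileup_tsv(path, sites: pd.DataFrame) -> None:
    """Write a combined pileup (``pos`` 1-based on disk)."""
    out = sites.copy()
    out["pos"] = out["pos"] + 1
    write_tsv(path, out[["seq", "pos", "allele", "depth_m", "depth_p"]])


def read_pileup_tsv(path) -> pd.DataFrame:
    from hybridseer.io import read_tsv

    df = read_tsv(path)
    required = {"seq", "pos", "allele", "depth_m", "depth_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pileup TSV missing columns {sorted(missing)}")
    df["pos"] = df["pos"] - 1
    return df


def sites_from_vcfs(maternal_vcf, paternal_vcf) -> pd.DataFrame:
    """Build the combined site table from two per-parent single-sample VCFs.

    The VCF REF allele is taken as the assembly (reference haplotype) allele;
    the supporting depth of each parent is the AD entry of the REF allele
    when FORMAT:AD is present, otherwise DP if the GT carries the REF allele
    (0 when it does not).
    """
    from cyvcf2 import VCF

    def one(path) -> dict[tuple[str, int], tuple[str, int]]:
        out = {}
        vcf = VCF(str(path))
        if len(vcf.samples) != 1:
            raise ValueError(f"{path}: expected a single-sample VCF")
        for rec in vcf:
            depth = 0
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is not None:
                depth = int(max(ad[0][0], 0))
            else:
                gt = rec.genotypes[0][:2]
                if 0 in gt:
                    dp = rec.format("DP")
                    depth = int(dp[0][0]) if dp is not None else 0
            out[(rec.CHROM, rec.POS - 1)] = (rec.REF, depth)
        return out

    m = one(maternal_vcf)
    p = one(paternal_vcf)
    keys = sorted(set(m) | set(p))
    rows = []
    for key in keys:
        ref_m, dm = m.get(key, (None, 0))
        ref_p, dp_ = p.get(key, (None, 0))
        ref = ref_m or ref_p
        if ref_m and ref_p and ref_m != ref_p:
            raise ValueError(f"REF mismatch between parent VCFs at {key}")
        rows.append((key[0], key[1], ref, dm, dp_))
    return pd.DataFrame(rows, columns=["seq", "pos", "allele", "depth_m", "depth_p"])


# ---------------------------------------------------------------------------
# Exhaustive-oracle helper (used by tests; kept here so the enumeration and
# the ladder share their thresholds' meaning, not their implementation)


def enumerate_evidence_vectors(max_count: int = 5):
    """Yield all small evidence vectors (cov flags x support counts)."""
    for cov_m, cov_p in product((0.0, 0.25, 0.5, 1.0), repeat=2):
        for sm, sp in product(range(max_count + 1), repeat=2):
            yield GeneEvidence(
                gene_id=f"g_{cov_m}_{cov_p}_{sm}_{sp}",
                seq="chr1",
                start=0,
                end=100,
                cov_m=cov_m,
                cov_p=cov_p,
                support_m=sm,
                support_p=sp,
                sites_considered=sm + sp,
            )
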