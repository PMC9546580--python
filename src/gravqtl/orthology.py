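"""One-to-one ortholog identification within QTL intervals.

QTL support intervals live on the genetic map (cM); gene annotations live on
physical coordinates (bp).  Marker anchors with both coordinates bridge the
two by linear interpolation.  Candidate genes are those overlapping an
interval by at least 1 bp; orthologs are then called by reciprocal best hit
(BBH): an interval gene of species A and its best-scoring hit in the *full*
species-B proteome form a pair iff the hit lies in a species-B interval and
its own best hit in the full species-A proteome is the original gene.

Alignment is Smith-Waterman local alignment with affine gaps under BLOSUM62
and blastp-default gap costs (open 11, extend 1; a gap of length L costs
11 + L).  Percent identity counts identities over all alignment columns,
gap columns included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "BBHPair",
    "cm_to_bp",
    "genes_in_interval",
    "make_aligner",
    "align_proteins",
    "best_hit",
    "find_bbh",
    "report_candidates",
    "run_orthology",
    "parse_tabular_hits",
]


@dataclass
class AlignmentResult:
    query: str
    subject: str
    score: float
    identities: int
    columns: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.columns if self.columns else 0.0


@dataclass
class BBHPair:
    gene_a: str
    gene_b: str
    forward: AlignmentResult  # a -> b
    reverse: AlignmentResult  # b -> a
    interval_a: str | None = None
    interval_b: str | None = None

    @property
    def percent_identity(self) -> float:
        return self.forward.percent_identity


# ---------------------------------------------------------------------------
# Coordinate conversion and gene extraction
# ---------------------------------------------------------------------------

def cm_to_bp(interval, anchors: pd.DataFrame):
    """Map a (chrom, cM_lo, cM_hi) interval to bp by linear interpolation.

    ``anchors`` has columns chrom, cM, bp; at least two anchors are needed
    on the chromosome and bp must be strictly monotone in cM.  Endpoints
    outside the anchor span are clamped to the terminal anchors; the return
    is (chrom, bp_lo, bp_hi, clamped_flag).
    """
    chrom, lo, hi = interval[0], float(interval[1]), float(interval[2])
    sub = anchors[anchors["chrom"] == chrom].sort_values("cM")
    if len(sub) < 2:
        raise ValueError(f"need >= 2 anchors on chromosome {chrom}")
    cm = sub["cM"].to_numpy(dtype=float)
    bp = sub["bp"].to_numpy(dtype=float)
    if np.any(np.diff(cm) <= 0) or np.any(np.diff(bp) <= 0):
        raise ValueError(f"anchors on chromosome {chrom} are not strictly monotone")
    clamped = lo < cm[0] or hi > cm[-1]
    bp_lo = float(np.interp(lo, cm, bp))
    bp_hi = float(np.interp(hi, cm, bp))
    return chrom, int(round(bp_lo)), int(round(bp_hi)), clamped


def genes_in_interval(genes: pd.DataFrame, interval) -> list[str]:
    """Genes whose [start, end] overlaps a (chrom, bp_lo, bp_hi) interval.

    Overlap of >= 1 bp counts, strand-agnostic.  An unknown chromosome
    returns an empty list with a warning.
    """
    chrom, lo, hi = interval[0], interval[1], interval[2]
    if chrom not in set(genes["chrom"]):
        warnings.warn(f"chromosome {chrom} not in annotation", stacklevel=2)
        return []
    sub = genes[(genes["chrom"] == chrom) & (genes["end"] >= lo) & (genes["start"] <= hi)]
    return sub["gene"].tolist()


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

def make_aligner(matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    """Smith-Waterman aligner with BLAST-convention affine gap costs.

    A gap of length L costs gap_open + L * gap_extend, i.e. the aligner's
    per-gap opening score is -(gap_open + gap_extend).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_seq(seq: str, alphabet) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"residues not in the scoring alphabet: {sorted(bad)}")


def align_proteins(
    a: str,
    b: str,
    aligner: Align.PairwiseAligner | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    Identity is counted over alignment columns including gap columns.
    """
    aligner = aligner or make_aligner()
    alphabet = str(aligner.substitution_matrix.alphabet)
    _check_seq(a, alphabet)
    _check_seq(b, alphabet)
    alns = aligner.align(a, b)
    try:
        aln = alns[0]
    except IndexError:
        # no positively scoring local alignment (e.g. only zero-score
        # residue pairs): empty alignment, identity undefined -> 0
        return AlignmentResult(
            query=query_id, subject=subject_id,
            score=float(aligner.score(a, b)), identities=0, columns=0,
        )
    c = aln.counts()
    # columns of the local alignment: matches + mismatches + internal gaps
    columns = int(c.identities + c.mismatches + c.internal_gaps)
    return AlignmentResult(
        query=query_id,
        subject=subject_id,
        score=float(aln.score),
        identities=int(c.identities),
        columns=columns,
    )


def best_hit(
    query: str,
    proteome: dict,
    aligner: Align.PairwiseAligner | None = None,
    min_score: float = 50.0,
    query_id: str = "query",
) -> AlignmentResult | None:
    """Highest-scoring local alignment of ``query`` against a proteome.

    Ties are broken by higher percent identity, then by lexicographically
    smallest subject id.  Returns None when no hit reaches ``min_score``.
    """
    if not proteome:
        raise ValueError("empty target proteome")
    aligner = aligner or make_aligner()
    scores = {sid: aligner.score(query, seq) for sid, seq in proteome.items()}
    top = max(scores.values())
    if top < min_score:
        return None
    tied = sorted(sid for sid, s in scores.items() if s == top)
    results = [
        align_proteins(query, proteome[sid], aligner, query_id=query_id, subject_id=sid)
        for sid in tied
    ]
    results.sort(key=lambda r: (-r.percent_identity, r.subject))
    return results[0]


# ---------------------------------------------------------------------------
# Reciprocal best hit within intervals
# ---------------------------------------------------------------------------

def find_bbh(
    interval_genes_a: dict,
    interval_genes_b: dict,
    proteome_a: dict,
    proteome_b: dict,
    aligner: Align.PairwiseAligner | None = None,
    min_score: float = 50.0,
) -> list[BBHPair]:
    """Reciprocal-best-hit pairs between two species' QTL interval genes.

    ``interval_genes_*`` map gene id -> interval label for genes inside QTL
    intervals; searches run against the *full* proteomes.  The construction
    is symmetric in A and B.  Genes without a protein are skipped with a
    warning.  Output is a partial matching (no gene in two pairs), sorted
    by species-A gene id.
    """
    aligner = aligner or make_aligner()
    fwd_cache: dict = {}

    def _bh(gene, src, dst):
        key = (gene, id(dst))
        if key not in fwd_cache:
            fwd_cache[key] = best_hit(src[gene], dst, aligner, min_score, query_id=gene)
        return fwd_cache[key]

    pairs = []
    seen_b = set()
    for ga in sorted(interval_genes_a):
        if ga not in proteome_a:
            warnings.warn(f"gene {ga} has no protein; skipped", stacklevel=2)
            continue
        fwd = _bh(ga, proteome_a, proteome_b)
        if fwd is None:
            continue
        gb = fwd.subject
        if gb not in interval_genes_b:
            continue
        rev = _bh(gb, proteome_b, proteome_a)
        if rev is None or rev.subject != ga:
            continue
        if gb in seen_b:
            raise RuntimeError(f"gene {gb} matched twice; matching invariant violated")
        seen_b.add(gb)
        pairs.append(
            BBHPair(
                gene_a=ga,
                gene_b=gb,
                forward=fwd,
                reverse=rev,
                interval_a=interval_genes_a[ga],
                interval_b=interval_genes_b[gb],
            )
        )
    return pairs


def report_candidates(pairs: list[BBHPair], gene_names: dict | None = None) -> pd.DataFrame:
    """Candidate table: one row per BBH pair, sorted by species-A QTL label.

    Columns mirror a published ortholog-candidate table: both QTL labels,
    both gene ids, percent identity, and an optional common gene name.
    """
    gene_names = gene_names or {}
    seen_a, seen_b = set(), set()
    rows = []
    for p in pairs:
        if p.gene_a in seen_a or p.gene_b in seen_b:
            raise ValueError(f"duplicate gene in pair ({p.gene_a}, {p.gene_b})")
        seen_a.add(p.gene_a)
        seen_b.add(p.gene_b)
        rows.append(
            {
                "qtl_a": p.interval_a,
                "gene_a": p.gene_a,
                "qtl_b": p.interval_b,
                "gene_b": p.gene_b,
                "percent_identity": round(p.percent_identity, 1),
                "name": gene_names.get(p.gene_a, gene_names.get(p.gene_b, "")),
            }
        )
    df = pd.DataFrame(
        rows, columns=["qtl_a", "gene_a", "qtl_b", "gene_b", "percent_identity", "name"]
    )
    return df.sort_values(["qtl_a", "gene_a"]).reset_index(drop=True) if len(df) else df


def _interval_gene_map(genes, anchors, intervals) -> dict:
    out: dict = {}
    for _, iv in intervals.iterrows():
        chrom, lo, hi, _ = cm_to_bp((iv["chrom"], iv["cM_lo"], iv["cM_hi"]), anchors)
        for g in genes_in_interval(genes, (chrom, lo, hi)):
            out.setdefault(g, iv["label"])
    return out


def run_orthology(
    genes_a,
    proteins_a,
    anchors_a,
    intervals_a,
    genes_b,
    proteins_b,
    anchors_b,
    intervals_b,
    min_score: float = 50.0,
    gene_names: dict | None = None,
):
    """Full interval-to-candidate-table pipeline for two species.

    cM intervals -> bp via anchors, gene extraction, reciprocal best hit
    against the full proteomes, and the candidate report.  Returns
    (pairs, table).
    """
    ig_a = _interval_gene_map(genes_a, anchors_a, intervals_a)
    ig_b = _interval_gene_map(genes_b, anchors_b, intervals_b)
    pairs = find_bbh(ig_a, ig_b, proteins_a, proteins_b, min_score=min_score)
    return pairs, report_candidates(pairs, gene_names)


def parse_tabular_hits(path) -> pd.DataFrame:
    """Adapter for external tabular search output (blast outfmt-6 style).

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore.  Lets full-genome searches run
    through an external engine while the BBH logic stays in-package.
    """
    cols = [
        "query", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    return pd.read_csv(path, sep="\t", names=cols, comment="#")
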