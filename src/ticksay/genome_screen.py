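"""Genome screening: local alignment, gene-cluster completeness, synteny,
fragmentation, fragment-based ANI, and morphotype/chemotype rules.

The screening questions this module answers, for an *Aspergillus flavus*
isolate genome, are the ones that decide its biocontrol profile:

* is a biosynthetic gene cluster (e.g. the ~29-gene aflatoxin cluster or the
  3-gene kojic acid cluster) present, complete and in the reference gene
  order (synteny)?
* which genes are fragmented, what is missing, and does the missing part
  include a known active site?
* how close is the genome to reference strains, summarised as a fragment
  based average nucleotide identity (ANI)?
* phenotype rules: sclerotium-diameter morphotype (L vs S at 400 µm) and the
  aflatoxin chemotype implied by the completeness of the G-type genes
  (aflU, aflF).

Alignment is a deliberately small, self-contained seed-and-extend local
aligner (exact-word seeding, ungapped X-drop extension, co-diagonal hit
chaining across small indels) with Karlin–Altschul E-values.  It is a
screening instrument for near-identical sequences, not a general homology
search tool.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Sequence",
    "AlignParams",
    "AlignmentHit",
    "GeneReport",
    "ClusterReport",
    "FragmentationReport",
    "ANIResult",
    "SeedExtendAligner",
    "local_align_hits",
    "gene_report",
    "cluster_screen",
    "synteny_concordance",
    "fragmentation_report",
    "ani_fragment",
    "classify_morphotype",
    "chemotype_inference",
    "fold_difference",
    "hits_to_tsv",
]

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over {A, C, G, T, N}, canonically uppercase."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        res = self.residues.upper()
        if not res:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(res) - _VALID
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "Sequence":
        return Sequence(self.id, self.residues.translate(_COMPLEMENT)[::-1])


def _ungapped_lambda(match: float, mismatch: float) -> float:
    """Karlin–Altschul lambda for uniform-composition DNA scoring."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(optimize.brentq(f, 1e-6, 10.0))


@dataclass(frozen=True)
class AlignParams:
    """Seed-and-extend parameters and E-value statistics.

    Defaults: match +1 / mismatch -2 scoring (lambda solved numerically,
    K = 0.621, the standard ungapped DNA value), 11 bp exact-word seeds,
    X-drop 20.  Gap penalties apply when co-diagonal hits are chained across
    a small indel (open 2.5, extend 0.5 per bp, band ``max_chain_gap``).
    """

    word_size: int = 11
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 2.5
    gap_extend: float = 0.5
    xdrop: float = 20.0
    evalue_max: float = 1e-3
    max_chain_gap: int = 30
    karlin_k: float = 0.621

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")

    @property
    def karlin_lambda(self) -> float:
        return _ungapped_lambda(self.match, self.mismatch)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment in BLAST-tabular conventions.

    Coordinates are 1-based inclusive; minus-strand hits carry
    ``s_start > s_end``.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    bit_score: float
    e_value: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity must lie in [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end


@dataclass(frozen=True)
class GeneReport:
    """Per-gene screening evidence: hit list collapsed to coverage/identity.

    ``coverage_pct`` is the union of query spans of retained hits over the
    gene length; ``identity_pct`` the alignment-length-weighted mean hit
    identity (NaN when there are no hits); ``complete`` means coverage at or
    above the completeness threshold the report was built with.
    """

    gene: str
    length: int
    hits: tuple[AlignmentHit, ...]
    coverage_pct: float
    identity_pct: float
    best_e_value: float
    complete: bool

    @property
    def best_hit(self) -> AlignmentHit | None:
        return max(self.hits, key=lambda h: h.bit_score) if self.hits else None


@dataclass(frozen=True)
class ClusterReport:
    """Whole-cluster completeness and synteny summary."""

    cluster: str
    gene_reports: tuple[GeneReport, ...]
    span_bp: int
    n_genes: int
    mean_coverage_pct: float
    mean_identity_pct: float
    synteny_tau: float
    colinear: bool

    def gene(self, name: str) -> GeneReport:
        for gr in self.gene_reports:
            if gr.gene == name:
                return gr
        raise KeyError(name)

    def to_json(self) -> str:
        def clean(v):
            return None if isinstance(v, float) and math.isnan(v) else v

        return json.dumps(
            {
                "cluster": self.cluster,
                "span_bp": self.span_bp,
                "n_genes": self.n_genes,
                "mean_coverage_pct": clean(self.mean_coverage_pct),
                "mean_identity_pct": clean(self.mean_identity_pct),
                "synteny_tau": clean(self.synteny_tau),
                "colinear": self.colinear,
                "genes": [
                    {
                        "gene": g.gene,
                        "length": g.length,
                        "n_hits": len(g.hits),
                        "coverage_pct": clean(g.coverage_pct),
                        "identity_pct": clean(g.identity_pct),
                        "best_e_value": clean(g.best_e_value),
                        "complete": g.complete,
                    }
                    for g in self.gene_reports
                ],
            },
            indent=2,
        )


@dataclass(frozen=True)
class FragmentationReport:
    """How a gene's alignment evidence tiles the reference gene.

    Fragments are query (reference-gene) spans, 1-based inclusive, sorted by
    start.  ``overlaps`` holds the pairwise overlap (bp) between consecutive
    fragments.  On a full tiling (no internal gaps) the bookkeeping conserves
    length:  missing_prefix + sum(lengths) - sum(overlaps) + missing_suffix
    = gene length.
    """

    gene: str
    gene_length: int
    fragments: tuple[tuple[int, int], ...]
    lengths: tuple[int, ...]
    overlaps: tuple[int, ...]
    missing_prefix: int
    missing_suffix: int

    def covers_position(self, position: int) -> bool:
        """Whether a 1-based reference site (e.g. an active site) is covered."""
        return any(s <= position <= e for s, e in self.fragments)

    @classmethod
    def from_spans(
        cls, gene: str, gene_length: int, spans: Iterable[tuple[int, int]]
    ) -> "FragmentationReport":
        spans = tuple(sorted((int(s), int(e)) for s, e in spans))
        if not spans:
            raise ValueError("cannot report fragmentation of an unhit gene")
        if any(s < 1 or e < s for s, e in spans):
            raise ValueError("fragment spans must be 1-based with start <= end")
        lengths = tuple(e - s + 1 for s, e in spans)
        overlaps = tuple(
            max(0, spans[i][1] - spans[i + 1][0] + 1) for i in range(len(spans) - 1)
        )
        return cls(
            gene=gene,
            gene_length=int(gene_length),
            fragments=spans,
            lengths=lengths,
            overlaps=overlaps,
            missing_prefix=spans[0][0] - 1,
            missing_suffix=max(0, int(gene_length) - spans[-1][1]),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene": self.gene,
                "gene_length": self.gene_length,
                "fragments": [list(f) for f in self.fragments],
                "lengths": list(self.lengths),
                "overlaps": list(self.overlaps),
                "missing_prefix": self.missing_prefix,
                "missing_suffix": self.missing_suffix,
            },
            indent=2,
        )


@dataclass(frozen=True)
class ANIResult:
    """Fragment-based average nucleotide identity (asymmetric in query/ref)."""

    ani_pct: float
    fragments_total: int
    fragments_mapped: int
    fragment_len: int
    min_identity: float

    @property
    def defined(self) -> bool:
        return self.fragments_mapped > 0


# ---------------------------------------------------------------------------
# Seed-and-extend aligner
# ---------------------------------------------------------------------------


def _encode(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


_N_BYTE = ord("N")


class SeedExtendAligner:
    """Local aligner holding a word index of one subject sequence.

    Build once per subject and reuse across queries (cluster screens, ANI
    fragments): index construction dominates for large subjects.
    """

    def __init__(self, subject: Sequence, params: AlignParams | None = None):
        self.subject = subject
        self.params = params or AlignParams()
        self._lambda = self.params.karlin_lambda
        self._fwd = _encode(subject.residues)
        self._rev = _encode(subject.reverse_complement().residues)
        self._index_fwd = self._build_index(subject.residues)
        self._index_rev = self._build_index(subject.reverse_complement().residues)

    def _build_index(self, residues: str) -> dict[str, list[int]]:
        w = self.params.word_size
        index: dict[str, list[int]] = {}
        for i in range(len(residues) - w + 1):
            word = residues[i : i + w]
            if "N" in word:
                continue
            index.setdefault(word, []).append(i)
        return index

    # -- extension ---------------------------------------------------------

    def _extend_on_diagonal(
        self,
        qa: np.ndarray,
        sa: np.ndarray,
        diag: int,
        seed_qpos: np.ndarray,
    ) -> list[tuple[int, int, int, int, float]]:
        """X-drop extend seeds on one diagonal (spos = qpos + diag).

        Returns (q_start0, q_end0, matches, length, score) tuples with
        0-based inclusive query coordinates.
        """
        p = self.params
        q0 = max(0, -diag)
        q1 = min(len(qa), len(sa) - diag)
        if q1 - q0 < p.word_size:
            return []
        qs = qa[q0:q1]
        ss = sa[q0 + diag : q1 + diag]
        eq = (qs == ss) & (qs != _N_BYTE) & (ss != _N_BYTE)
        scores = np.where(eq, p.match, p.mismatch)
        hits = []
        covered = -1
        for qpos in np.sort(seed_qpos):
            i = int(qpos) - q0  # local index of seed start
            if i <= covered:
                continue
            # forward from seed start (inclusive)
            fwd = scores[i:]
            cum = np.cumsum(fwd)
            runmax = np.maximum.accumulate(cum)
            drops = np.nonzero(runmax - cum > p.xdrop)[0]
            limit = int(drops[0]) if drops.size else len(fwd)
            if limit == 0:
                continue
            end_rel = int(np.argmax(cum[:limit]))
            # backward from seed start (exclusive)
            bwd = scores[:i][::-1]
            if bwd.size:
                cumb = np.cumsum(bwd)
                runmaxb = np.maximum.accumulate(cumb)
                dropsb = np.nonzero(runmaxb - cumb > p.xdrop)[0]
                limitb = int(dropsb[0]) if dropsb.size else len(bwd)
                if limitb > 0:
                    best_b = int(np.argmax(cumb[:limitb]))
                    start_rel = i - best_b - 1 if cumb[best_b] > 0 else i
                else:
                    start_rel = i
            else:
                start_rel = i
            lo, hi = start_rel, i + end_rel
            covered = hi
            matches = int(eq[lo : hi + 1].sum())
            length = hi - lo + 1
            score = matches * p.match + (length - matches) * p.mismatch
            hits.append((lo + q0, hi + q0, matches, length, float(score)))
        return hits


    def _chain(self, raw: list[dict]) -> list[dict]:
        """Merge co-linear hits separated by a small indel into gapped hits."""
        p = self.params
        raw = sorted(raw, key=lambda h: (h["q0"], h["s0"]))
        merged: list[dict] = []
        for h in raw:
            if merged:
                prev = merged[-1]
                qgap = h["q0"] - prev["q1"] - 1
                sgap = h["s0"] - prev["s1"] - 1
                shift = abs(qgap - sgap)
                if (
                    0 <= qgap <= p.max_chain_gap
                    and 0 <= sgap <= p.max_chain_gap
                    and 1 <= shift <= p.max_chain_gap
                ):
                    gap_cost = p.gap_open + p.gap_extend * shift
                    combined = prev["score"] + h["score"] - gap_cost
                    if combined > max(prev["score"], h["score"]):
                        prev.update(
                            q1=h["q1"],
                            s1=h["s1"],
                            matches=prev["matches"] + h["matches"],
                            length=prev["length"] + h["length"] + shift,
                            gap_opens=prev["gap_opens"] + h["gap_opens"] + 1,
                            gap_bp=prev["gap_bp"] + h["gap_bp"] + shift,
                            score=combined,
                        )
                        continue
            merged.append(dict(h))
        return merged

    def search(self, query: Sequence) -> list[AlignmentHit]:
        """All local hits of ``query`` against the subject, both strands,
        filtered at the params E-value cutoff and sorted by bit score."""
        p = self.params
        if len(query) < p.word_size:
            logger.warning(
                "query %s shorter than word size %d: no hits", query.id, p.word_size
            )
            return []
        qa = _encode(query.residues)
        m, n = len(query), len(self.subject)
        hits: list[AlignmentHit] = []
        for strand, sa, index in (
            ("+", self._fwd, self._index_fwd),
            ("-", self._rev, self._index_rev),
        ):
            seeds: dict[int, list[int]] = {}
            qres = query.residues
            for qpos in range(m - p.word_size + 1):
                word = qres[qpos : qpos + p.word_size]
                for spos in index.get(word, ()):
                    seeds.setdefault(spos - qpos, []).append(qpos)
            raw: list[dict] = []
            for diag, qpositions in seeds.items():
                for q0, q1, matches, length, score in self._extend_on_diagonal(
                    qa, sa, diag, np.asarray(qpositions)
                ):
                    raw.append(
                        dict(
                            q0=q0,
                            q1=q1,
                            s0=q0 + diag,
                            s1=q1 + diag,
                            matches=matches,
                            length=length,
                            gap_opens=0,
                            gap_bp=0,
                            score=score,
                        )
                    )
            for h in self._chain(raw):
                bit = (self._lambda * h["score"] - math.log(p.karlin_k)) / math.log(2)
                evalue = p.karlin_k * m * n * math.exp(-self._lambda * h["score"])
                if evalue > p.evalue_max:
                    continue
                if strand == "+":
                    s_start, s_end = h["s0"] + 1, h["s1"] + 1
                else:
                    s_start, s_end = n - h["s0"], n - h["s1"]
                hits.append(
                    AlignmentHit(
                        query_id=query.id,
                        subject_id=self.subject.id,
                        pct_identity=100.0 * h["matches"] / h["length"],
                        align_length=h["length"],
                        mismatches=h["length"] - h["matches"] - h["gap_bp"],
                        gap_opens=h["gap_opens"],
                        q_start=h["q0"] + 1,
                        q_end=h["q1"] + 1,
                        s_start=s_start,
                        s_end=s_end,
                        bit_score=bit,
                        e_value=evalue,
                        score=h["score"],
                    )
                )
        hits.sort(key=lambda h: h.bit_score, reverse=True)
        return hits


def local_align_hits(
    query: Sequence, subject: Sequence, params: AlignParams | None = None
) -> list[AlignmentHit]:
    """One-shot seed-and-extend search of ``query`` against ``subject``."""
    return SeedExtendAligner(subject, params).search(query)


def hits_to_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits as 12-column BLAST-tabular-like TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.align_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.e_value:.2e}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def _union_span_length(spans: Iterable[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(spans):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s + 1
    return total


def gene_report(
    gene: Sequence,
    genome: Sequence,
    params: AlignParams | None = None,
    completeness_threshold: float = 90.0,
    aligner: SeedExtendAligner | None = None,
) -> GeneReport:
    """Screen one gene against a genome.

    Coverage is the union of query spans of retained hits (no double
    counting of overlapping hits); identity the alignment-length-weighted
    mean of hit identities; completeness the coverage >= threshold rule
    (default 90%).
    """
    if aligner is None:
        aligner = SeedExtendAligner(genome, params)
    hits = tuple(aligner.search(gene))
    if hits:
        coverage = 100.0 * _union_span_length(
            (h.q_start, h.q_end) for h in hits
        ) / len(gene)
        coverage = min(coverage, 100.0)
        weights = np.array([h.align_length for h in hits], dtype=float)
        idents = np.array([h.pct_identity for h in hits], dtype=float)
        identity = float((weights * idents).sum() / weights.sum())
        best_e = min(h.e_value for h in hits)
    else:
        coverage, identity, best_e = 0.0, math.nan, math.nan
    return GeneReport(
        gene=gene.id,
        length=len(gene),
        hits=hits,
        coverage_pct=coverage,
        identity_pct=identity,
        best_e_value=best_e,
        complete=coverage >= completeness_threshold,
    )


def synteny_concordance(
    gene_reports: TypingSequence[GeneReport],
) -> tuple[float, bool]:
    """Kendall tau between reference gene order and genomic best-hit order.

    Midpoints of each gene's best hit on the genome are rank-correlated with
    the reference order; ties in midpoints are broken by reference order
    (with a logged warning).  ``colinear`` iff ``|tau| = 1``.
    """
    placed = [(i, gr.best_hit) for i, gr in enumerate(gene_reports) if gr.best_hit]
    if len(placed) < 2:
        raise ValueError("synteny undefined: fewer than 2 genes with hits")
    midpoints = [
        (min(h.s_start, h.s_end) + max(h.s_start, h.s_end)) / 2.0 for _, h in placed
    ]
    if len(set(midpoints)) < len(midpoints):
        logger.warning("tied best-hit midpoints: breaking ties by reference order")
        order = np.argsort(np.asarray(midpoints), kind="stable")
        ranks = np.empty(len(midpoints))
        ranks[order] = np.arange(len(midpoints))
        midpoints = list(ranks)
    tau = float(stats.kendalltau([i for i, _ in placed], midpoints).statistic)
    return tau, bool(abs(tau) >= 1.0 - 1e-12)


def cluster_screen(
    cluster_genes: TypingSequence[Sequence],
    genome: Sequence,
    params: AlignParams | None = None,
    completeness_threshold: float = 90.0,
    cluster_name: str = "cluster",
) -> ClusterReport:
    """Screen an ordered gene cluster against a genome.

    Produces per-gene reports, cluster-level means (over genes with at least
    one hit), the synteny concordance of best-hit midpoints, and the genomic
    span from first to last best-hit coordinate.
    """
    if len(cluster_genes) < 2:
        raise ValueError("cluster must have >= 2 genes")
    aligner = SeedExtendAligner(genome, params)
    reports = tuple(
        gene_report(
            g,
            genome,
            completeness_threshold=completeness_threshold,
            aligner=aligner,
        )
        for g in cluster_genes
    )
    with_hits = [r for r in reports if r.hits]
    if with_hits:
        mean_cov = float(np.mean([r.coverage_pct for r in with_hits]))
        mean_ident = float(np.mean([r.identity_pct for r in with_hits]))
        coords = [
            c
            for r in with_hits
            for c in (r.best_hit.s_start, r.best_hit.s_end)
        ]
        span = max(coords) - min(coords) + 1
    else:
        mean_cov, mean_ident, span = 0.0, math.nan, 0
    if len(with_hits) >= 2:
        tau, colinear = synteny_concordance(reports)
    else:
        tau, colinear = math.nan, False
    return ClusterReport(
        cluster=cluster_name,
        gene_reports=reports,
        span_bp=span,
        n_genes=len(cluster_genes),
        mean_coverage_pct=mean_cov,
        mean_identity_pct=mean_ident,
        synteny_tau=tau,
        colinear=colinear,
    )


def fragmentation_report(
    gene: Sequence | int, hits: TypingSequence[AlignmentHit]
) -> FragmentationReport:
    """Project a gene's hits onto the reference gene and account for what is
    missing.

    ``gene`` may be the reference :class:`Sequence` or its length in bp.
    Raises when there are no hits — fragmentation of an unhit gene cannot be
    reported.
    """
    if not hits:
        raise ValueError("cannot report fragmentation of an unhit gene")
    if isinstance(gene, Sequence):
        name, length = gene.id, len(gene)
    else:
        name, length = hits[0].query_id, int(gene)
    return FragmentationReport.from_spans(
        name, length, ((h.q_start, h.q_end) for h in hits)
    )


def ani_fragment(
    query_genome: Sequence,
    ref_genome: Sequence,
    fragment_len: int = 3000,
    min_identity: float = 80.0,
    params: AlignParams | None = None,
) -> ANIResult:
    """Fragment-based average nucleotide identity of ``query`` vs ``ref``.

    The query is cut into consecutive non-overlapping fragments of
    ``fragment_len`` bp; each fragment's best local hit on the reference
    counts as mapped when its identity reaches ``min_identity``; the ANI is
    the mean identity of mapped fragments.  Asymmetric in (query, ref), as
    in the underlying fragment-mapping method.  ANI is NaN (undefined,
    distinct from 0) when nothing maps.
    """
    if len(query_genome) <= fragment_len:
        raise ValueError("query must be longer than fragment_len")
    aligner = SeedExtendAligner(ref_genome, params)
    n_frag = len(query_genome) // fragment_len
    identities = []
    for i in range(n_frag):
        frag = Sequence(
            f"{query_genome.id}|frag{i}",
            query_genome.residues[i * fragment_len : (i + 1) * fragment_len],
        )
        hits = aligner.search(frag)
        if hits and hits[0].pct_identity >= min_identity:
            identities.append(hits[0].pct_identity)
    return ANIResult(
        ani_pct=float(np.mean(identities)) if identities else math.nan,
        fragments_total=n_frag,
        fragments_mapped=len(identities),
        fragment_len=fragment_len,
        min_identity=min_identity,
    )


# ---------------------------------------------------------------------------
# Phenotype rules
# ---------------------------------------------------------------------------


def classify_morphotype(mean_sclerotium_diameter: float) -> str:
    """L/S morphotype from mean sclerotium diameter (µm).

    Morphotype L requires sclerotia *over* 400 µm; 400 µm or below
    (boundary included) is S.
    """
    if not mean_sclerotium_diameter > 0:
        raise ValueError("sclerotium diameter must be > 0 µm")
    return "L" if mean_sclerotium_diameter > 400.0 else "S"


def chemotype_inference(
    cluster_report: ClusterReport,
    g_type_genes: Iterable[str] = ("aflU", "aflF"),
    core_genes: Iterable[str] = ("aflR", "aflC"),
) -> str:
    """Aflatoxin chemotype implied by cluster completeness.

    ``"none"`` when a core gene (pathway regulator aflR or polyketide
    synthase aflC) is incomplete; ``"B-only"`` when the core is complete but
    a G-type-essential gene (aflU, aflF) is not; ``"B+G"`` when everything
    is complete.
    """
    names = {gr.gene for gr in cluster_report.gene_reports}
    missing = (set(g_type_genes) | set(core_genes)) - names
    if missing:
        raise ValueError(f"genes absent from cluster report: {sorted(missing)}")
    if any(not cluster_report.gene(g).complete for g in core_genes):
        return "none"
    if any(not cluster_report.gene(g).complete for g in g_type_genes):
        return "B-only"
    return "B+G"


def fold_difference(a: float, b: float) -> float:
    """Fold difference ``a / b`` between two concentrations (b > 0)."""
    if b <= 0:
        raise ValueError("denominator concentration must be > 0")
    if a < 0:
        raise ValueError("concentration must be >= 0")
    return a / b
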