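"""Producer/consumer trait calling and gene-neighborhood analyses.

A genome is a *potential phosphonate producer* iff it carries a gene
with an above-cutoff pepM homology hit whose protein contains the
catalytic EDK(X)5NS motif. Downstream biosynthesis genes (ppd, pdh,
mpnS) are not required; they are recorded only when adjacent to pepM.

A genome is a *potential consumer* iff one of four catabolic pathways
(C-P lyase, 2-aminoethylphosphonate via PhnWX, PhnYZ, phosphonoacet-
aldehyde phosphonatase) is supported by multiple co-occurring genes
within a single neighborhood window on one contig.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from scipy import stats

from .models import GENE_FAMILIES, GeneFeature, GenomeRecord, HitRecord, TraitCall

_PEPM_MOTIF = re.compile(r"EDK.{5}NS")
_AA_OK = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYBXZJUO*]+$")

#: Adjacency window for recording ppd/pdh/mpnS near pepM: within this
#: many genes or this many bp on the same contig.
ADJACENCY_GENES = 5
ADJACENCY_BP = 10_000


@dataclass
class PathwayRule:
    """Co-occurrence rule for one catabolic pathway."""

    name: str
    required: frozenset[str]
    min_count: int
    window_bp: int = 10_000
    anchor: str | None = None  # family that must itself be present

    def __post_init__(self) -> None:
        if self.min_count > len(self.required):
            raise ValueError(f"{self.name}: min_count exceeds |required|")
        unknown = self.required - GENE_FAMILIES
        if unknown:
            raise ValueError(f"{self.name}: unknown families {sorted(unknown)}")


def default_pathway_rules() -> list[PathwayRule]:
    """The four consumption-pathway rules.

    C-P lyase needs the catalytic phnJ plus at least two other cluster
    genes; the two-gene pathways need both members; phosphonatase
    accepts a standalone above-cutoff phnX.
    """
    return [
        PathwayRule(
            name="CP_lyase",
            required=frozenset({"phnG", "phnH", "phnI", "phnJ", "phnK", "phnL", "phnM"}),
            min_count=3,
            anchor="phnJ",
        ),
        PathwayRule(name="AEP_PhnWX", required=frozenset({"phnW", "phnX"}), min_count=2),
        PathwayRule(name="PhnYZ", required=frozenset({"phnY", "phnZ"}), min_count=2),
        PathwayRule(name="phosphonatase", required=frozenset({"phnX"}), min_count=1),
    ]


def validate_pepm_motif(protein: str) -> bool:
    """True iff the protein contains the catalytic EDK(X)5NS signature:
    E, D, K, exactly five arbitrary residues, N, S, contiguous, at any
    position."""
    if not protein:
        raise ValueError("empty protein")
    if not _AA_OK.match(protein):
        raise ValueError("protein contains non-amino-acid characters")
    return bool(_PEPM_MOTIF.search(protein))


def _best_hits(hits: list[HitRecord]) -> dict[tuple[str, str], HitRecord]:
    """Best-scoring record per (query, family)."""
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.family)
        if key not in best or h.score > best[key].score:
            best[key] = h
    return best


def call_producer(genome: GenomeRecord, hits: list[HitRecord]) -> TraitCall:
    """Producer verdict for one genome.

    ``operon_length_bp`` is the gap-inclusive span (min start to max
    end) over the pepM cassette: the valid pepM gene(s) plus adjacent
    biosynthesis and glycosylation genes on the same contig.
    """
    call = TraitCall(genome_id=genome.genome_id, clade=genome.clade)
    best = _best_hits(hits)
    genes_by_id = {g.gene_id: g for g in genome.genes}

    valid_pepm: list[GeneFeature] = []
    for (qid, fam), h in best.items():
        if fam != "pepM" or not h.above_cutoff or qid not in genes_by_id:
            continue
        gene = genes_by_id[qid]
        ok = bool(gene.protein) and validate_pepm_motif(gene.protein)
        call.pepm_genes.append((qid, ok))
        if ok:
            valid_pepm.append(gene)
    call.pepm_genes.sort()

    if not valid_pepm:
        return call
    call.is_producer = True

    # Cassette members: biosynthesis + glyco genes adjacent to a valid
    # pepM (same contig, within ADJACENCY_GENES gene ranks or
    # ADJACENCY_BP). Non-adjacent copies elsewhere in the genome are
    # flagged as a possible contig-break cassette but do not change the
    # verdict.
    neighbor_fams = {"ppd", "pdh", "mpnS", "pglC", "pglL", "wzx"}
    cassette = list(valid_pepm)
    for pep in valid_pepm:
        same_contig = sorted(
            (g for g in genome.genes if g.contig_id == pep.contig_id),
            key=lambda g: g.start,
        )
        rank = {g.gene_id: i for i, g in enumerate(same_contig)}
        for g in same_contig:
            if g.family not in neighbor_fams:
                continue
            near_rank = abs(rank[g.gene_id] - rank[pep.gene_id]) <= ADJACENCY_GENES
            near_bp = (
                min(abs(g.start - pep.end), abs(pep.start - g.end)) <= ADJACENCY_BP
                or not (g.end <= pep.start or pep.end <= g.start)
            )
            if near_rank or near_bp:
                cassette.append(g)
                if g.family in {"ppd", "pdh", "mpnS"}:
                    call.adjacent_biosynthesis.add(g.family)

    off_contig = {
        g.family
        for g in genome.genes
        if g.family in {"ppd", "pdh", "mpnS"}
        and g.contig_id not in {p.contig_id for p in valid_pepm}
    }
    call.cross_contig_cassette = bool(off_contig - call.adjacent_biosynthesis)

    # Span per pepM contig; use the widest cassette span.
    spans = []
    for cid in {g.contig_id for g in valid_pepm}:
        members = [g for g in cassette if g.contig_id == cid]
        spans.append(max(g.end for g in members) - min(g.start for g in members))
    call.operon_length_bp = max(spans)
    return call


def call_consumer(
    genome: GenomeRecord,
    hits: list[HitRecord],
    rules: list[PathwayRule] | None = None,
) -> TraitCall:
    """Consumer verdict: a pathway is called iff its minimum co-occurring
    family count is met within one window on a single contig."""
    rules = rules if rules is not None else default_pathway_rules()
    call = TraitCall(genome_id=genome.genome_id, clade=genome.clade)
    best = _best_hits(hits)
    hit_genes: dict[str, set[str]] = {}
    for (qid, fam), h in best.items():
        if h.above_cutoff:
            hit_genes.setdefault(qid, set()).add(fam)

    by_contig: dict[str, list[GeneFeature]] = {}
    for g in genome.genes:
        if g.gene_id in hit_genes:
            by_contig.setdefault(g.contig_id, []).append(g)

    for rule in rules:
        if _pathway_called(rule, by_contig, hit_genes):
            call.pathways.add(rule.name)
    call.is_consumer = bool(call.pathways)
    return call


def _pathway_called(
    rule: PathwayRule,
    by_contig: dict[str, list[GeneFeature]],
    hit_genes: dict[str, set[str]],
) -> bool:
    for genes in by_contig.values():
        genes = sorted(genes, key=lambda g: g.start)
        relevant = [
            g for g in genes if hit_genes.get(g.gene_id, set()) & rule.required
        ]
        if not relevant:
            continue
        # Exhaustive window scan anchored at each relevant gene.
        for i, g0 in enumerate(relevant):
            fams: set[str] = set()
            for g in relevant[i:]:
                if g.end - g0.start > rule.window_bp:
                    break
                fams |= hit_genes[g.gene_id] & rule.required
            if len(fams) >= rule.min_count and (
                rule.anchor is None or rule.anchor in fams
            ):
                return True
    return False


def call_traits(
    genome: GenomeRecord,
    hits: list[HitRecord],
    rules: list[PathwayRule] | None = None,
) -> TraitCall:
    """Combined producer + consumer call for one genome."""
    prod = call_producer(genome, hits)
    cons = call_consumer(genome, hits, rules)
    prod.is_consumer = cons.is_consumer
    prod.pathways = cons.pathways
    return prod


def colocalize(
    genome: GenomeRecord,
    family_a: str,
    family_b: str,
    segment_bp: int = 10_000,
    same_contig: bool = True,
) -> dict:
    """Do two families co-occur within one genome segment?

    ``same_contig`` mode: some (a, b) gene pair on one contig spans
    (max end - min start) <= segment_bp. Relaxed mode: both families
    occur anywhere in the genome, contigs disregarded (partial
    assemblies break cassettes across contigs).
    """
    if segment_bp <= 0:
        raise ValueError("segment_bp must be positive")
    a_genes = genome.genes_by_family(family_a)
    b_genes = genome.genes_by_family(family_b)
    if not a_genes or not b_genes:
        return {"colocalized": False, "min_span": None}
    if not same_contig:
        return {"colocalized": True, "min_span": None}
    min_span = None
    for a in a_genes:
        for b in b_genes:
            if a.contig_id != b.contig_id:
                continue
            span = max(a.end, b.end) - min(a.start, b.start)
            if min_span is None or span < min_span:
                min_span = span
    return {
        "colocalized": min_span is not None and min_span <= segment_bp,
        "min_span": min_span,
    }


def enrichment_test(
    neighborhood_genes: int,
    neighborhood_hits: int,
    universe_genes: int,
    universe_hits: int,
) -> float:
    """Upper-tail hypergeometric enrichment P(X >= observed).

    Drawing ``neighborhood_genes`` from a universe of ``universe_genes``
    containing ``universe_hits`` marked genes, the probability of seeing
    at least ``neighborhood_hits`` marked genes.
    """
    if not (
        0 <= neighborhood_hits <= neighborhood_genes <= universe_genes
        and 0 <= universe_hits <= universe_genes
        and neighborhood_hits <= universe_hits
    ):
        raise ValueError("inconsistent counts")
    if neighborhood_hits == 0:
        return 1.0
    return float(
        stats.hypergeom.sf(
            neighborhood_hits - 1, universe_genes, universe_hits, neighborhood_genes
        )
    )


def summarize_calls(calls: list[TraitCall]) -> dict:
    """Collection-level summary of trait calls.

    ``pct_dual`` is reported to one decimal against two denominators:
    all genomes, and genomes bearing at least one trait (the natural
    alternative reading of a 'dual-trait fraction').
    """
    if not calls:
        raise ValueError("empty call list")
    n_total = len(calls)
    n_producer = sum(c.is_producer for c in calls)
    n_consumer = sum(c.is_consumer for c in calls)
    n_dual = sum(c.dual_trait for c in calls)
    n_trait = sum(c.is_producer or c.is_consumer for c in calls)
    per_clade: dict[str, dict] = {}
    for c in calls:
        d = per_clade.setdefault(
            c.clade or "unknown",
            {"n_total": 0, "n_producer": 0, "n_consumer": 0, "n_dual": 0},
        )
        d["n_total"] += 1
        d["n_producer"] += c.is_producer
        d["n_consumer"] += c.is_consumer
        d["n_dual"] += c.dual_trait
    return {
        "n_total": n_total,
        "n_producer": n_producer,
        "n_consumer": n_consumer,
        "n_dual": n_dual,
        "pct_dual": round(100.0 * n_dual / n_total, 1),
        "pct_dual_of_trait_bearing": (
            round(100.0 * n_dual / n_trait, 1) if n_trait else 0.0
        ),
        "per_clade": per_clade,
    }
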