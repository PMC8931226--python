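"""Metagenome read classification and marker-normalized trait fractions.

Reads (peptides) are assigned to gene families by a best-hit-with-decoys
rule: a read belongs to family F iff its best-scoring reference over
targets plus decoys is in F and the score clears F's cutoff. This
operationalizes reciprocal-best-hit filtering for short reads, where a
true bidirectional search is ill-defined.

The per-genome unit comes from ten single-copy marker families: the
fraction of genomes carrying the production trait is the
length-normalized pepM read abundance divided by the median
length-normalized abundance of the ten markers. The ratio is invariant
to sequencing depth by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import MARKER_FAMILIES, HitRecord

KMER_SIZE = 5  # amino-acid k-mer for the built-in scorer


def _kmers(seq: str, k: int = KMER_SIZE) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class KmerScorer:
    """Shared amino-acid 5-mer counting against family references.

    A deliberately simple stand-in scorer for synthetic error-free
    peptide reads; external aligner hit tables are accepted wherever a
    scorer would be used.
    """

    def __init__(self, references: dict[str, str], k: int = KMER_SIZE):
        self.k = k
        self.ref_kmers = {name: _kmers(seq, k) for name, seq in references.items()}

    def score(self, read: str, ref_name: str) -> int:
        return len(_kmers(read, self.k) & self.ref_kmers[ref_name])

    def best_hit(self, read: str) -> tuple[str, int]:
        """Best reference by shared k-mers; ties broken by reference id."""
        rk = _kmers(read, self.k)
        best_name, best_score = "", -1
        for name in sorted(self.ref_kmers):
            s = len(rk & self.ref_kmers[name])
            if s > best_score:
                best_name, best_score = name, s
        return best_name, best_score


def classify_reads(
    reads: list[tuple[str, str]],
    target_refs: dict[str, str],
    decoy_refs: dict[str, str] | None = None,
    score_cutoffs: dict[str, float] | None = None,
    default_cutoff: float = 5.0,
) -> list[HitRecord]:
    """Assign each read to a target family or 'none'.

    ``target_refs`` maps family -> reference protein; ``decoy_refs``
    are competing references whose wins veto assignment. A read is
    assigned to family F iff its best hit overall is F's reference and
    the score >= cutoff(F).
    """
    if not target_refs:
        raise ValueError("no target references")
    score_cutoffs = score_cutoffs or {}
    refs: dict[str, str] = {}
    fam_of: dict[str, str] = {}
    for fam, seq in target_refs.items():
        rid = f"target::{fam}"
        refs[rid] = seq
        fam_of[rid] = fam
    for name, seq in (decoy_refs or {}).items():
        refs[f"decoy::{name}"] = seq
    scorer = KmerScorer(refs)
    out = []
    for rid, seq in reads:
        ref, score = scorer.best_hit(seq)
        fam = fam_of.get(ref)
        if fam is not None and score >= score_cutoffs.get(fam, default_cutoff):
            out.append(HitRecord(query_id=rid, family=fam, score=score, above_cutoff=True))
        else:
            out.append(HitRecord(query_id=rid, family="none", score=score, above_cutoff=False))
    return out


@dataclass
class ReadProfile:
    """Per-family read counts normalized by reference length."""

    counts: dict[str, int]
    lengths: dict[str, float]  # residues
    marker_set: tuple[str, ...] = MARKER_FAMILIES
    taxon_scope: str = "all"
    normalized: dict[str, float] = field(init=False)
    marker_median: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.marker_set) != 10:
            raise ValueError("exactly 10 marker families are required")
        for fam, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {fam}")
            if n > 0 and fam not in ("none",) and self.lengths.get(fam, 0) <= 0:
                raise ValueError(f"family {fam} has hits but no positive length")
        self.normalized = {
            fam: self.counts.get(fam, 0) / self.lengths[fam]
            for fam in self.lengths
        }
        # A marker absent from the hit table contributes abundance 0.
        vals = sorted(self.normalized.get(fam, 0.0) for fam in self.marker_set)
        self.marker_median = (vals[4] + vals[5]) / 2.0


def profile(
    hits: list[HitRecord],
    family_lengths: dict[str, float],
    marker_set: tuple[str, ...] = MARKER_FAMILIES,
    taxon_scope: str = "all",
) -> ReadProfile:
    """Build a ReadProfile from classified reads."""
    counts: dict[str, int] = {}
    for h in hits:
        if h.family == "none" or not h.above_cutoff:
            continue
        counts[h.family] = counts.get(h.family, 0) + 1
    return ReadProfile(
        counts=counts,
        lengths=dict(family_lengths),
        marker_set=tuple(marker_set),
        taxon_scope=taxon_scope,
    )


@dataclass
class TraitAbundance:
    taxon_scope: str
    pepm_norm: float
    marker_median: float
    producer_fraction_pct: float
    flags: list[str] = field(default_factory=list)


def producer_fraction(prof: ReadProfile, pepm_family: str = "pepM") -> TraitAbundance:
    """Fraction of genomes carrying the production trait, as a percent.

    (pepM count / pepM length) / median marker normalized abundance.
    Values above 100% (multi-copy families or noise) are reported with
    a flag, never capped.
    """
    pepm_norm = prof.normalized.get(pepm_family, 0.0)
    flags = []
    if prof.marker_median <= 0:
        return TraitAbundance(
            taxon_scope=prof.taxon_scope,
            pepm_norm=pepm_norm,
            marker_median=prof.marker_median,
            producer_fraction_pct=float("nan"),
            flags=["undefined: marker median is zero"],
        )
    pct = 100.0 * pepm_norm / prof.marker_median
    if pct > 100.0:
        flags.append("fraction exceeds 100%")
    return TraitAbundance(
        taxon_scope=prof.taxon_scope,
        pepm_norm=pepm_norm,
        marker_median=prof.marker_median,
        producer_fraction_pct=pct,
        flags=flags,
    )
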