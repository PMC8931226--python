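"""Synthetic genome collections, metagenomes, spectra and sample tables
with known ground truth.

The generator emulates the inputs of a single-cell-genomics phosphonate
survey: partial single-cell assemblies with planted biosynthesis or
catabolism cassettes, peptide read sets drawn from a community with a
known trait frequency, Lorentzian 31P spectra with configured peak
areas, and per-sample trait counts from a beta-binomial depth/basin
model. Every generated object carries a truth record; pipeline outputs
are validated against truth, never against other pipeline outputs.

Incompleteness is modeled as whole-contig dropout (single-cell assembly
loss is contig-grained, not base-grained): contigs are retained so the
realized length fraction is as close as possible to the target
completeness. Cassettes sit on one uniformly chosen contig, so cassette
survival is Bernoulli(completeness) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    AMINO_ACIDS,
    MARKER_FAMILIES,
    GeneFeature,
    GenomeRecord,
    HitRecord,
    Spectrum,
)

# Producer cassette: pepM + decarboxylase/dehydrogenase (+ optional MpnS,
# + glycosylation genes within the same neighborhood).
PRODUCER_CORE = ("pepM", "ppd", "pdh")
PRODUCER_OPTIONAL = ("mpnS",)
PRODUCER_GLYCO = ("pglC", "wzx", "pglL")

# Four catabolic cassettes, one per consumption pathway.
CONSUMER_CASSETTES: dict[str, tuple[str, ...]] = {
    "CP_lyase": ("phnG", "phnH", "phnI", "phnJ", "phnK", "phnL", "phnM"),
    "AEP_PhnWX": ("phnW", "phnX"),
    "PhnYZ": ("phnY", "phnZ"),
    "phosphonatase": ("phnX",),
}

PEPM_MOTIF_PREFIX = "EDK"
PEPM_MOTIF_SUFFIX = "NS"


@dataclass
class GenomeTruth:
    genome_id: str
    clade: str
    is_producer: bool
    is_consumer: bool
    pathways: set[str]
    cassette_retained: bool
    true_length: int
    target_completeness: float
    realized_completeness: float


@dataclass
class SynthTruth:
    """Ground truth for one generator call; the seed is recorded."""

    seed: int
    genomes: dict[str, GenomeTruth] = field(default_factory=dict)
    community: dict[str, float] = field(default_factory=dict)
    read_sources: dict[str, str] = field(default_factory=dict)
    spectrum_peaks: list[tuple[float, float, float]] = field(default_factory=list)
    sample_params: dict[str, float] = field(default_factory=dict)


@dataclass
class GenomeConfig:
    """Study conditions for a synthetic genome collection.

    Defaults emulate a tropical-ocean single-cell survey: ~1.5 Mbp
    streamlined genomes over ~25 contigs, producer frequency 0.15,
    consumer frequency 0.20, dual-trait frequency 0.007.
    """

    n_genomes: int = 100
    clades: tuple[str, ...] = ("Prochlorococcus-HLII", "SAR11-Ia")
    clade_weights: tuple[float, ...] | None = None
    producer_freq: float | dict[str, float] = 0.15
    consumer_freq: float | dict[str, float] = 0.20
    dual_freq: float = 0.007
    mean_genome_length: int = 1_500_000
    n_contigs: int = 25
    completeness: float | tuple[float, float] = 1.0  # scalar or Uniform(lo, hi)
    decoy_freq: float = 0.05  # motif-less pepM-like decoy genes
    genes_per_contig: int = 4
    protein_len: int = 120

    def freq(self, which: str, clade: str) -> float:
        v = getattr(self, which)
        return v.get(clade, 0.0) if isinstance(v, dict) else float(v)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_pepm_protein(rng: np.random.Generator, length: int = 120) -> str:
    """Random protein carrying the catalytic EDK(X)5NS signature."""
    motif = (
        PEPM_MOTIF_PREFIX + _random_protein(rng, 5) + PEPM_MOTIF_SUFFIX
    )
    body = _random_protein(rng, max(length - len(motif), 10))
    pos = int(rng.integers(0, len(body) + 1))
    return body[:pos] + motif + body[pos:]


def make_decoy_pepm_protein(rng: np.random.Generator, length: int = 120) -> str:
    """pepM-homologous decoy whose protein lacks the catalytic motif."""
    while True:
        p = _random_protein(rng, length)
        from .traitcall import validate_pepm_motif

        if not validate_pepm_motif(p):
            return p


def _place_cassette(
    rng: np.random.Generator,
    families: tuple[str, ...],
    contig_id: str,
    contig_len: int,
    genome_id: str,
    tag: str,
    gene_len: int = 900,
    gap: int = 100,
) -> list[GeneFeature]:
    """Place a contiguous cassette of ``families`` on one contig."""
    span = len(families) * gene_len + (len(families) - 1) * gap
    if span > contig_len:
        raise ValueError(
            f"cassette of {len(families)} genes ({span} bp) does not fit on "
            f"contig of {contig_len} bp"
        )
    start = int(rng.integers(0, contig_len - span + 1))
    genes = []
    pos = start
    for k, fam in enumerate(families):
        prot_len = gene_len // 3
        if fam == "pepM":
            prot = make_pepm_protein(rng, prot_len)
        else:
            prot = _random_protein(rng, prot_len)
        genes.append(
            GeneFeature(
                gene_id=f"{genome_id}_{tag}_{k:02d}",
                contig_id=contig_id,
                start=pos,
                end=pos + gene_len,
                strand="+" if rng.random() < 0.5 else "-",
                family=fam,
                protein=prot,
            )
        )
        pos += gene_len + gap
    return genes


def gen_genomes(
    config: GenomeConfig, seed: int
) -> tuple[list[GenomeRecord], SynthTruth]:
    """Generate a genome collection with planted trait cassettes.

    Producer genomes carry a contiguous pepM cassette (pepM, ppd, pdh,
    optionally mpnS, plus glycosylation genes nearby); consumer genomes
    carry one of the four catabolic cassettes. Incompleteness drops whole
    contigs; truth records whether each cassette survived dropout.
    """
    for which in ("producer_freq", "consumer_freq", "dual_freq"):
        v = getattr(config, which)
        vals = v.values() if isinstance(v, dict) else [v]
        if any(not (0.0 <= x <= 1.0) for x in vals):
            raise ValueError(f"{which} must lie in [0, 1]")
    if config.n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")

    rng = np.random.default_rng(seed)
    truth = SynthTruth(seed=seed)
    genomes: list[GenomeRecord] = []

    weights = config.clade_weights or tuple(
        1.0 / len(config.clades) for _ in config.clades
    )
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()

    for i in range(config.n_genomes):
        gid = f"G{i:05d}"
        clade = str(rng.choice(list(config.clades), p=weights))

        # True (complete) genome: n_contigs with jittered lengths.
        base = config.mean_genome_length / config.n_contigs
        lengths = np.maximum(
            (base * rng.uniform(0.6, 1.4, size=config.n_contigs)).astype(int), 2_000
        )
        contig_ids = [f"{gid}_c{j:02d}" for j in range(config.n_contigs)]
        contigs = list(zip(contig_ids, (int(x) for x in lengths)))
        true_length = int(lengths.sum())

        genes: list[GeneFeature] = []
        # Background genes (few per contig keeps large collections cheap).
        for cid, clen in contigs:
            for k in range(config.genes_per_contig):
                glen = 3 * config.protein_len
                start = int(rng.integers(0, clen - glen))
                fam = "other"
                genes.append(
                    GeneFeature(
                        gene_id=f"{cid}_g{k}",
                        contig_id=cid,
                        start=start,
                        end=start + glen,
                        strand="+" if rng.random() < 0.5 else "-",
                        family=fam,
                        protein="",
                    )
                )
        # One copy of each single-copy marker, spread over contigs.
        for m, fam in enumerate(MARKER_FAMILIES):
            cid, clen = contigs[m % len(contigs)]
            glen = 3 * config.protein_len
            start = int(rng.integers(0, clen - glen))
            genes.append(
                GeneFeature(
                    gene_id=f"{gid}_{fam}",
                    contig_id=cid,
                    start=start,
                    end=start + glen,
                    strand="+",
                    family=fam,
                    protein="",
                )
            )

        # Trait assignment. Dual-trait genomes are drawn first so the
        # marginal frequencies stay close to the per-trait settings.
        is_dual = rng.random() < config.dual_freq
        if is_dual:
            is_producer = is_consumer = True
        else:
            is_producer = rng.random() < config.freq("producer_freq", clade)
            is_consumer = (not is_producer) and (
                rng.random() < config.freq("consumer_freq", clade)
            )

        cassette_contig_idx: int | None = None
        pathways: set[str] = set()
        if is_producer:
            fams = list(PRODUCER_CORE)
            if rng.random() < 0.5:
                fams += list(PRODUCER_OPTIONAL)
            fams += list(PRODUCER_GLYCO)
            cassette_contig_idx = int(rng.integers(0, config.n_contigs))
            cid, clen = contigs[cassette_contig_idx]
            genes += _place_cassette(rng, tuple(fams), cid, clen, gid, "prod")
        if is_consumer:
            pathway = str(rng.choice(sorted(CONSUMER_CASSETTES)))
            pathways = {pathway}
            idx = (
                cassette_contig_idx
                if cassette_contig_idx is not None
                else int(rng.integers(0, config.n_contigs))
            )
            # Consumer cassette goes on a different contig than the
            # producer cassette to keep placements independent.
            cons_idx = (idx + 1) % config.n_contigs if is_producer else idx
            cid, clen = contigs[cons_idx]
            genes += _place_cassette(
                rng, CONSUMER_CASSETTES[pathway], cid, clen, gid, "cons"
            )
            if cassette_contig_idx is None:
                cassette_contig_idx = cons_idx

        # Motif-less decoy pepM homolog (tests rejection downstream).
        if rng.random() < config.decoy_freq:
            cid, clen = contigs[int(rng.integers(0, config.n_contigs))]
            glen = 3 * config.protein_len
            start = int(rng.integers(0, clen - glen))
            genes.append(
                GeneFeature(
                    gene_id=f"{gid}_decoy",
                    contig_id=cid,
                    start=start,
                    end=start + glen,
                    strand="+",
                    family="pepM",
                    protein=make_decoy_pepm_protein(rng, config.protein_len),
                )
            )

        # Whole-contig dropout to the target completeness.
        if isinstance(config.completeness, tuple):
            target_c = float(rng.uniform(*config.completeness))
        else:
            target_c = float(config.completeness)
        keep = _dropout_contigs(rng, lengths, target_c)
        kept_ids = {contig_ids[j] for j in np.flatnonzero(keep)}
        kept_contigs = [(cid, ln) for cid, ln in contigs if cid in kept_ids]
        kept_genes = [g for g in genes if g.contig_id in kept_ids]
        realized_len = sum(ln for _, ln in kept_contigs)
        realized_c = realized_len / true_length

        cassette_retained = True
        if is_producer:
            cassette_retained = contig_ids[cassette_contig_idx] in kept_ids

        genomes.append(
            GenomeRecord(
                genome_id=gid,
                clade=clade,
                contigs=kept_contigs,
                genes=kept_genes,
                completeness=realized_c,
            )
        )
        truth.genomes[gid] = GenomeTruth(
            genome_id=gid,
            clade=clade,
            is_producer=is_producer,
            is_consumer=is_consumer,
            pathways=pathways,
            cassette_retained=cassette_retained,
            true_length=true_length,
            target_completeness=target_c,
            realized_completeness=realized_c,
        )
    return genomes, truth


def _dropout_contigs(
    rng: np.random.Generator, lengths: np.ndarray, target_c: float
) -> np.ndarray:
    """Retain a random contig subset whose length fraction ~ target_c.

    Contigs are visited in random order and retained until the target
    fraction is reached; the last contig is kept only if that lands the
    realized fraction closer to the target. At least one contig is
    always retained (an empty assembly is not a record).
    """
    total = float(lengths.sum())
    order = rng.permutation(len(lengths))
    keep = np.zeros(len(lengths), dtype=bool)
    acc = 0.0
    for j in order:
        if acc >= target_c * total:
            break
        new = acc + float(lengths[j])
        # keep j if it moves the realized fraction closer to target
        if abs(new - target_c * total) <= abs(acc - target_c * total) or acc == 0.0:
            keep[j] = True
            acc = new
    if not keep.any():
        keep[order[0]] = True
    return keep


def hits_from_genomes(genomes: list[GenomeRecord]) -> list[HitRecord]:
    """Emit the homology hit table implied by ground-truth family labels.

    Stands in for an external profile-HMM search: every non-background
    gene receives an above-cutoff hit to its own family. Decoy pepM-like
    genes therefore hit pepM above cutoff but fail motif validation
    downstream, exercising the rejection path.
    """
    hits = []
    for gn in genomes:
        for g in gn.genes:
            if g.family == "other":
                continue
            hits.append(
                HitRecord(
                    query_id=g.gene_id, family=g.family, score=100.0, above_cutoff=True
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Metagenome reads


def gen_metagenome(
    community: dict[str, float],
    references: dict[str, str],
    n_reads: int,
    read_len: int,
    seed: int,
) -> tuple[list[tuple[str, str]], SynthTruth]:
    """Draw error-free peptide reads from reference proteins.

    Reads are uniform substrings of the family reference, with family
    sampling probability proportional to abundance x reference length
    (shotgun sampling is per-residue, not per-gene).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    missing = set(community) - set(references)
    if missing:
        raise ValueError(f"community families without references: {sorted(missing)}")
    truth = SynthTruth(seed=seed)
    if n_reads == 0:
        return [], truth

    fams = sorted(f for f, a in community.items() if a > 0)
    abund = np.array([community[f] for f in fams], dtype=float)
    abund = abund / abund.sum()
    lens = np.array([len(references[f]) for f in fams], dtype=float)
    if read_len > lens.min():
        raise ValueError("read_len exceeds the shortest reference")
    probs = abund * lens
    probs /= probs.sum()
    truth.community = dict(zip(fams, abund))

    rng = np.random.default_rng(seed)
    picks = rng.choice(len(fams), size=n_reads, p=probs)
    reads = []
    for i, k in enumerate(picks):
        fam = fams[k]
        ref = references[fam]
        start = int(rng.integers(0, len(ref) - read_len + 1))
        rid = f"read{i:06d}"
        reads.append((rid, ref[start : start + read_len]))
        truth.read_sources[rid] = fam
    return reads, truth


def make_family_references(
    families: list[str], length: int, seed: int
) -> dict[str, str]:
    """One random reference protein per family (pepM carries the motif)."""
    rng = np.random.default_rng(seed)
    refs = {}
    for fam in families:
        if fam == "pepM":
            refs[fam] = make_pepm_protein(rng, length)
        else:
            refs[fam] = _random_protein(rng, length)
    return refs


# ---------------------------------------------------------------------------
# 31P spectra


def gen_spectrum(
    peaks: list[tuple[float, float, float]],
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    n_points: int = 20_001,
    ppm_range: tuple[float, float] = (-30.0, 40.0),
    seed: int = 0,
    label: str = "",
) -> tuple[Spectrum, SynthTruth]:
    """Simulate a 1-D 31P spectrum as a sum of Lorentzians plus noise.

    Each peak is (center ppm, area, half-width gamma); the Lorentzian
    A * (gamma/pi) / ((x-c)^2 + gamma^2) integrates to A over the real
    line. Default half-width 0.3 ppm.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if any(w <= 0 for _, _, w in peaks):
        raise ValueError("peak widths must be positive")
    ppm = np.linspace(ppm_range[0], ppm_range[1], n_points)
    intensity = np.full(n_points, float(baseline))
    for center, area, gamma in peaks:
        intensity += area * (gamma / np.pi) / ((ppm - center) ** 2 + gamma**2)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=n_points)
    truth = SynthTruth(seed=seed, spectrum_peaks=list(peaks))
    return Spectrum(ppm=ppm, intensity=intensity, label=label), truth


# ---------------------------------------------------------------------------
# Sample metadata with beta-binomial trait counts


def gen_sample_metadata(
    n_samples: int,
    depth_range: tuple[float, float],
    basins: tuple[str, ...],
    beta0: float,
    beta_depth: float,
    beta_basin: float,
    phi: float,
    genomes_per_sample: int,
    seed: int,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Per-sample producer counts from a logit-linear beta-binomial model.

    logit(mu_i) = beta0 + beta_depth * depth_i + beta_basin * I(basin_i
    == basins[1]); counts y_i ~ BetaBinomial(m_i, mu_i, phi) with
    phi = rho/(1-rho) the overdispersion (phi -> 0 recovers the
    binomial). Defaults elsewhere follow the survey design scale:
    28 samples of m = 241 single-cell genomes.
    """
    for b in (beta0, beta_depth, beta_basin):
        if not np.isfinite(b):
            raise ValueError("coefficients must be finite")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    rng = np.random.default_rng(seed)
    depth = rng.uniform(depth_range[0], depth_range[1], size=n_samples)
    basin = rng.choice(list(basins), size=n_samples)
    is_alt = (basin == basins[1]).astype(float) if len(basins) > 1 else np.zeros(n_samples)
    eta = beta0 + beta_depth * depth + beta_basin * is_alt
    mu = 1.0 / (1.0 + np.exp(-eta))
    m = np.full(n_samples, genomes_per_sample)
    if phi == 0.0:
        y = rng.binomial(m, mu)
    else:
        a = mu / phi
        b = (1.0 - mu) / phi
        p = rng.beta(a, b)
        y = rng.binomial(m, p)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n_samples)],
            "depth_m": depth,
            "basin": basin,
            "n_genomes": m,
            "n_producers": y,
        }
    )
    truth = SynthTruth(
        seed=seed,
        sample_params={
            "beta0": beta0,
            "beta_depth": beta_depth,
            "beta_basin": beta_basin,
            "phi": phi,
        },
    )
    return df, truth


# ---------------------------------------------------------------------------
# Random trees and SPR perturbation (fixtures for tree-distance analyses)


def random_tree_newick(leaves: list[str], seed: int) -> str:
    """Uniform random binary topology by sequential random joining."""
    rng = np.random.default_rng(seed)
    nodes = [f"{lf}" for lf in leaves]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});" if len(nodes) == 2 else f"({nodes[0]});"


def spr_perturb(newick: str, n_moves: int, seed: int) -> str:
    """Apply ``n_moves`` random subtree-prune-regraft moves to a tree."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    rng = np.random.default_rng(seed)
    for _ in range(n_moves):
        tree = _one_spr(tree, rng)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _one_spr(tree, rng: np.random.Generator):
    import dendropy

    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    # Prune a random proper subtree (here: a random leaf clade of size
    # 1-3) and reattach on a random remaining edge.
    k = int(rng.integers(1, min(4, len(taxa) - 3)))
    moved = list(rng.choice(taxa, size=k, replace=False))
    rest = [t for t in taxa if t not in moved]
    sub = tree.extract_tree_with_taxa_labels(moved)
    host = tree.extract_tree_with_taxa_labels(rest)
    sub_nwk = sub.as_string(schema="newick", suppress_rooting=True).strip().rstrip(";")
    host_edges = [
        e
        for e in host.preorder_edge_iter()
        if e.head_node is not host.seed_node
    ]
    edge = host_edges[int(rng.integers(0, len(host_edges)))]
    head = edge.head_node
    parent = head.parent_node
    new = dendropy.Node()
    parent.remove_child(head)
    parent.add_child(new)
    new.add_child(head)
    graft = dendropy.Tree.get(data=sub_nwk + ";", schema="newick")
    new.add_child(graft.seed_node)
    combined = host.as_string(schema="newick", suppress_rooting=True)
    return dendropy.Tree.get(data=combined, schema="newick")
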