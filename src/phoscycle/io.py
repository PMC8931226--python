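"""Readers and writers for every on-disk format the pipeline touches.

FASTA goes through Biopython's SeqIO; Newick through dendropy; tabular
data through pandas. GFF3 is handled by a small boundary converter:
internally all coordinates are 0-based half-open, the files are written
1-based inclusive per the GFF3 standard.

Every writer round-trips: ``read(write(x)) == x`` for the fields the
format carries.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneFeature, GenomeRecord, Spectrum

# ---------------------------------------------------------------------------
# FASTA (protein sequences and peptide reads)


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (gene features) + companion protein FASTA


def write_gff3(genome: GenomeRecord, path: str | Path) -> None:
    """Write the gene table of one genome as GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for contig_id, length in genome.contigs:
        lines.append(f"##sequence-region {contig_id} 1 {length}")
    for g in genome.genes:
        attrs = f"ID={g.gene_id};family={g.family}"
        lines.append(
            "\t".join(
                [
                    g.contig_id,
                    "phoscycle",
                    "CDS",
                    str(g.start + 1),  # 0-based half-open -> 1-based inclusive
                    str(g.end),
                    ".",
                    g.strand,
                    "0",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(
    path: str | Path,
    genome_id: str,
    clade: str = "",
    completeness: float = 1.0,
    proteins: dict[str, str] | None = None,
) -> GenomeRecord:
    """Read a GFF3 gene table back into a GenomeRecord.

    ``proteins`` (gene_id -> residues), typically from the companion
    FASTA, re-attaches protein sequences the format itself cannot carry.
    """
    contigs: list[tuple[str, int]] = []
    genes: list[GeneFeature] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            _, contig_id, _, length = line.split()
            contigs.append((contig_id, int(length)))
            continue
        if not line or line.startswith("#"):
            continue
        contig_id, _, _, start, end, _, strand, _, attrs = line.split("\t")
        fields = dict(kv.split("=", 1) for kv in attrs.split(";"))
        gene_id = fields["ID"]
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                contig_id=contig_id,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                family=fields["family"],
                protein=(proteins or {}).get(gene_id, ""),
            )
        )
    return GenomeRecord(
        genome_id=genome_id,
        clade=clade,
        contigs=contigs,
        genes=genes,
        completeness=completeness,
    )


def write_genome_dir(genomes: list[GenomeRecord], outdir: str | Path) -> None:
    """One GFF3 + protein FASTA per genome, plus a metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for gn in genomes:
        write_gff3(gn, outdir / f"{gn.genome_id}.gff3")
        prots = {g.gene_id: g.protein for g in gn.genes if g.protein}
        if prots:
            write_fasta(prots, outdir / f"{gn.genome_id}.faa")
        meta.append(
            {
                "genome_id": gn.genome_id,
                "clade": gn.clade,
                "completeness": gn.completeness,
                "assembly_length": gn.assembly_length,
            }
        )
    pd.DataFrame(meta).to_csv(outdir / "genomes.tsv", sep="\t", index=False)


def read_genome_dir(indir: str | Path) -> list[GenomeRecord]:
    indir = Path(indir)
    meta = pd.read_csv(indir / "genomes.tsv", sep="\t")
    genomes = []
    for row in meta.itertuples():
        faa = indir / f"{row.genome_id}.faa"
        proteins = read_fasta(faa) if faa.exists() else {}
        genomes.append(
            read_gff3(
                indir / f"{row.genome_id}.gff3",
                genome_id=row.genome_id,
                clade=row.clade if isinstance(row.clade, str) else "",
                completeness=row.completeness,
                proteins=proteins,
            )
        )
    return genomes


# ---------------------------------------------------------------------------
# Hit tables / generic TSV


def write_hits(hits, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "family": h.family,
                "score": h.score,
                "above_cutoff": h.above_cutoff,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path):
    from .models import HitRecord

    df = pd.read_csv(path, sep="\t")
    return [
        HitRecord(
            query_id=str(r.query_id),
            family=str(r.family),
            score=float(r.score),
            above_cutoff=bool(r.above_cutoff),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Spectra (two-column TSV: ppm, intensity)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    header = f"# label={spectrum.label}\nppm\tintensity\n"
    body = "\n".join(
        f"{p:.10g}\t{i:.10g}" for p, i in zip(spectrum.ppm, spectrum.intensity)
    )
    Path(path).write_text(header + body + "\n")


def read_spectrum(path: str | Path) -> Spectrum:
    label = ""
    text = Path(path).read_text().splitlines()
    rows = []
    for line in text:
        if line.startswith("# label="):
            label = line.split("=", 1)[1]
            continue
        if not line or line.startswith(("#", "ppm")):
            continue
        p, i = line.split("\t")
        rows.append((float(p), float(i)))
    arr = np.array(rows, dtype=float)
    return Spectrum(ppm=arr[:, 0], intensity=arr[:, 1], label=label)


# ---------------------------------------------------------------------------
# JSON report helper


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
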