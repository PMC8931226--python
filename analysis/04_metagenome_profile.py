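#!/usr/bin/env python
"""Estimate the producer fraction of a community from metagenome reads.

Simulates 100,000 peptide reads from a 1,000-genome community in which
150 genomes carry pepM and every genome carries each of the ten
single-copy markers, classifies reads by best-hit-with-decoys, and
converts counts to a per-genome trait fraction via the marker-median
normalization. The estimate is depth-invariant by construction.
"""

import sys
from pathlib import Path

import numpy as np

from phoscycle import io, metaprofile, synthio
from phoscycle.models import MARKER_FAMILIES

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

SEED = 23
N_READS = 100_000


def main() -> None:
    fams = ["pepM"] + list(MARKER_FAMILIES)
    refs = synthio.make_family_references(fams, 300, seed=SEED)
    rng = np.random.default_rng(SEED + 1)
    decoys = {
        f"bg{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300))
        for i in range(5)
    }
    community = {f: 1_000.0 for f in MARKER_FAMILIES}
    community["pepM"] = 150.0
    for name in decoys:
        community[name] = 700.0
    all_refs = dict(refs)
    all_refs.update(decoys)

    reads, truth = synthio.gen_metagenome(community, all_refs, N_READS, 30, seed=SEED + 2)
    hits = metaprofile.classify_reads(reads, refs, decoy_refs=decoys)
    correct = sum(
        1 for h in hits
        if h.family == truth.read_sources[h.query_id]
        or (truth.read_sources[h.query_id] not in refs and h.family == "none")
    )
    prof = metaprofile.profile(hits, {f: float(len(s)) for f, s in refs.items()})
    ta = metaprofile.producer_fraction(prof)

    doubled = metaprofile.ReadProfile(
        counts={k: 2 * v for k, v in prof.counts.items()}, lengths=prof.lengths
    )
    ta2 = metaprofile.producer_fraction(doubled)

    RESULTS.mkdir(exist_ok=True)
    io.write_json(
        {
            "n_reads": N_READS,
            "true_producer_pct": 15.0,
            "estimated_producer_pct": ta.producer_fraction_pct,
            "classification_accuracy": correct / len(hits),
            "depth_doubling_invariant": ta2.producer_fraction_pct == ta.producer_fraction_pct,
            "marker_median": ta.marker_median,
        },
        RESULTS / "04_metagenome_profile.json",
    )
    print(f"classified {N_READS} reads (accuracy {correct / len(hits):.4f})")
    print(f"estimated producer fraction: {ta.producer_fraction_pct:.1f}% (truth 15%)")
    print(f"doubling depth leaves the estimate unchanged: "
          f"{ta2.producer_fraction_pct == ta.producer_fraction_pct}")


if __name__ == "__main__":
    sys.exit(main())
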