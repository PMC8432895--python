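"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results with plain dict/set/loop
code, independent of the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from synteny_decay.busco_io import GeneLocus, GenomeGeneMap


# ---------------------------------------------------------------------------
# map builders

def make_map(
    taxon: str,
    chrom_orders: dict[str, list[str]],
    *,
    spacing: int = 1000,
    missing: list[str] | None = None,
) -> GenomeGeneMap:
    """Build a GenomeGeneMap from explicit per-chromosome gene orders."""
    loci = []
    for seq_id, genes in chrom_orders.items():
        for i, g in enumerate(genes):
            start = i * spacing + 1
            loci.append(
                GeneLocus(
                    gene_id=g,
                    status="Complete",
                    seq_id=seq_id,
                    start=start,
                    end=start + spacing // 2,
                )
            )
    for g in missing or []:
        loci.append(GeneLocus(gene_id=g, status="Missing"))
    return GenomeGeneMap(
        taxon_id=taxon, loci=tuple(loci), chromosome_ids=frozenset(chrom_orders)
    )


def random_map(
    taxon: str,
    rng: np.random.Generator,
    n_genes: int = 60,
    n_chrom: int = 3,
) -> GenomeGeneMap:
    """Random single-copy genome: genes shuffled over chromosomes."""
    genes = [f"g{i:04d}" for i in range(n_genes)]
    rng.shuffle(genes)
    cuts = sorted(rng.choice(np.arange(1, n_genes), size=n_chrom - 1, replace=False))
    chroms = {}
    prev = 0
    for ci, cut in enumerate(list(cuts) + [n_genes]):
        chroms[f"chr{ci + 1}"] = genes[prev:cut]
        prev = cut
    return make_map(taxon, chroms)


# ---------------------------------------------------------------------------
# GOC oracle: filter-then-window by hand

def goc_oracle(map_a: GenomeGeneMap, map_b: GenomeGeneMap, mode: str = "strict"):
    """Brute-force per-gene GOC via explicit window enumeration.

    Returns (per_gene_scores, total, normalized).
    """
    shared = map_a.gene_ids & map_b.gene_ids

    def windows(gmap):
        out = {}
        for order in gmap.ordered_index.values():
            r = [g for g in order if g in shared]
            for i, g in enumerate(r):
                up = r[max(0, i - 2) : i]
                down = r[i + 1 : i + 3]
                out[g] = (set(up) | set(down), len(up) + len(down))
        return out

    wa, wb = windows(map_a), windows(map_b)
    scores = {}
    for g in sorted(shared):
        Wa, na = wa[g]
        Wb, nb = wb[g]
        if mode == "strict":
            if na == 4 and nb == 4:
                scores[g] = len(Wa & Wb) / 4
        else:
            den = max(na, nb)
            if den > 0:
                scores[g] = len(Wa & Wb) / den
    total = sum(scores.values())
    n = len(scores)
    return scores, total, (total / n if n else None)


# ---------------------------------------------------------------------------
# BUSCO table fixtures

V5_TOY = """\
# BUSCO version is: 5.2.2
# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength
100043at50557\tComplete\tchr2\t1200\t5600\t+\t900.1\t4400
g2\tComplete\tchr1\t100\t400\t-\t800.0\t300
g3\tComplete\tchr1\t900\t1300\t+\t700.0\t400
g4\tDuplicated\tchr1\t2000\t2400\t+\t600.0\t400
g4\tDuplicated\tchr2\t7000\t7400\t-\t600.0\t400
g5\tMissing
"""

V2_TOY = """\
# BUSCO version is: 2.0
# Busco id\tStatus\tContig\tStart\tEnd\tScore\tLength
100043at50557\tComplete\tchr2\t1200\t5600\t900.1\t4400
g2\tComplete\tchr1\t100\t400\t800.0\t300
g3\tComplete\tchr1\t900\t1300\t700.0\t400
g4\tDuplicated\tchr1\t2000\t2400\t600.0\t400
g4\tDuplicated\tchr2\t7000\t7400\t600.0\t400
g5\tMissing
"""


@pytest.fixture
def v5_toy_path(tmp_path):
    p = tmp_path / "full_table_toy.tsv"
    p.write_text(V5_TOY)
    return p


@pytest.fixture
def v2_toy_path(tmp_path):
    p = tmp_path / "full_table_toy_v2.tsv"
    p.write_text(V2_TOY)
    return p
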