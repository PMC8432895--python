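"""Chromosome-level synteny summaries between a reference genome and targets.

Where the GOC score measures *local* gene-order conservation, the summaries
here measure *inter-chromosomal* synteny: for each reference chromosome, on
which target chromosomes do its shared orthologs now live? The headline
statistic is chromosome **intactness** — the fraction of a reference
chromosome's shared genes found on its single best-matching target
chromosome — which stays high over long divergence times even when gene
order within the chromosome is thoroughly reshuffled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .busco_io import GenomeGeneMap
from .goc_score import NoComparableGenesError

__all__ = [
    "AssignmentTable",
    "chromosome_assignment",
    "intactness_summary",
    "ideogram_links",
    "write_assignments",
    "write_links",
]


@dataclass
class AssignmentTable:
    """Shared-gene tally of one reference chromosome across target
    chromosomes.

    ``intactness`` = majority count / total shared genes on the reference
    chromosome. Ties for the majority target are broken by the
    lexicographically smallest target seq_id and flagged.
    """

    reference_chromosome: str
    counts: dict[str, int]
    majority_target: str
    intactness: float
    tie: bool = False

    @property
    def n_genes(self) -> int:
        return sum(self.counts.values())


def _positions(gmap: GenomeGeneMap) -> pd.DataFrame:
    df = gmap.to_frame()
    return df[df["status"] != "Missing"][["gene_id", "seq_id", "start", "end"]]


def chromosome_assignment(
    ref: GenomeGeneMap,
    target: GenomeGeneMap,
    *,
    min_genes: int = 5,
) -> list[AssignmentTable]:
    """Per-reference-chromosome tallies of where shared genes land in the
    target genome.

    Both maps should be chromosome-restricted and status-filtered. Reference
    chromosomes with fewer than ``min_genes`` shared genes are dropped (an
    intactness percentage over a couple of genes is meaningless); if none
    remains, raises.
    """
    a, b = _positions(ref), _positions(target)
    merged = a.merge(b, on="gene_id", suffixes=("_ref", "_tgt"))
    if merged.empty:
        raise NoComparableGenesError(
            f"no shared genes between {ref.taxon_id} and {target.taxon_id}"
        )
    tables: list[AssignmentTable] = []
    for ref_chr, grp in merged.groupby("seq_id_ref", sort=True):
        counts = grp["seq_id_tgt"].value_counts().sort_index()
        n = int(counts.sum())
        if n < min_genes:
            continue
        best = int(counts.max())
        winners = counts[counts == best].index.tolist()
        tables.append(
            AssignmentTable(
                reference_chromosome=str(ref_chr),
                counts={str(k): int(v) for k, v in counts.items()},
                majority_target=sorted(winners)[0],
                intactness=best / n,
                tie=len(winners) > 1,
            )
        )
    if not tables:
        raise ValueError(
            f"no reference chromosome of {ref.taxon_id} has >= {min_genes} "
            f"shared genes with {target.taxon_id}"
        )
    return tables


def intactness_summary(tables: list[AssignmentTable]) -> dict:
    """Per-chromosome intactness vector plus its range, as percentages."""
    if not tables:
        raise ValueError("need at least one assignment table")
    vec = {t.reference_chromosome: 100.0 * t.intactness for t in tables}
    lo, hi = min(vec.values()), max(vec.values())
    return {
        "per_chromosome_percent": vec,
        "min_percent": lo,
        "max_percent": hi,
        "range": f"{lo:.0f}–{hi:.0f}%",
    }


def ideogram_links(ref: GenomeGeneMap, target: GenomeGeneMap) -> pd.DataFrame:
    """One link row per shared gene with coordinates in both genomes,
    suitable for external ideogram/ribbon plotting."""
    a, b = _positions(ref), _positions(target)
    merged = a.merge(b, on="gene_id", suffixes=("_ref", "_tgt"))
    if merged.empty:
        warnings.warn(
            f"no shared genes between {ref.taxon_id} and {target.taxon_id}; "
            "empty link table",
            stacklevel=2,
        )
    out = merged.rename(
        columns={
            "seq_id_ref": "ref_chr",
            "start_ref": "ref_start",
            "end_ref": "ref_end",
            "seq_id_tgt": "target_chr",
            "start_tgt": "target_start",
            "end_tgt": "target_end",
        }
    )
    cols = [
        "ref_chr", "ref_start", "ref_end",
        "target_chr", "target_start", "target_end", "gene_id",
    ]
    return out[cols].sort_values(["ref_chr", "ref_start"], kind="stable").reset_index(drop=True)


def write_assignments(tables: list[AssignmentTable], path: str | Path) -> None:
    """Assignment TSV: ref_chr, target_chr, count, fraction."""
    rows = []
    for t in tables:
        for tgt, c in sorted(t.counts.items()):
            rows.append((t.reference_chromosome, tgt, c, c / t.n_genes))
    pd.DataFrame(
        rows, columns=["ref_chr", "target_chr", "count", "fraction"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_links(links: pd.DataFrame, path: str | Path) -> None:
    links.to_csv(path, sep="\t", index=False)
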