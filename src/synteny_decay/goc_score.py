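"""Gene Order Conservation (GOC) scoring between genome pairs.

The GOC score quantifies local gene-order (micro-synteny) conservation from
shared single-copy ortholog positions. For each shared gene a neighborhood of
up to two genes upstream and two downstream is taken in each genome, built on
the per-chromosome gene orders *after* restricting to the shared gene set.
The gene scores 1, 0.75, 0.5, 0.25 or 0 according to whether 4, 3, 2, 1 or 0
of its window genes in one genome also lie in its window in the other. The
pairwise GOC score is the sum of per-gene scores (``total``), optionally
divided by the number of scored genes (``normalized``, in [0, 1]).

Two completeness modes are offered. In ``strict`` mode (default) a gene is
scored only if it has two shared neighbors on each flank in *both* genomes,
so every score is an exact quarter and a genome against itself normalizes to
exactly 1. In ``relaxed`` mode truncated windows near chromosome ends are
scored with denominator ``max(|W_a|, |W_b|)``.

Matching rule: a window gene counts as conserved if it lies anywhere within
the focal gene's window in the other genome (symmetric set intersection,
tolerant of local inversions). A stricter ``same_side`` rule that requires
the neighbor to stay on the same flank is available as an option.
Strand/orientation is ignored; windows never span sequence boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .busco_io import GenomeGeneMap

__all__ = [
    "GocOptions",
    "NeighborhoodWindow",
    "GocResult",
    "GocMatrix",
    "NoComparableGenesError",
    "shared_single_copy",
    "neighborhood",
    "goc_pair",
    "goc_matrix",
]


class NoComparableGenesError(ValueError):
    """Two genomes share no single-copy genes — no comparison possible."""


@dataclass(frozen=True)
class GocOptions:
    """Scoring options.

    mode
        ``"strict"`` (only doubly-complete windows scored; quarter scores) or
        ``"relaxed"`` (truncated windows allowed, denominator
        ``max(|W_a|,|W_b|)``).
    k
        Neighbors per side (2 gives the classic four-gene window).
    match_rule
        ``"window"`` (set intersection; default) or ``"same_side"``
        (upstream genes must stay upstream, downstream downstream).
    """

    mode: str = "strict"
    k: int = 2
    match_rule: str = "window"

    def __post_init__(self) -> None:
        if self.mode not in {"strict", "relaxed"}:
            raise ValueError("mode must be 'strict' or 'relaxed'")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.match_rule not in {"window", "same_side"}:
            raise ValueError("match_rule must be 'window' or 'same_side'")


@dataclass(frozen=True)
class NeighborhoodWindow:
    """Up to ``2k`` shared genes flanking a focal gene on its sequence."""

    focal_gene: str
    upstream: tuple[str, ...]
    downstream: tuple[str, ...]

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.upstream) | frozenset(self.downstream)

    @property
    def complete(self) -> bool:
        return len(self.upstream) == len(self.downstream) == 2


@dataclass
class GocResult:
    """Pairwise GOC outcome.

    ``normalized`` is ``None`` (undefined, flagged) when no gene could be
    scored; ``total`` is then 0.
    """

    taxon_a: str
    taxon_b: str
    n_shared: int
    n_scored: int
    per_gene_scores: dict[str, float]
    total: float
    normalized: float | None
    options: GocOptions

    @property
    def category_tally(self) -> dict[float, int]:
        tally: dict[float, int] = {}
        for s in self.per_gene_scores.values():
            tally[s] = tally.get(s, 0) + 1
        return tally


def shared_single_copy(map_a: GenomeGeneMap, map_b: GenomeGeneMap) -> frozenset[str]:
    """Gene ids present (non-Missing) in both maps.

    The maps are expected to be already filtered to single-copy,
    chromosome-localized loci; genes missing from either genome are discarded
    from the comparison.
    """
    shared = map_a.gene_ids & map_b.gene_ids
    if not shared:
        raise NoComparableGenesError(
            f"no comparable genes between {map_a.taxon_id} and {map_b.taxon_id}"
        )
    return frozenset(shared)


def _restricted_orders(
    gmap: GenomeGeneMap, shared: frozenset[str]
) -> list[list[str]]:
    """Per-sequence gene orders with non-shared genes removed."""
    return [
        [g for g in order if g in shared]
        for order in gmap.ordered_index.values()
    ]


def neighborhood(
    gmap: GenomeGeneMap,
    gene: str,
    shared: Iterable[str],
    k: int = 2,
) -> NeighborhoodWindow:
    """The up-to-``k``-per-side window around ``gene`` in the shared-gene-
    restricted order of its sequence."""
    shared = frozenset(shared)
    if gene not in shared:
        raise KeyError(f"{gene!r} is not in the shared gene set")
    for order in _restricted_orders(gmap, shared):
        if gene in order:
            i = order.index(gene)
            return NeighborhoodWindow(
                focal_gene=gene,
                upstream=tuple(order[max(0, i - k) : i]),
                downstream=tuple(order[i + 1 : i + 1 + k]),
            )
    raise KeyError(f"{gene!r} not present in {gmap.taxon_id}")


# ---------------------------------------------------------------------------
# vectorized pair scoring

def _window_arrays(
    orders: list[np.ndarray], n_genes: int, k: int, fill: int
) -> tuple[np.ndarray, np.ndarray]:
    """(windows, sizes): for each gene code, the 2k window gene codes
    (``fill`` where the flank is truncated) and the window size."""
    win = np.full((n_genes, 2 * k), fill, dtype=np.int64)
    size = np.zeros(n_genes, dtype=np.int64)
    for order in orders:
        m = len(order)
        if m == 0:
            continue
        for off in range(1, k + 1):
            up = order[:-off]
            win[order[off:], off - 1] = up
            down = order[off:]
            win[order[:-off], k + off - 1] = down
        pos = np.arange(m)
        size[order] = np.minimum(pos, k) + np.minimum(m - 1 - pos, k)
    return win, size


def _prep_codes(
    gmap: GenomeGeneMap, genes: np.ndarray
) -> list[np.ndarray]:
    """Per-sequence orders of shared genes as integer codes into ``genes``
    (a sorted array of gene ids)."""
    orders = []
    for order in gmap.ordered_index.values():
        arr = np.asarray(order, dtype=object)
        codes = np.searchsorted(genes, arr)
        codes = np.clip(codes, 0, len(genes) - 1)
        mask = genes[codes] == arr
        if mask.any():
            orders.append(codes[mask].astype(np.int64))
    return orders


def goc_pair(
    map_a: GenomeGeneMap,
    map_b: GenomeGeneMap,
    opts: GocOptions | None = None,
) -> GocResult:
    """Pairwise GOC between two prepared genome maps.

    Both maps should already be single-copy-filtered and chromosome-
    restricted. Symmetric in its arguments by construction.
    """
    opts = opts or GocOptions()
    shared = shared_single_copy(map_a, map_b)
    genes = np.asarray(sorted(shared), dtype=object)
    n = len(genes)
    k = opts.k

    orders_a = _prep_codes(map_a, genes)
    orders_b = _prep_codes(map_b, genes)
    wa, sa = _window_arrays(orders_a, n, k, fill=-2)
    wb, sb = _window_arrays(orders_b, n, k, fill=-3)

    if opts.match_rule == "window":
        matches = (wa[:, :, None] == wb[:, None, :]).sum(axis=(1, 2))
    else:  # same_side: upstream vs upstream, downstream vs downstream
        matches = (wa[:, :k, None] == wb[:, None, :k]).sum(axis=(1, 2)) + (
            wa[:, k:, None] == wb[:, None, k:]
        ).sum(axis=(1, 2))

    if opts.mode == "strict":
        scored_mask = (sa == 2 * k) & (sb == 2 * k)
        denom = np.full(n, 2 * k, dtype=float)
    else:
        denom = np.maximum(sa, sb).astype(float)
        scored_mask = denom > 0

    scores = np.zeros(n, dtype=float)
    scores[scored_mask] = matches[scored_mask] / denom[scored_mask]

    n_scored = int(scored_mask.sum())
    total = float(scores[scored_mask].sum())
    per_gene = {
        str(genes[i]): float(scores[i]) for i in np.flatnonzero(scored_mask)
    }
    return GocResult(
        taxon_a=map_a.taxon_id,
        taxon_b=map_b.taxon_id,
        n_shared=n,
        n_scored=n_scored,
        per_gene_scores=per_gene,
        total=total,
        normalized=(total / n_scored) if n_scored else None,
        options=opts,
    )


# ---------------------------------------------------------------------------
# all-pairs matrix

@dataclass
class GocMatrix:
    """Symmetric all-pairs GOC over a taxon set.

    Holds both scales: ``total`` (summed per-gene scores, the scale used for
    the published pairwise matrices) and ``normalized`` (mean per-gene score
    in [0, 1]). The diagonal carries each genome's self-comparison — the
    maximum attainable value on each scale.
    """

    taxa: tuple[str, ...]
    total: pd.DataFrame
    normalized: pd.DataFrame
    pairs: pd.DataFrame  # long format: taxon_a, taxon_b, n_shared, n_scored, total, normalized
    options: GocOptions = field(default_factory=GocOptions)

    def values(self, scale: str = "normalized") -> pd.DataFrame:
        if scale not in {"total", "normalized"}:
            raise ValueError("scale must be 'total' or 'normalized'")
        return getattr(self, scale)

    def write(self, path: str | Path, scale: str = "normalized") -> None:
        """Square labeled TSV (taxon header row and column)."""
        self.values(scale).to_csv(path, sep="\t", float_format="%.10g")

    def write_pairs(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(
        cls, path: str | Path, scale: str = "normalized", sep: str | None = None
    ) -> "GocMatrix":
        """Load a square labeled matrix TSV/CSV as a one-scale GocMatrix."""
        df = _read_square_matrix(path, sep=sep)
        empty = df.copy()
        empty.values[:] = np.nan
        kw = {"total": df if scale == "total" else empty,
              "normalized": df if scale == "normalized" else empty}
        return cls(taxa=tuple(df.index), pairs=pd.DataFrame(), **kw)


def _read_square_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix row and column labels differ")
    return df


def goc_matrix(
    maps: Sequence[GenomeGeneMap] | Mapping[str, GenomeGeneMap],
    opts: GocOptions | None = None,
) -> GocMatrix:
    """All unordered pairwise GOC comparisons, mirrored into a symmetric
    matrix; taxa keep their input order."""
    opts = opts or GocOptions()
    if isinstance(maps, Mapping):
        maps = list(maps.values())
    if len(maps) < 2:
        raise ValueError("need at least two genome maps")
    taxa = [m.taxon_id for m in maps]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon_id among input maps")

    n = len(taxa)
    tot = np.zeros((n, n))
    norm = np.zeros((n, n))
    rows = []
    for i in range(n):
        self_res = goc_pair(maps[i], maps[i], opts)
        tot[i, i] = self_res.total
        norm[i, i] = self_res.normalized if self_res.normalized is not None else np.nan
        for j in range(i + 1, n):
            r = goc_pair(maps[i], maps[j], opts)
            tot[i, j] = tot[j, i] = r.total
            norm[i, j] = norm[j, i] = r.normalized if r.normalized is not None else np.nan
            rows.append(
                (r.taxon_a, r.taxon_b, r.n_shared, r.n_scored, r.total, r.normalized)
            )
    pairs = pd.DataFrame(
        rows,
        columns=["taxon_a", "taxon_b", "n_shared", "n_scored", "total", "normalized"],
    )
    return GocMatrix(
        taxa=tuple(taxa),
        total=pd.DataFrame(tot, index=taxa, columns=taxa),
        normalized=pd.DataFrame(norm, index=taxa, columns=taxa),
        pairs=pairs,
        options=opts,
    )
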