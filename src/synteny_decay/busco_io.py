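"""Reading and normalising BUSCO "full table" outputs.

BUSCO writes one tab-separated ``full_table*.tsv`` per genome listing every
ortholog in the lineage set with a status (Complete / Duplicated / Fragmented /
Missing) and, for located loci, the sequence and coordinates of the best hit.
The column layout changed between major versions:

* v2/v3: ``# Busco id  Status  Contig  Start  End  Score  Length``
* v4/v5: ``# Busco id  Status  Sequence  Gene Start  Gene End  Strand  Score
  Length [OrthoDB url  Description]``

Both dialects are read into the same :class:`GenomeGeneMap`, an ordered
gene-position model that the synteny statistics downstream operate on.
Coordinates are kept 1-based inclusive (the BUSCO convention); only the order
of genes along a sequence matters downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneLocus",
    "GenomeGeneMap",
    "BuscoParseError",
    "parse_busco_full_table",
    "filter_status",
    "restrict_to_chromosomes",
    "ordered_gene_list",
    "write_full_table",
    "write_gene_positions",
    "read_sequence_lengths",
    "read_chromosome_list",
]

STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")
#: Statuses retained by the "single-copy" preset (Duplicated always excluded).
SINGLE_COPY_STATUSES = frozenset({"Complete"})
#: Statuses used for chromosome-level synteny summaries, where fragmented
#: loci with coordinates still carry positional signal.
SINGLE_AND_FRAGMENTED_STATUSES = frozenset({"Complete", "Fragmented"})


class BuscoParseError(ValueError):
    """Raised for malformed BUSCO full-table rows."""


@dataclass(frozen=True)
class GeneLocus:
    """One BUSCO ortholog placement in one genome.

    ``start``/``end`` are 1-based inclusive base-pair positions. Missing loci
    carry no coordinates (``seq_id`` empty, ``start``/``end`` zero).
    """

    gene_id: str
    status: str
    seq_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown BUSCO status {self.status!r}")
        if self.status != "Missing" and self.seq_id and self.start > self.end:
            raise ValueError(
                f"locus {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class GenomeGeneMap:
    """One taxon's BUSCO loci, ordered along named sequences.

    Parameters
    ----------
    taxon_id
        Name of the genome/taxon the table came from.
    loci
        All parsed loci (any status).
    chromosome_ids
        seq_ids designated as chromosomes; empty until
        :func:`restrict_to_chromosomes` is applied (or set explicitly).
    """

    taxon_id: str
    loci: tuple[GeneLocus, ...]
    chromosome_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        self.chromosome_ids = frozenset(self.chromosome_ids)
        self._index: dict[str, tuple[str, ...]] | None = None

    # -- basic views ------------------------------------------------------

    @property
    def seq_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for loc in self.loci:
            if loc.seq_id:
                seen.setdefault(loc.seq_id, None)
        return tuple(seen)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(loc.gene_id for loc in self.loci if loc.status != "Missing")

    def to_frame(self) -> pd.DataFrame:
        """Loci as a DataFrame (gene_id, status, seq_id, start, end, strand)."""
        return pd.DataFrame(
            [
                (l.gene_id, l.status, l.seq_id, l.start, l.end, l.strand)
                for l in self.loci
            ],
            columns=["gene_id", "status", "seq_id", "start", "end", "strand"],
        )

    @property
    def ordered_index(self) -> Mapping[str, tuple[str, ...]]:
        """Per-sequence gene_ids sorted by (start, end, gene_id)."""
        if self._index is None:
            by_seq: dict[str, list[GeneLocus]] = {}
            for loc in self.loci:
                if loc.seq_id and loc.status != "Missing":
                    by_seq.setdefault(loc.seq_id, []).append(loc)
            self._index = {
                sid: tuple(
                    l.gene_id
                    for l in sorted(locs, key=lambda l: (l.start, l.end, l.gene_id))
                )
                for sid, locs in by_seq.items()
            }
        return self._index

    # -- convenience methods mirroring the module-level operations --------

    def filter_status(self, statuses: Iterable[str] | str) -> "GenomeGeneMap":
        return filter_status(self, statuses)

    def restrict_to_chromosomes(self, **kwargs) -> "GenomeGeneMap":
        return restrict_to_chromosomes(self, **kwargs)

    def ordered_gene_list(self, seq_id: str) -> tuple[str, ...]:
        return ordered_gene_list(self, seq_id)


# ---------------------------------------------------------------------------
# parsing

_V4V5_HEADER = re.compile(r"#\s*Busco id\s+Status\s+Sequence", re.I)
_V2V3_HEADER = re.compile(r"#\s*Busco id\s+Status\s+Contig", re.I)


def _sniff_dialect(lines: Sequence[str]) -> str:
    for line in lines:
        if not line.startswith("#"):
            break
        if _V4V5_HEADER.search(line):
            return "v5"
        if _V2V3_HEADER.search(line):
            return "v2"
    # No informative header: decide from the first data row. v4/v5 rows carry
    # a strand column at index 5; v2/v3 have a numeric score there.
    for line in lines:
        if line.startswith("#") or not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 6 and parts[5].strip() in {"+", "-"}:
            return "v5"
        return "v2"
    return "v5"


def _clean_seq_id(raw: str) -> str:
    # some BUSCO builds emit "seq:start-end"; keep the sequence name
    return raw.split(":", 1)[0]


def parse_busco_full_table(
    path: str | Path, *, dialect: str = "auto", taxon_id: str | None = None
) -> GenomeGeneMap:
    """Parse a BUSCO full table (v2–v5) into a :class:`GenomeGeneMap`.

    Parameters
    ----------
    path
        Tab-separated BUSCO full table; comment lines start with ``#``.
    dialect
        ``"auto"`` (header sniffing), ``"v2"``/``"v3"`` or ``"v4"``/``"v5"``.
    taxon_id
        Defaults to the file's stem.

    Missing rows are retained with status only. Fragmented/Complete rows that
    lack coordinates (some BUSCO versions omit them) are dropped to Missing.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "auto":
        dialect = _sniff_dialect(lines)
    dialect = {"v2": "v2", "v3": "v2", "v4": "v5", "v5": "v5"}.get(dialect)
    if dialect is None:
        raise ValueError("dialect must be one of auto, v2, v3, v4, v5")

    loci: list[GeneLocus] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        gene_id, status = parts[0].strip(), parts[1].strip() if len(parts) > 1 else ""
        if status not in STATUSES:
            raise BuscoParseError(
                f"{path.name}:{lineno}: unknown status {status!r}"
            )
        if status == "Missing":
            loci.append(GeneLocus(gene_id=gene_id, status="Missing"))
            continue
        if len(parts) < 5 or not parts[2].strip():
            if len(parts) <= 2:
                # located status without coordinates: unusable downstream
                loci.append(GeneLocus(gene_id=gene_id, status="Missing"))
                continue
            raise BuscoParseError(
                f"{path.name}:{lineno}: expected >=5 columns, got {len(parts)}"
            )
        try:
            start, end = int(float(parts[3])), int(float(parts[4]))
        except ValueError as exc:
            raise BuscoParseError(
                f"{path.name}:{lineno}: non-numeric coordinates "
                f"{parts[3]!r}/{parts[4]!r}"
            ) from exc
        strand = "unknown"
        if dialect == "v5" and len(parts) > 5 and parts[5].strip() in {"+", "-"}:
            strand = parts[5].strip()
        if start > end:  # tolerate reverse-strand coordinate order
            start, end = end, start
        loci.append(
            GeneLocus(
                gene_id=gene_id,
                status=status,
                seq_id=_clean_seq_id(parts[2].strip()),
                start=start,
                end=end,
                strand=strand,
            )
        )
    return GenomeGeneMap(taxon_id=taxon_id or path.stem, loci=tuple(loci))


# ---------------------------------------------------------------------------
# filtering

def filter_status(
    gmap: GenomeGeneMap, statuses: Iterable[str] | str
) -> GenomeGeneMap:
    """Restrict loci to the requested statuses.

    ``statuses`` may be a set of status names or the preset string
    ``"single-copy"`` (Complete only — Duplicated always excluded) or
    ``"single-and-fragmented"`` (Complete + Fragmented, the chromosome-level
    summary preset).
    """
    if isinstance(statuses, str):
        preset = statuses.replace("_", "-").lower()
        if preset == "single-copy":
            wanted = SINGLE_COPY_STATUSES
        elif preset == "single-and-fragmented":
            wanted = SINGLE_AND_FRAGMENTED_STATUSES
        else:
            raise ValueError(f"unknown status preset {statuses!r}")
    else:
        wanted = frozenset(statuses)
        unknown = wanted - set(STATUSES)
        if unknown:
            raise ValueError(f"unknown statuses {sorted(unknown)}")
    kept = tuple(l for l in gmap.loci if l.status in wanted)
    return GenomeGeneMap(gmap.taxon_id, kept, gmap.chromosome_ids)


def restrict_to_chromosomes(
    gmap: GenomeGeneMap,
    *,
    seq_ids: Iterable[str] | None = None,
    pattern: str | None = None,
    min_length: int | None = None,
    seq_lengths: Mapping[str, int] | None = None,
) -> GenomeGeneMap:
    """Keep only loci on sequences designated as chromosomes.

    Exactly one selector must be given: an explicit ``seq_ids`` list, a name
    ``pattern`` (regex, matched with :func:`re.search`), or a ``min_length``
    threshold in bp together with per-sequence ``seq_lengths``. A selector
    that matches no sequence raises (guards silently empty analyses).
    """
    given = [seq_ids is not None, pattern is not None, min_length is not None]
    if sum(given) != 1:
        raise ValueError("give exactly one of seq_ids, pattern, min_length")
    present = set(gmap.seq_ids)
    if seq_ids is not None:
        chosen = present & set(seq_ids)
    elif pattern is not None:
        rx = re.compile(pattern)
        chosen = {s for s in present if rx.search(s)}
    else:
        if seq_lengths is None:
            raise ValueError("min_length selector requires seq_lengths")
        chosen = {s for s in present if seq_lengths.get(s, 0) >= min_length}
    if not chosen:
        raise ValueError(
            f"{gmap.taxon_id}: chromosome selector matched no sequences"
        )
    kept = tuple(
        l for l in gmap.loci if l.status == "Missing" or l.seq_id in chosen
    )
    return GenomeGeneMap(gmap.taxon_id, kept, frozenset(chosen))


def ordered_gene_list(gmap: GenomeGeneMap, seq_id: str) -> tuple[str, ...]:
    """gene_ids on ``seq_id`` sorted by (start, end, gene_id); ties are
    broken deterministically by the lexicographic gene_id."""
    index = gmap.ordered_index
    if seq_id not in index:
        raise KeyError(f"{gmap.taxon_id}: unknown seq_id {seq_id!r}")
    return index[seq_id]


# ---------------------------------------------------------------------------
# writers / auxiliary readers

def write_full_table(gmap: GenomeGeneMap, path: str | Path, *, dialect: str = "v5") -> None:
    """Write the map back out as a BUSCO full table in the given dialect."""
    dialect = {"v2": "v2", "v3": "v2", "v4": "v5", "v5": "v5"}.get(dialect)
    if dialect is None:
        raise ValueError("dialect must be v2, v3, v4 or v5")
    lines = []
    if dialect == "v5":
        lines.append("# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength")
    else:
        lines.append("# Busco id\tStatus\tContig\tStart\tEnd\tScore\tLength")
    for l in sorted(gmap.loci, key=lambda l: l.gene_id):
        if l.status == "Missing":
            lines.append(f"{l.gene_id}\tMissing")
        elif dialect == "v5":
            strand = l.strand if l.strand in {"+", "-"} else "+"
            lines.append(
                f"{l.gene_id}\t{l.status}\t{l.seq_id}\t{l.start}\t{l.end}\t{strand}\t0.0\t{l.end - l.start + 1}"
            )
        else:
            lines.append(
                f"{l.gene_id}\t{l.status}\t{l.seq_id}\t{l.start}\t{l.end}\t0.0\t{l.end - l.start + 1}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_positions(gmap: GenomeGeneMap, path: str | Path) -> None:
    """Normalized gene-position TSV: taxon_id, gene_id, seq_id, start, end,
    strand, status."""
    df = gmap.to_frame()
    df.insert(0, "taxon_id", gmap.taxon_id)
    df.to_csv(path, sep="\t", index=False)


def read_sequence_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (seq_id, length in bp) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1])
    return dict(zip(df[0].astype(str), df[1].astype(int)))


def read_chromosome_list(path: str | Path) -> list[str]:
    """Plain text chromosome list, one seq_id per line."""
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
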