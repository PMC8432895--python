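"""Windowed genome profiles: soft-masked (repeat) fraction and gene density.

Repeat maskers encode repetitive bases as lowercase ("soft masking"). The
profile tiles each sequence into fixed-size non-overlapping windows (default
1 Mb; the last window of a sequence may be short) and reports per window the
fraction of lowercase bases and the number of genes whose start position
falls in the window.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .busco_io import GenomeGeneMap

__all__ = [
    "window_masked_fraction",
    "window_gene_density",
    "write_profile",
]

_COLS = ["seq_id", "window_start", "window_end", "masked_fraction", "gene_count"]


def _iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) preserving case. Plain streaming reader —
    case-sensitive access to whole sequences is all that is needed here."""
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def _window_bounds(length: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, window)
    ends = np.minimum(starts + window, length)
    return starts, ends


def window_masked_fraction(
    fasta: str | Path, window: int = 1_000_000
) -> pd.DataFrame:
    """Per-window fraction of soft-masked (lowercase) bases.

    Returns a frame with columns seq_id, window_start (1-based), window_end
    (inclusive), masked_fraction, gene_count (0 — filled by the caller if a
    gene map is profiled too). N bases count by their case as written.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for name, seq in _iter_fasta(fasta):
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        lower = ((codes >= 97) & (codes <= 122)).astype(np.int64)
        starts, ends = _window_bounds(len(codes), window)
        masked = np.add.reduceat(lower, starts) if len(codes) else np.array([])
        for s, e, m in zip(starts, ends, masked):
            rows.append((name, int(s) + 1, int(e), m / (e - s), 0))
    return pd.DataFrame(rows, columns=_COLS)


def window_gene_density(
    gmap: GenomeGeneMap, window: int = 1_000_000
) -> pd.DataFrame:
    """Per-window gene counts; a gene belongs to the window containing its
    start position (genes straddling a boundary are counted once)."""
    if window <= 0:
        raise ValueError("window must be positive")
    df = gmap.to_frame()
    df = df[(df["status"] != "Missing") & (df["seq_id"] != "")]
    rows = []
    for seq_id, grp in df.groupby("seq_id", sort=True):
        bins = (grp["start"] - 1) // window
        counts = bins.value_counts()
        # tile out to the furthest occupied window; true sequence length is
        # unknown from coordinates alone
        n_win = int(bins.max()) + 1 if len(bins) else 0
        for w in range(n_win):
            rows.append(
                (
                    seq_id,
                    w * window + 1,
                    (w + 1) * window,
                    float("nan"),
                    int(counts.get(w, 0)),
                )
            )
    return pd.DataFrame(rows, columns=_COLS)


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """BED-like TSV: seq_id, 0-based half-open start, end, masked_fraction,
    gene_count."""
    out = profile.copy()
    out["window_start"] = out["window_start"] - 1
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.10g")
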