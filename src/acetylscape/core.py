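"""Genomic interval primitives, peak-set I/O, and overlap/nearest-TSS machinery.

All coordinates are stored 0-based half-open ([start, end)). File dialects
that use 1-based closed coordinates are converted at the I/O boundary and
written back in their native convention, so a read/write round trip is
bit-exact. Chromosome names are compared as exact strings; no "chr" prefix
normalization is performed.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "TssDistance",
    "PeakFileError",
    "read_peaks",
    "write_peaks",
    "read_genes",
    "write_genes",
    "overlap_pairs",
    "shared_peaks",
    "union_length",
    "coverage_per_mb",
    "distance_bin",
    "nearest_tss",
    "nearest_tss_table",
]

#: Distance-to-TSS bin edges in bp; closed on the left bin (<=5 kb is "0-5 kb").
TSS_BIN_EDGES = (5_000, 50_000)
TSS_BIN_LABELS = ("0-5 kb", "5-50 kb", ">50 kb")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located genomic region, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Peak:
    """A signal-bearing region: the atom of every ChIP-seq analysis here.

    ``signal`` is a normalized tag count over the region (reads-per-million
    scale); ``sample`` is a free-form donor/timepoint label.
    """

    interval: GenomicInterval
    id: str
    signal: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak {self.id}: signal must be >= 0")


class PeakSet:
    """A sorted collection of peaks for one histone mark.

    Peaks are sorted by (chrom, start, end); ids must be unique within the
    set. ``genome_size`` is the total assayable genome length in bp and is
    required for coverage summaries.
    """

    def __init__(
        self,
        peaks: Iterable[Peak],
        mark: str = "H3K27Ac",
        genome_size: int | None = None,
    ):
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate peak ids: {list(dup[dup > 1].index[:5])}")
        self.mark = mark
        if genome_size is not None and genome_size <= 0:
            raise ValueError("genome_size must be > 0")
        self.genome_size = genome_size

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def by_id(self, peak_id: str) -> Peak:
        return self._id_index()[peak_id]

    @functools.lru_cache(maxsize=1)
    def _id_index(self) -> dict:
        return {p.id: p for p in self.peaks}

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.interval.chrom, []).append(p)
        return out

    def subset(self, ids: Iterable[str]) -> "PeakSet":
        wanted = set(ids)
        return PeakSet(
            [p for p in self.peaks if p.id in wanted],
            mark=self.mark,
            genome_size=self.genome_size,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in self.peaks],
                "start": [p.interval.start for p in self.peaks],
                "end": [p.interval.end for p in self.peaks],
                "peak_id": self.ids,
                "signal": [p.signal for p in self.peaks],
                "sample": [p.sample for p in self.peaks],
            }
        )

    # hashing/caching helper: PeakSet is treated as immutable after creation
    def __hash__(self) -> int:  # pragma: no cover - identity hash
        return id(self)


@dataclass
class GeneModel:
    """Gene with strand and TSS anchoring the distance/exclusion logic.

    ``baseline_expression`` is on the RPKM scale and is used for the
    expressed-gene (RPKM > 1) filters.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval
    baseline_expression: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (self.body.start <= self.tss <= self.body.end):
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} outside body "
                f"[{self.body.start}, {self.body.end}]"
            )
        if self.baseline_expression < 0:
            raise ValueError("baseline_expression must be >= 0")


@dataclass
class TssDistance:
    """Signed, strand-aware distance from a peak midpoint to its nearest TSS.

    Negative distances are upstream of the TSS relative to the gene's strand.
    ``assigned`` is False when the peak's chromosome carries no gene; such
    records keep gene_id/bin as None rather than raising.
    """

    peak_id: str
    gene_id: str | None
    signed_distance: float | None
    bin: str | None
    assigned: bool = True


class PeakFileError(ValueError):
    """Raised for unparseable peak/gene files; carries per-line messages."""

    def __init__(self, path, line_errors: Sequence[tuple[int, str]]):
        self.path = str(path)
        self.line_errors = list(line_errors)
        detail = "; ".join(f"line {n}: {msg}" for n, msg in self.line_errors[:10])
        super().__init__(f"{self.path}: {detail}")


# ---------------------------------------------------------------------------
# I/O


def _convert_in(start: int, end: int, coords: str) -> tuple[int, int]:
    if coords == "0-based":
        return start, end
    if coords == "1-based":  # 1-based closed -> 0-based half-open
        return start - 1, end
    raise ValueError(f"unknown coordinate convention {coords!r}")


def _convert_out(start: int, end: int, coords: str) -> tuple[int, int]:
    if coords == "0-based":
        return start, end
    if coords == "1-based":
        return start + 1, end
    raise ValueError(f"unknown coordinate convention {coords!r}")


def read_peaks(
    path,
    dialect: str = "bed",
    coords: str = "0-based",
    mark: str = "H3K27Ac",
    genome_size: int | None = None,
) -> PeakSet:
    """Read a peak file into a sorted :class:`PeakSet`.

    Parameters
    ----------
    dialect:
        ``"bed"`` for headerless BED3+name+score (chrom, start, end, name,
        signal) or ``"tsv"`` for a header-carrying table with columns
        chrom/start/end/peak_id/signal (optional sample).
    coords:
        ``"0-based"`` (half-open, BED native) or ``"1-based"`` (closed);
        converted to the internal 0-based half-open convention.

    Malformed lines (wrong column count, non-numeric coordinates,
    start >= end after conversion) are collected and reported with their
    line numbers in a single :class:`PeakFileError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    peaks: list[Peak] = []
    errors: list[tuple[int, str]] = []
    lines = path.read_text().splitlines()
    start_line = 0
    header: list[str] | None = None
    if dialect == "tsv":
        if not lines:
            raise PeakFileError(path, [(0, "empty TSV, header expected")])
        header = lines[0].rstrip("\n").split("\t")
        for col in ("chrom", "start", "end", "peak_id", "signal"):
            if col not in header:
                raise PeakFileError(path, [(1, f"missing column {col!r}")])
        start_line = 1
    elif dialect != "bed":
        raise ValueError(f"unknown dialect {dialect!r}")

    for lineno, raw in enumerate(lines[start_line:], start=start_line + 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if dialect == "bed":
                if len(fields) < 5:
                    raise ValueError(f"expected >=5 columns, got {len(fields)}")
                chrom, s, e, name, score = fields[:5]
                sample = fields[5] if len(fields) > 5 else ""
            else:
                row = dict(zip(header, fields))
                chrom, s, e = row["chrom"], row["start"], row["end"]
                name, score = row["peak_id"], row["signal"]
                sample = row.get("sample", "")
            start, end = _convert_in(int(s), int(e), coords)
            if start >= end:
                raise ValueError(f"start >= end ({s}, {e})")
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), name, float(score), sample)
            )
        except (ValueError, KeyError) as exc:
            errors.append((lineno, str(exc)))
    if errors:
        raise PeakFileError(path, errors)
    return PeakSet(peaks, mark=mark, genome_size=genome_size)


def write_peaks(ps: PeakSet, path, dialect: str = "bed", coords: str = "0-based") -> None:
    path = Path(path)
    rows = []
    for p in ps:
        s, e = _convert_out(p.interval.start, p.interval.end, coords)
        rows.append((p.interval.chrom, s, e, p.id, p.signal, p.sample))
    if dialect == "bed":
        with path.open("w") as fh:
            for chrom, s, e, name, sig, sample in rows:
                cols = [chrom, str(s), str(e), name, repr(sig)]
                if sample:
                    cols.append(sample)
                fh.write("\t".join(cols) + "\n")
    elif dialect == "tsv":
        pd.DataFrame(
            rows, columns=["chrom", "start", "end", "peak_id", "signal", "sample"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "start", "end", "baseline_expression"]


def read_genes(path, dialect: str = "tsv") -> list[GeneModel]:
    """Read gene models from a TSV (explicit tss column) or 6-column BED.

    In the BED dialect the TSS is inferred from the strand (start for '+',
    end for '-') and the score column carries baseline expression (RPKM).
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in GENE_COLUMNS if c not in df.columns]
        if missing:
            raise PeakFileError(path, [(1, f"missing columns {missing}")])
        genes = [
            GeneModel(
                str(r.gene_id),
                str(r.chrom),
                str(r.strand),
                int(r.tss),
                GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                float(r.baseline_expression),
            )
            for r in df.itertuples()
        ]
    elif dialect == "bed":
        genes = []
        errors = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if len(f) < 6:
                    raise ValueError(f"expected 6 columns, got {len(f)}")
                chrom, s, e, name, score, strand = f[:6]
                start, end = int(s), int(e)
                tss = start if strand == "+" else end
                genes.append(
                    GeneModel(
                        name, chrom, strand, tss,
                        GenomicInterval(chrom, start, end), float(score),
                    )
                )
            except ValueError as exc:
                errors.append((lineno, str(exc)))
        if errors:
            raise PeakFileError(path, errors)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return genes


def write_genes(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.strand, g.tss, g.body.start, g.body.end,
             g.baseline_expression)
            for g in genes
        ],
        columns=GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Overlap machinery


def _trees(ps: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in ps:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p.id
        )
    return trees


def overlap_pairs(a: PeakSet, b: PeakSet) -> list[tuple[str, str]]:
    """All (id_a, id_b) pairs whose intervals intersect by >= 1 bp.

    Symmetric in content: (x, y) appears here iff (y, x) appears for the
    swapped arguments. Empty inputs yield an empty list.
    """
    trees = _trees(b)
    pairs: list[tuple[str, str]] = []
    for p in a:
        tree = trees.get(p.interval.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(p.interval.start, p.interval.end)):
            pairs.append((p.id, hit.data))
    return pairs


def shared_peaks(donor1: PeakSet, donor2: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Peaks of donor1 with >= ``min_overlap`` bp overlap with any donor2 peak.

    Reference-donor convention: the result is a subset of donor1's catalog,
    one output peak per donor1 peak regardless of how many donor2 peaks it
    touches. Both directions can be obtained by swapping the arguments.
    """
    if donor1.mark != donor2.mark:
        raise ValueError(
            f"mark mismatch: {donor1.mark!r} vs {donor2.mark!r}"
        )
    trees = _trees(donor2)
    kept = []
    for p in donor1:
        tree = trees.get(p.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.interval.start, p.interval.end):
            if min(hit.end, p.interval.end) - max(hit.begin, p.interval.start) >= min_overlap:
                kept.append(p)
                break
    return PeakSet(kept, mark=donor1.mark, genome_size=donor1.genome_size)


def union_length(ps: PeakSet) -> int:
    """Total bp in the union of the peak intervals (overlaps counted once)."""
    total = 0
    for chrom, peaks in ps.by_chrom().items():
        cur_start, cur_end = None, None
        for p in peaks:  # already sorted by start
            if cur_end is None or p.interval.start > cur_end:
                if cur_end is not None:
                    total += cur_end - cur_start
                cur_start, cur_end = p.interval.start, p.interval.end
            else:
                cur_end = max(cur_end, p.interval.end)
        if cur_end is not None:
            total += cur_end - cur_start
    return total


def coverage_per_mb(ps: PeakSet) -> float:
    """bp of genome covered by the peak union per Mb of assayable genome."""
    if ps.genome_size is None or ps.genome_size <= 0:
        raise ValueError("coverage_per_mb requires genome_size > 0")
    return union_length(ps) / (ps.genome_size / 1e6)


# ---------------------------------------------------------------------------
# Nearest TSS


def distance_bin(signed_distance: float) -> str:
    d = abs(signed_distance)
    if d <= TSS_BIN_EDGES[0]:
        return TSS_BIN_LABELS[0]
    if d <= TSS_BIN_EDGES[1]:
        return TSS_BIN_LABELS[1]
    return TSS_BIN_LABELS[2]


def _gene_arrays(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray, list]]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        out[chrom] = (
            np.array([g.tss for g in gs], dtype=float),
            np.array([1.0 if g.strand == "+" else -1.0 for g in gs]),
            gs,
        )
    return out


def nearest_tss(p: Peak, genes: Sequence[GeneModel]) -> TssDistance:
    """Nearest-TSS record for a single peak (midpoint anchor, strand-aware sign).

    The distance is measured from the peak midpoint to the gene TSS with
    minimal absolute distance on the same chromosome; for '-' strand genes the
    sign is flipped so negative always means upstream of the TSS. Peaks on a
    chromosome without genes yield an unassigned record rather than an error.
    """
    if not genes:
        raise ValueError("nearest_tss requires at least one gene")
    arrays = _gene_arrays(genes)
    return _nearest_one(p, arrays)


def _nearest_one(p: Peak, arrays) -> TssDistance:
    chrom = p.interval.chrom
    if chrom not in arrays:
        return TssDistance(p.id, None, None, None, assigned=False)
    tss, sign, gs = arrays[chrom]
    mid = p.interval.midpoint
    d = mid - tss
    i = int(np.argmin(np.abs(d)))
    signed = float(d[i] * sign[i])
    return TssDistance(p.id, gs[i].gene_id, signed, distance_bin(signed))


def nearest_tss_table(ps: PeakSet, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Vectorized nearest-TSS over a whole PeakSet.

    Returns a DataFrame with columns peak_id, gene_id, signed_distance,
    bin, assigned.
    """
    if not genes:
        raise ValueError("nearest_tss_table requires at least one gene")
    arrays = _gene_arrays(genes)
    records = [_nearest_one(p, arrays) for p in ps]
    return pd.DataFrame(
        {
            "peak_id": [r.peak_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "signed_distance": [r.signed_distance for r in records],
            "bin": [r.bin for r in records],
            "assigned": [r.assigned for r in records],
        }
    )
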