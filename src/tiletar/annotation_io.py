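"""Genome annotation, probe-design and interval plumbing.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted on read and write, BED is native.  Chromosome sort order is
lexicographic by name so every output file is deterministic.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

log = logging.getLogger(__name__)

CHROM_X = "X"
CHROM_AUTOSOME = "autosome"

#: probe length bounds of the array design (bp)
DEFAULT_PROBE_LENGTH_RANGE = (49, 74)


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open [start, end)."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chromosome}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "Interval") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def interval_gap(a: Interval, b: Interval) -> int:
    """Base pairs strictly between two intervals; 0 if they overlap or abut.

    Raises ``ValueError`` for intervals on different chromosomes: a gap is
    only meaningful within one chromosome, so callers must pre-filter.
    """
    if a.chromosome != b.chromosome:
        raise ValueError(
            f"interval_gap requires one chromosome, got {a.chromosome!r} and {b.chromosome!r}"
        )
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) pairs as a sorted, non-overlapping list."""
    pairs = sorted(pairs)
    merged: list[list[int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_length(pairs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(pairs))


@dataclass(frozen=True)
class Gene:
    """A gene as a set of non-overlapping exon intervals on one chromosome.

    ``exons`` must already be the merged union (overlapping exon records from
    multiple isoforms are unioned on read, because the expressed-fraction rule
    needs a well-defined exonic footprint).
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon [{s}, {e}) in {self.gene_id}")
            if s < prev_end:
                raise ValueError(
                    f"exons of {self.gene_id} overlap or are unsorted; union them first"
                )
            prev_end = e


def gene_span(gene: Gene) -> Interval:
    """Genomic span of a gene, introns included."""
    return Interval(gene.chromosome, gene.exons[0][0], gene.exons[-1][1])


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    chrom_class: str = CHROM_AUTOSOME

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name} has length {self.length}")
        if self.chrom_class not in {CHROM_X, CHROM_AUTOSOME}:
            raise ValueError(f"bad chromosome class {self.chrom_class!r}")


@dataclass
class GenomeAnnotation:
    chromosomes: list[Chromosome]
    genes: list[Gene]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = {c.name: c.length for c in self.chromosomes}
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chromosome not in lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chromosome}")
            if g.exons[-1][1] > lengths[g.chromosome]:
                raise ValueError(f"gene {g.gene_id} extends past chromosome end")
        self.chromosomes.sort(key=lambda c: c.name)
        self.genes.sort(key=lambda g: (g.chromosome, g.exons[0][0], g.gene_id))

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def genes_on(self, chromosome: str) -> list[Gene]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def gene_spans_by_chromosome(self) -> dict[str, list[Interval]]:
        spans: dict[str, list[Interval]] = {c.name: [] for c in self.chromosomes}
        for g in self.genes:
            spans[g.chromosome].append(gene_span(g))
        for lst in spans.values():
            lst.sort(key=lambda iv: (iv.start, iv.end))
        return spans


@dataclass(frozen=True)
class Probe:
    probe_id: str
    probe_class: str  # "experimental" | "random"
    address: Interval | None

    @property
    def length(self) -> int | None:
        return None if self.address is None else self.address.length


class ProbeDesign:
    """Tiled experimental probes plus the address-less random-null population.

    Experimental probes are kept sorted by (chromosome, start); random probes
    never carry a genomic address, because the Markov-null background must not
    intersect any genomic feature logic.
    """

    def __init__(
        self,
        experimental: Sequence[Probe],
        random: Sequence[Probe],
        length_range: tuple[int, int] = DEFAULT_PROBE_LENGTH_RANGE,
    ) -> None:
        lo, hi = length_range
        ids: set[str] = set()
        for p in list(experimental) + list(random):
            if p.probe_id in ids:
                raise ValueError(f"duplicate probe id {p.probe_id}")
            ids.add(p.probe_id)
        for p in experimental:
            if p.address is None:
                raise ValueError(f"experimental probe {p.probe_id} lacks an address")
            if not (lo <= p.address.length <= hi):
                raise ValueError(
                    f"probe {p.probe_id} length {p.address.length} outside [{lo}, {hi}]"
                )
        for p in random:
            if p.address is not None:
                raise ValueError(f"random probe {p.probe_id} carries an address")
        self.experimental: list[Probe] = sorted(
            experimental, key=lambda p: (p.address.chromosome, p.address.start, p.address.end)
        )
        self.random: list[Probe] = list(random)
        self.length_range = (lo, hi)
        self._by_chrom: dict[str, tuple[list[int], list[int], list[Probe]]] | None = None

    def __len__(self) -> int:
        return len(self.experimental) + len(self.random)

    @property
    def random_ids(self) -> list[str]:
        return [p.probe_id for p in self.random]

    @property
    def experimental_ids(self) -> list[str]:
        return [p.probe_id for p in self.experimental]

    def _index(self) -> dict[str, tuple[list[int], list[int], list[Probe]]]:
        if self._by_chrom is None:
            by: dict[str, tuple[list[int], list[int], list[Probe]]] = {}
            for p in self.experimental:
                assert p.address is not None
                starts, ends, probes = by.setdefault(p.address.chromosome, ([], [], []))
                starts.append(p.address.start)
                ends.append(p.address.end)
                probes.append(p)
            self._by_chrom = by
        return self._by_chrom

    def probes_overlapping(self, interval: Interval) -> list[Probe]:
        """Experimental probes with ≥1 bp overlap with ``interval``."""
        idx = self._index().get(interval.chromosome)
        if idx is None:
            return []
        starts, ends, probes = idx
        max_len = self.length_range[1]
        lo = bisect.bisect_left(starts, interval.start - max_len)
        hi = bisect.bisect_left(starts, interval.end)
        return [
            probes[i]
            for i in range(lo, hi)
            if ends[i] > interval.start and starts[i] < interval.end
        ]


# ---------------------------------------------------------------------------
# GFF3


def _default_is_x(name: str) -> bool:
    return name.upper() == "X" or name.upper().endswith("X")


def _validate_gff_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GFF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GFF line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}: malformed GFF line {lineno}: bad coordinate range {start}-{end}"
                )


def read_gff(
    path: str | Path, x_chromosomes: Iterable[str] | None = None
) -> GenomeAnnotation:
    """Read a GFF3 annotation into a :class:`GenomeAnnotation`.

    GFF 1-based inclusive coordinates are converted to 0-based half-open.
    Exons are grouped under their (possibly transcript-mediated) parent gene
    and overlapping exon records are unioned.  Chromosome lengths come from
    ``##sequence-region`` pragmas when present, else from feature extents.
    Chromosomes are labelled X when named in ``x_chromosomes`` (default: any
    name ending in "X").
    """
    path = Path(path)
    _validate_gff_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    chrom_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chrom_lengths[parts[1]] = int(parts[3])

    gene_exons: dict[str, list[tuple[int, int]]] = {}
    gene_meta: dict[str, tuple[str, str]] = {}
    claimed_exons: set[str] = set()
    for gene in db.features_of_type("gene"):
        gid = gene.id
        gene_meta[gid] = (gene.seqid, gene.strand if gene.strand in "+-" else ".")
        exons = []
        for exon in db.children(gene, featuretype="exon"):
            claimed_exons.add(exon.id)
            exons.append((exon.start - 1, exon.end))
        if not exons:
            log.warning("gene %s has no exon records; using the gene extent", gid)
            exons = [(gene.start - 1, gene.end)]
        merged = merge_intervals(exons)
        if len(merged) != len(exons):
            log.warning("gene %s: overlapping exon records merged into union", gid)
        gene_exons[gid] = merged

    n_orphans = sum(
        1 for exon in db.features_of_type("exon") if exon.id not in claimed_exons
    )
    if n_orphans:
        log.warning("skipped %d exon record(s) without a parent gene", n_orphans)

    for gid, exons in gene_exons.items():
        chrom = gene_meta[gid][0]
        chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), exons[-1][1])

    is_x = (
        (lambda name: name in set(x_chromosomes))
        if x_chromosomes is not None
        else _default_is_x
    )
    chromosomes = [
        Chromosome(name, length, CHROM_X if is_x(name) else CHROM_AUTOSOME)
        for name, length in chrom_lengths.items()
    ]
    genes = [
        Gene(gid, gene_meta[gid][0], gene_meta[gid][1], tuple(exons))
        for gid, exons in gene_exons.items()
    ]
    return GenomeAnnotation(chromosomes, genes)


def write_gff(annotation: GenomeAnnotation, path: str | Path, source: str = "tiletar") -> None:
    """Write an annotation as GFF3 (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in annotation.chromosomes:
            fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
        for g in annotation.genes:
            span = gene_span(g)
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Probe design TSV

_PROBE_COLUMNS = ["probe_id", "class", "chromosome", "start", "end"]


def read_probe_design(
    path: str | Path,
    annotation: GenomeAnnotation | None = None,
    length_range: tuple[int, int] = DEFAULT_PROBE_LENGTH_RANGE,
) -> ProbeDesign:
    """Read the probe-design TSV (probe_id, class, chromosome, start, end).

    Random probes must be address-less; an address on a random probe is
    ignored with a warning.  When ``annotation`` is given, experimental
    probes outside chromosome bounds raise an error.
    """
    experimental: list[Probe] = []
    random: list[Probe] = []
    lengths = annotation.chromosome_lengths if annotation is not None else None
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[: len(_PROBE_COLUMNS)] != _PROBE_COLUMNS:
                    raise ValueError(
                        f"{path}: expected columns {_PROBE_COLUMNS}, got {header}"
                    )
                continue
            row = dict(zip(header, fields))
            pid, pclass = row["probe_id"], row["class"]
            has_address = row.get("chromosome", "") not in ("", ".")
            if pclass == "random":
                if has_address:
                    log.warning(
                        "%s line %d: random probe %s carries an address; ignored",
                        path, lineno, pid,
                    )
                random.append(Probe(pid, "random", None))
            elif pclass == "experimental":
                if not has_address:
                    raise ValueError(
                        f"{path} line {lineno}: experimental probe {pid} lacks an address"
                    )
                iv = Interval(row["chromosome"], int(row["start"]), int(row["end"]))
                if lengths is not None:
                    if iv.chromosome not in lengths:
                        raise ValueError(
                            f"{path} line {lineno}: probe {pid} on unknown chromosome "
                            f"{iv.chromosome}"
                        )
                    if iv.end > lengths[iv.chromosome]:
                        raise ValueError(
                            f"{path} line {lineno}: probe {pid} extends past the end of "
                            f"{iv.chromosome}"
                        )
                experimental.append(Probe(pid, "experimental", iv))
            else:
                raise ValueError(f"{path} line {lineno}: unknown probe class {pclass!r}")
    return ProbeDesign(experimental, random, length_range=length_range)


def write_probe_design(design: ProbeDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PROBE_COLUMNS) + "\n")
        for p in design.experimental:
            a = p.address
            assert a is not None
            fh.write(f"{p.probe_id}\texperimental\t{a.chromosome}\t{a.start}\t{a.end}\n")
        for p in design.random:
            fh.write(f"{p.probe_id}\trandom\t\t\t\n")


# ---------------------------------------------------------------------------
# BED


@dataclass(frozen=True)
class BedRecord:
    interval: Interval
    name: str = "."
    score: int = 0
    strand: str = "."


def write_bed(records: Iterable, path: str | Path, track_name: str = "tiletar") -> None:
    """Write intervals/TAR-like records as BED6.

    Accepts :class:`Interval`, :class:`BedRecord`, or any object with an
    ``interval`` attribute plus optional ``id``/``mean_signal``.  The score
    column is mean signal × 100 rounded, clamped to the BED range [0, 1000].
    """
    rows: list[BedRecord] = []
    for r in records:
        if isinstance(r, BedRecord):
            rows.append(r)
        elif isinstance(r, Interval):
            rows.append(BedRecord(r))
        else:
            signal = getattr(r, "mean_signal", 0.0) or 0.0
            score = int(min(1000, max(0, round(signal * 100))))
            rows.append(BedRecord(r.interval, getattr(r, "id", "."), score))
    rows.sort(key=lambda b: (b.interval.chromosome, b.interval.start, b.interval.end))
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for b in rows:
            iv = b.interval
            fh.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{b.name}\t{b.score}\t{b.strand}\n"
            )


def read_bed(path: str | Path) -> list[BedRecord]:
    records: list[BedRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            iv = Interval(fields[0], int(fields[1]), int(fields[2]))
            name = fields[3] if len(fields) > 3 else "."
            score = int(fields[4]) if len(fields) > 4 else 0
            strand = fields[5] if len(fields) > 5 else "."
            records.append(BedRecord(iv, name, score, strand))
    return records
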