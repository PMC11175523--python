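"""Readers, writers and the shared data model for gene maps, ortholog tables,
repeat annotations and species trees.

All coordinates are 0-based half-open internally; conversion from the 1-based
closed GFF3 convention (and to/from RepeatMasker ``.out``) happens only at the
I/O boundary.  Genes belong to the chromosome named in their record, and the
synteny statistics downstream operate on per-chromosome gene *ranks* (order by
ascending start), never on base-pair positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

TE_CLASSES = ("DNA", "LTR", "LINE", "SINE")

__all__ = [
    "Gene",
    "GeneMap",
    "OrthologPairSet",
    "TETrack",
    "read_gene_map",
    "write_gene_map",
    "read_ortholog_pairs",
    "write_ortholog_pairs",
    "read_te_annotation",
    "write_te_track",
    "read_species_tree",
    "TE_CLASSES",
]


class ParseError(ValueError):
    """A malformed input line; carries the offending line number."""


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"
    rank: int = -1  # 0-based index along the chromosome, by ascending start


@dataclass
class GeneMap:
    """Ordered gene coordinates and per-chromosome gene ranks for one genome."""

    genome_id: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in genome {self.genome_id!r}")
            if g.start >= g.end:
                raise ValueError(f"gene {g.gene_id!r}: start must be < end")
            seen.add(g.gene_id)
        if any(g.rank < 0 for g in self.genes):
            self.genes = _assign_ranks(self.genes)
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in first-appearance order."""
        out: list[str] = []
        for g in self.genes:
            if g.chrom not in out:
                out.append(g.chrom)
        return out

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted((g for g in self.genes if g.chrom == chrom), key=lambda g: g.rank)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: sum(1 for g in self.genes if g.chrom == c) for c in self.chromosomes}


def _assign_ranks(genes: Sequence[Gene]) -> list[Gene]:
    out: list[Gene] = []
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    ranked: dict[str, Gene] = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(gs):
            ranked[g.gene_id] = Gene(g.gene_id, g.chrom, g.start, g.end, g.strand, i)
    for g in genes:
        out.append(ranked[g.gene_id])
    return out


@dataclass
class OrthologPairSet:
    """One-to-one ortholog pairs between two genomes.

    ``conflicts`` lists genes that appeared in more than one input pair and
    whose pairs were therefore all dropped.
    """

    genome_a: str
    genome_b: str
    pairs: list[tuple[str, str]] = field(default_factory=list)
    provenance: str = "given"
    conflicts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_seen: set[str] = set()
        b_seen: set[str] = set()
        for a, b in self.pairs:
            if a in a_seen or b in b_seen:
                raise ValueError(f"pair ({a},{b}) violates one-to-one orthology")
            a_seen.add(a)
            b_seen.add(b)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class TETrack:
    """Typed repeat intervals (DNA/LTR/LINE/SINE), 0-based half-open."""

    genome_id: str
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    dropped_classes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, start, end, cls in self.intervals:
            if start >= end:
                raise ValueError(f"TE interval on {chrom}: start must be < end")
            if cls not in TE_CLASSES:
                raise ValueError(f"unknown TE class {cls!r}")

    def __len__(self) -> int:
        return len(self.intervals)

    def on(self, chrom: str, classes: Iterable[str] | None = None) -> list[tuple[int, int, str]]:
        keep = set(TE_CLASSES if classes is None else classes)
        return [(s, e, c) for ch, s, e, c in self.intervals if ch == chrom and c in keep]


# ---------------------------------------------------------------------------
# readers


def read_gene_map(path: str | Path, format: str, genome_id: str | None = None) -> GeneMap:
    """Read a gene map from GFF3 (1-based closed) or BED (0-based half-open)."""
    path = Path(path)
    gid = genome_id or path.stem
    if format == "gff3":
        genes = list(_iter_gff3(path))
    elif format == "bed":
        genes = list(_iter_bed(path))
    else:
        raise ValueError(f"unknown gene map format {format!r}")
    return GeneMap(gid, genes)


def _iter_gff3(path: Path):
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="error", from_string=False,
    )
    featuretypes = set(db.featuretypes())
    ftype = "gene" if "gene" in featuretypes else None
    feats = db.features_of_type(ftype) if ftype else db.all_features()
    for f in feats:
        gene_id = f.attributes.get("ID", [f.id])[0]
        # GFF3 is 1-based closed: (start-1, end) is the half-open interval
        yield Gene(gene_id, f.seqid, f.start - 1, f.end, f.strand if f.strand in "+-" else "+")


def _iter_bed(path: Path):
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: BED record needs >=4 fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
        yield Gene(parts[3], parts[0], start, end, strand)


def write_gene_map(gmap: GeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tchrom\tstart\tend\tstrand\trank\n")
        for g in gmap.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.rank}\n")


def read_ortholog_pairs(path: str | Path, genome_a: str = "A", genome_b: str = "B") -> OrthologPairSet:
    """Read a >=2 column TSV of gene id pairs.

    Exact duplicate rows are collapsed; genes that still appear in more than
    one pair violate the one-to-one rule and *all* their pairs are dropped
    (the genes are recorded in ``conflicts``).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty ortholog table")
    rows = list(dict.fromkeys(zip(df[0], df[1])))  # dedup, keep order
    from collections import Counter

    ca = Counter(a for a, _ in rows)
    cb = Counter(b for _, b in rows)
    bad_a = {a for a, n in ca.items() if n > 1}
    bad_b = {b for b, n in cb.items() if n > 1}
    pairs = [(a, b) for a, b in rows if a not in bad_a and b not in bad_b]
    conflicts = sorted(bad_a) + sorted(bad_b)
    return OrthologPairSet(genome_a, genome_b, pairs, "given", conflicts)


def write_ortholog_pairs(pairs: OrthologPairSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gene_{pairs.genome_a}\tgene_{pairs.genome_b}\n")
        for a, b in pairs.pairs:
            fh.write(f"{a}\t{b}\n")


def _map_te_class(raw: str) -> str | None:
    for cls in TE_CLASSES:
        if raw.upper().startswith(cls):
            return cls
    return None


def read_te_annotation(path: str | Path, format: str, genome_id: str | None = None) -> TETrack:
    """Read repeat intervals from RepeatMasker ``.out`` or BED-with-class.

    The class/family column is mapped onto the four TE classes by prefix
    (``DNA*``, ``LTR*``, ``LINE*``, ``SINE*``); anything else (simple repeats,
    satellites, ...) is dropped and tallied in ``dropped_classes``.
    """
    path = Path(path)
    gid = genome_id or path.stem
    intervals: list[tuple[str, int, int, str]] = []
    dropped: dict[str, int] = {}
    if format == "rm_out":
        lines = path.read_text().splitlines()
        for line in lines[3:]:  # standard 3-line header
            if not line.strip():
                continue
            parts = line.split()
            chrom, begin, end, raw_cls = parts[4], int(parts[5]), int(parts[6]), parts[10]
            cls = _map_te_class(raw_cls)
            if cls is None:
                dropped[raw_cls] = dropped.get(raw_cls, 0) + 1
                continue
            intervals.append((chrom, begin - 1, end, cls))  # rm_out is 1-based closed
    elif format == "bed":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
        for _, row in df.iterrows():
            cls = _map_te_class(str(row[3]))
            if cls is None:
                dropped[str(row[3])] = dropped.get(str(row[3]), 0) + 1
                continue
            intervals.append((str(row[0]), int(row[1]), int(row[2]), cls))
    else:
        raise ValueError(f"unknown TE annotation format {format!r}")
    return TETrack(gid, intervals, dropped)


def write_te_track(track: TETrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tte_class\n")
        for chrom, start, end, cls in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{cls}\n")


def read_species_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted newick species tree (path or newick string)."""
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        data = Path(source).read_text()
    else:
        data = str(source)
    tree = dendropy.Tree.get(data=data, schema="newick", suppress_internal_node_taxa=False)
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in species tree")
    return tree
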