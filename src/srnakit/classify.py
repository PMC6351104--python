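"""ncRNA exclusion, exact-match genome alignment, small-RNA class taxonomy.

Alignment is zero-mismatch by contract: an insert is reported only where the
genome substring equals it exactly (both strands; minus-strand hits are given
in forward coordinates with strand '-').  Classes are assigned per read with
the precedence miRNA > 21U > 22G > 26G > other:

* miRNA — insert equals an annotated mature miRNA sequence;
* 21U   — 21 nt, 5' U, aligned within an annotated 21U locus on its strand;
* 22G   — 21-23 nt, 5' G, antisense to an annotated gene (also rolled up
          into the broader 21-23 nt siRNA tally);
* 26G   — 25-27 nt, 5' G, antisense to a gene.

Library depth for rpm normalization is the number of genome-mapping reads
excluding those matching known ncRNAs (rRNA/tRNA/snoRNA).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import GenomeBundle, IntervalIndex, revcomp

SEED_K = 15  # minimum query length the index supports


@dataclass(frozen=True)
class Alignment:
    read_id: str
    chrom: str
    start: int  # 0-based, forward coordinates
    strand: str
    length: int
    n_hits: int

    @property
    def weight(self) -> float:
        return 1.0 / self.n_hits

    @property
    def end(self) -> int:
        return self.start + self.length


class NormalizationError(ZeroDivisionError):
    """rpm requested against a zero normalization depth."""


class ExactMatchIndex:
    """Seed-and-verify exact-match index over both genome strands.

    Seeds are 15-mers; queries of length 15-30 are located by looking up
    their leading 15-mer and verifying the full-length extension against
    the genome, so only perfect full-length matches are ever reported.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise ValueError("empty genome")
        self.sequences = sequences
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in sequences.items():
            for i in range(len(seq) - SEED_K + 1):
                self._seeds.setdefault(seq[i : i + SEED_K], []).append((chrom, i))

    @classmethod
    def from_bundle(cls, bundle: GenomeBundle) -> "ExactMatchIndex":
        return cls(bundle.sequences)

    def lookup(self, query: str) -> list[tuple[str, int, str]]:
        """All (chrom, start, strand) loci whose sequence equals the query."""
        if len(query) < SEED_K:
            raise ValueError(f"query shorter than {SEED_K} nt")
        hits = []
        n = len(query)
        for chrom, i in self._seeds.get(query[:SEED_K], ()):
            if self.sequences[chrom][i : i + n] == query:
                hits.append((chrom, i, "+"))
        rc = revcomp(query)
        for chrom, i in self._seeds.get(rc[:SEED_K], ()):
            if self.sequences[chrom][i : i + n] == rc:
                hits.append((chrom, i, "-"))
        hits.sort(key=lambda h: (h[0], h[1], h[2]))
        return hits


def exclude_ncrna(inserts, bundle: GenomeBundle):
    """Drop inserts matching any ncRNA feature sequence (either strand).

    Matching means exact occurrence as a substring of the annotated feature,
    mirroring a zero-mismatch alignment against an ncRNA reference.
    Returns (retained, n_excluded).
    """
    blobs = []
    for f in bundle.ncrnas:
        s = bundle.sequences[f.chrom][f.start:f.end]
        blobs.append(s)
        blobs.append(revcomp(s))
    blob = "#".join(blobs)
    retained = [r for r in inserts if r.insert not in blob]
    return retained, len(inserts) - len(retained)


def align_perfect(inserts, index: ExactMatchIndex):
    """Zero-mismatch alignment; multi-mappers get weight 1/n_hits per hit.

    Returns (alignments: read_id -> [Alignment...], unaligned read_ids).
    """
    alignments: dict[str, list[Alignment]] = {}
    unaligned: list[str] = []
    for rec in inserts:
        hits = index.lookup(rec.insert)
        if not hits:
            unaligned.append(rec.read_id)
            continue
        alignments[rec.read_id] = [
            Alignment(rec.read_id, c, s, d, rec.length, len(hits)) for c, s, d in hits
        ]
    return alignments, unaligned


class AnnotationLookup:
    """Fast containment queries against the bundle's annotation tracks."""

    def __init__(self, bundle: GenomeBundle):
        self.genes = IntervalIndex(bundle.genes)
        self.pirna = IntervalIndex(bundle.pirna_loci)
        self.mirna_seqs = frozenset(bundle.feature_seq(m) for m in bundle.mirnas)

    def gene_containing(self, aln: Alignment):
        return self.genes.containing(aln.chrom, aln.start, aln.end)

    def antisense_gene(self, aln: Alignment):
        g = self.gene_containing(aln)
        if g is not None and g.strand != aln.strand:
            return g
        return None


def classify_read(insert, alignments, ann: AnnotationLookup) -> str:
    """Assign the small-RNA class of one aligned read (precedence above)."""
    if not alignments:
        raise ValueError("classify_read requires at least one alignment")
    if insert.insert in ann.mirna_seqs:
        return "miRNA"
    if insert.length == 21 and insert.first_nt == "T":
        for aln in alignments:
            locus = ann.pirna.containing(aln.chrom, aln.start, aln.end)
            if locus is not None and locus.strand == aln.strand:
                return "21U"
    if insert.first_nt == "G":
        if 21 <= insert.length <= 23:
            if any(ann.antisense_gene(a) is not None for a in alignments):
                return "22G"
        if 25 <= insert.length <= 27:
            if any(ann.antisense_gene(a) is not None for a in alignments):
                return "26G"
    return "other"


@dataclass
class LibraryStats:
    """Per-library tallies and the rpm normalization denominator."""

    depth: int
    class_counts: dict
    n_ncrna_excluded: int
    n_unaligned: int
    sirna_21_23: int  # 21-23 nt reads antisense to genes (encompasses 22G)

    def rpm(self, count: float) -> float:
        return normalize_rpm(count, self.depth)

    def as_dict(self) -> dict:
        return {
            "depth": self.depth,
            "class_counts": {
                k: {"reads": v, "rpm": normalize_rpm(v, self.depth)}
                for k, v in self.class_counts.items()
            },
            "n_ncrna_excluded": self.n_ncrna_excluded,
            "n_unaligned": self.n_unaligned,
            "sirna_21_23": self.sirna_21_23,
        }


def normalize_rpm(count: float, depth: int) -> float:
    """reads-per-million: 1e6 * count / depth."""
    if depth <= 0:
        raise NormalizationError("normalization depth is zero")
    return 1e6 * count / depth


def classify_library(inserts, bundle: GenomeBundle, index: ExactMatchIndex | None = None):
    """Full per-library classification: exclude ncRNA, align, classify.

    Returns (hits, stats) where hits is a DataFrame with one row per
    genomic hit (multi-mappers appear n_hits times with weight 1/n_hits;
    is_best marks the lowest-coordinate hit used for class tallies) and
    stats is a LibraryStats whose class counts partition the depth.
    """
    if index is None:
        index = ExactMatchIndex.from_bundle(bundle)
    retained, n_excluded = exclude_ncrna(inserts, bundle)
    alignments, unaligned = align_perfect(retained, index)
    ann = AnnotationLookup(bundle)

    rows = []
    class_counts: dict[str, int] = {}
    sirna = 0
    by_id = {r.read_id: r for r in retained}
    for read_id, alns in alignments.items():
        rec = by_id[read_id]
        label = classify_read(rec, alns, ann)
        class_counts[label] = class_counts.get(label, 0) + 1
        if 21 <= rec.length <= 23 and label not in ("miRNA", "21U"):
            if any(ann.antisense_gene(a) is not None for a in alns):
                sirna += 1
        for j, aln in enumerate(alns):
            rows.append(
                (read_id, aln.chrom, aln.start, aln.strand, aln.length,
                 rec.first_nt, aln.n_hits, aln.weight, label, j == 0)
            )
    hits = pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "start", "strand", "length",
                 "first_nt", "n_hits", "weight", "class", "is_best"],
    )
    stats = LibraryStats(
        depth=len(alignments),
        class_counts=class_counts,
        n_ncrna_excluded=n_excluded,
        n_unaligned=len(unaligned),
        sirna_21_23=sirna,
    )
    return hits, stats
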