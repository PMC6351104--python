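"""Toy genome model: sequences, gene/ncRNA/miRNA/21U annotations, target sets.

Internal coordinates are 0-based half-open throughout; GFF3 I/O converts to
and from the on-disk 1-based closed convention.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and map U to T (RNA input is treated as DNA internally)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene interval (single transcript model per gene)."""

    id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Feature:
    """A non-gene annotation interval (rRNA/tRNA/snoRNA, miRNA, 21U locus)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # rRNA | tRNA | snoRNA | miRNA | piRNA

    @property
    def length(self) -> int:
        return self.end - self.start


class PlacementError(RuntimeError):
    """Raised when non-overlapping feature placement fails after retries."""


@dataclass
class GenomeBundle:
    """A toy genome plus every annotation track the pipeline consumes.

    ``target_sets`` holds named Argonaute target lists (gene-ID sets) such as
    CSR1 / WAGO1 / HRDE1, used by the overlap and metagene stages.
    """

    sequences: dict[str, str]
    genes: list[GeneModel]
    ncrnas: list[Feature] = field(default_factory=list)
    mirnas: list[Feature] = field(default_factory=list)
    pirna_loci: list[Feature] = field(default_factory=list)
    target_sets: dict[str, set[str]] = field(default_factory=dict)

    def validate(self) -> None:
        gene_ids = [g.id for g in self.genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene IDs are not unique")
        for feat in self.all_features():
            seq = self.sequences.get(feat.chrom)
            if seq is None:
                raise ValueError(f"{feat.id}: unknown chromosome {feat.chrom}")
            if feat.start < 0 or feat.end > len(seq):
                raise ValueError(f"{feat.id}: outside chromosome bounds")
        id_set = set(gene_ids)
        for name, members in self.target_sets.items():
            if not members <= id_set:
                raise ValueError(f"target set {name} contains unknown gene IDs")
        for g in self.genes:
            for nc in self.ncrnas:
                if g.chrom == nc.chrom and g.start < nc.end and nc.start < g.end:
                    raise ValueError(f"gene {g.id} overlaps ncRNA {nc.id}")

    def all_features(self) -> list:
        return list(self.genes) + self.ncrnas + self.mirnas + self.pirna_loci

    def feature_seq(self, feat) -> str:
        """Strand-aware sequence of a feature (5'->3' on its own strand)."""
        s = self.sequences[feat.chrom][feat.start:feat.end]
        return revcomp(s) if feat.strand == "-" else s

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def to_gff3(self, path) -> None:
        rows = []
        for g in self.genes:
            rows.append((g.chrom, "gene", g.start, g.end, g.strand, g.id))
        for feat in self.ncrnas + self.mirnas + self.pirna_loci:
            rows.append((feat.chrom, feat.kind, feat.start, feat.end, feat.strand, feat.id))
        rows.sort(key=lambda r: (r[0], r[2], r[5]))
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, ftype, start, end, strand, fid in rows:
                # 0-based half-open -> 1-based closed
                fh.write(
                    f"{chrom}\tsrnakit\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\tID={fid}\n"
                )

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_fasta(outdir / "genome.fa")
        self.to_gff3(outdir / "features.gff3")
        with open(outdir / "target_sets.json", "w") as fh:
            json.dump({k: sorted(v) for k, v in self.target_sets.items()}, fh, indent=1)

    @classmethod
    def from_files(cls, fasta_path, gff3_path, target_sets_path=None) -> "GenomeBundle":
        import gffutils
        from Bio import SeqIO

        sequences = {
            rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
        )
        genes: list[GeneModel] = []
        ncrnas: list[Feature] = []
        mirnas: list[Feature] = []
        pirna: list[Feature] = []
        for f in db.all_features():
            start, end = f.start - 1, f.end  # 1-based closed -> 0-based half-open
            fid = f.attributes.get("ID", [f.id])[0]
            if f.featuretype == "gene":
                genes.append(GeneModel(fid, f.seqid, start, end, f.strand))
            elif f.featuretype in ("rRNA", "tRNA", "snoRNA"):
                ncrnas.append(Feature(fid, f.seqid, start, end, f.strand, f.featuretype))
            elif f.featuretype == "miRNA":
                mirnas.append(Feature(fid, f.seqid, start, end, f.strand, "miRNA"))
            elif f.featuretype == "piRNA":
                pirna.append(Feature(fid, f.seqid, start, end, f.strand, "piRNA"))
        target_sets: dict[str, set[str]] = {}
        if target_sets_path is not None:
            with open(target_sets_path) as fh:
                target_sets = {k: set(v) for k, v in json.load(fh).items()}
        bundle = cls(sequences, genes, ncrnas, mirnas, pirna, target_sets)
        bundle.validate()
        return bundle


class IntervalIndex:
    """Locate the containing feature for a position among disjoint intervals."""

    def __init__(self, features) -> None:
        self._by_chrom: dict[str, tuple[list[int], list]] = {}
        for chrom in {f.chrom for f in features}:
            feats = sorted((f for f in features if f.chrom == chrom), key=lambda f: f.start)
            self._by_chrom[chrom] = ([f.start for f in feats], feats)

    def containing(self, chrom: str, start: int, end: int):
        """Feature whose interval fully contains [start, end), or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, feats = entry
        i = bisect_right(starts, start) - 1
        if i >= 0 and feats[i].start <= start and end <= feats[i].end:
            return feats[i]
        return None
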