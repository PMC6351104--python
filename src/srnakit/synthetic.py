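"""Synthetic small-RNA data with planted, known ground truth.

Generates toy genomes with gene/ncRNA/miRNA/21U annotation tracks, small-RNA
FASTQ libraries whose reads follow the field's class signatures (22G: 22 nt,
5' G, antisense to a gene; 21U: 21 nt, 5' U from dedicated loci; 26G: 26 nt,
5' G antisense; miRNA: copies of annotated mature miRNAs), and replicate
negative-binomial count tables. Every read carries a truth record (class,
source gene, scaled position) so each downstream stage can be verified
against what was planted.

Mutant libraries implement two phenotypes: per-gene 22G depletion (gene
sampling weights multiplied by a fold-change) and a 3'-ward positional shift
(genotype-specific Beta parameters for the within-gene 5'-end position).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Feature, GeneModel, GenomeBundle, PlacementError, revcomp
from .read_processing import find_linker

CLASS_NAMES = ("miRNA", "21U", "22G", "26G", "other", "ncRNA")
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream_seed(seed: int, name: str) -> int:
    """Stable per-library seed derived from a global seed and a library name.

    Adding a library never perturbs the streams of existing ones.
    """
    digest = hashlib.blake2b(f"{seed}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def beta_for_mean(mean: float, concentration: float = 10.0) -> tuple[float, float]:
    """Beta(a, b) parameters with the given mean and a + b = concentration."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie in (0, 1)")
    return mean * concentration, (1.0 - mean) * concentration


@dataclass
class SimulationConfig:
    """Parameters of a simulated small-RNA library.

    ``five_prime_bias`` maps genotype to Beta(a, b) parameters over the
    scaled transcript coordinate of 22G 5' ends; shifting the mutant Beta
    mean 3'-ward implements a 5'-depletion phenotype.  ``depleted_genes``
    maps gene IDs to mutant fold-changes applied to 22G sampling weights.
    """

    class_mixture: dict = field(
        default_factory=lambda: {"miRNA": 0.15, "21U": 0.20, "22G": 0.50, "26G": 0.05, "other": 0.10}
    )
    depth: int = 100_000
    depleted_genes: dict = field(default_factory=dict)
    five_prime_bias: dict = field(
        default_factory=lambda: {"WT": beta_for_mean(0.5), "MUT": beta_for_mean(0.5)}
    )
    error_rate: float = 0.0
    barcode: str = "ACGT"
    linker: str = "CTGTAG"
    read_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.class_mixture) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown classes in mixture: {sorted(unknown)}")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture sums to {total}, not 1")
        if any(p < 0 for p in self.class_mixture.values()):
            raise ValueError("mixture proportions must be non-negative")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must lie in [0, 0.1)")
        for geno, ab in self.five_prime_bias.items():
            if len(ab) != 2 or ab[0] <= 0 or ab[1] <= 0:
                raise ValueError(f"bad Beta parameters for {geno}: {ab}")
        for gid, fc in self.depleted_genes.items():
            if fc < 0:
                raise ValueError(f"negative fold-change for {gid}")


# --------------------------------------------------------------------- genome


def _place(rng, occupied_starts, occupied, length, chrom_length, max_tries=2000):
    """Pick a start for a new interval disjoint from all placed ones."""
    from bisect import bisect_left, insort

    for _ in range(max_tries):
        s = int(rng.integers(0, chrom_length - length))
        e = s + length
        i = bisect_left(occupied_starts, e)
        # neighbours that could overlap [s, e)
        ok = True
        if i > 0 and occupied[i - 1][1] > s:
            ok = False
        if i < len(occupied) and occupied[i][0] < e:
            ok = False
        if ok:
            insort(occupied_starts, s)
            occupied.insert(bisect_left(occupied_starts, s), (s, e))
            # keep both lists aligned
            occupied.sort()
            return s
    raise PlacementError(
        f"could not place a {length}-nt feature in a {chrom_length}-nt chromosome"
    )


def generate_genome(
    n_genes: int,
    gene_length_range: tuple[int, int] = (500, 1500),
    n_ncrna: int = 6,
    n_mirna: int = 8,
    n_pirna: int = 20,
    seed: int = 0,
    chrom: str = "chr1",
    chrom_length: int | None = None,
    out_dir=None,
) -> GenomeBundle:
    """Random toy genome with mutually disjoint annotation tracks.

    Deterministic for a fixed seed.  21U loci are planted with a 5' T so
    that reads copied from them carry the class's first-nucleotide
    signature.  Target sets CSR1/WAGO1/HRDE1 are random gene subsets
    (40/30/30%, possibly overlapping, as Argonaute target lists do).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gene_length_range
    if lo < 100:
        raise ValueError("gene lengths must be >= 100 nt")
    rng = np.random.default_rng(seed)

    gene_lengths = rng.integers(lo, hi + 1, size=n_genes)
    nc_kinds = ["rRNA", "tRNA", "snoRNA"]
    nc_lengths = [120, 72, 90]
    mass = int(gene_lengths.sum()) + sum(
        nc_lengths[i % 3] for i in range(n_ncrna)
    ) + 22 * n_mirna + 21 * n_pirna
    if chrom_length is None:
        chrom_length = int(2.2 * mass) + 2000

    seq = bytearray(_NT[rng.integers(0, 4, size=chrom_length)].tobytes())

    occupied_starts: list[int] = []
    occupied: list[tuple[int, int]] = []
    genes = []
    for i in range(n_genes):
        length = int(gene_lengths[i])
        s = _place(rng, occupied_starts, occupied, length, chrom_length)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{i:04d}", chrom, s, s + length, strand))
    ncrnas = []
    for i in range(n_ncrna):
        kind = nc_kinds[i % 3]
        length = nc_lengths[i % 3]
        s = _place(rng, occupied_starts, occupied, length, chrom_length)
        strand = "+" if rng.random() < 0.5 else "-"
        ncrnas.append(Feature(f"ncrna{i:02d}_{kind}", chrom, s, s + length, strand, kind))
    mirnas = []
    for i in range(n_mirna):
        s = _place(rng, occupied_starts, occupied, 22, chrom_length)
        strand = "+" if rng.random() < 0.5 else "-"
        mirnas.append(Feature(f"mir{i:02d}", chrom, s, s + 22, strand, "miRNA"))
    pirna = []
    for i in range(n_pirna):
        s = _place(rng, occupied_starts, occupied, 21, chrom_length)
        strand = "+" if rng.random() < 0.5 else "-"
        # plant the 21U 5'-uridine signature
        if strand == "+":
            seq[s] = ord("T")
        else:
            seq[s + 20] = ord("A")
        pirna.append(Feature(f"p21u{i:03d}", chrom, s, s + 21, strand, "piRNA"))

    gene_ids = np.array([g.id for g in genes])
    target_sets = {}
    for name, frac in (("CSR1", 0.4), ("WAGO1", 0.3), ("HRDE1", 0.3)):
        k = max(1, int(round(frac * n_genes)))
        target_sets[name] = set(rng.choice(gene_ids, size=min(k, n_genes), replace=False))

    bundle = GenomeBundle(
        sequences={chrom: seq.decode()},
        genes=genes,
        ncrnas=ncrnas,
        mirnas=mirnas,
        pirna_loci=pirna,
        target_sets=target_sets,
    )
    bundle.validate()
    if out_dir is not None:
        bundle.to_dir(out_dir)
    return bundle


# -------------------------------------------------------------------- library


class ConfigurationError(ValueError):
    """A requested read class has no compatible locus in the bundle."""


def _unambiguous(insert: str, linker: str) -> bool:
    """True when linker search on insert + linker hits exactly the junction.

    Emitted inserts are constrained to contain no window within one
    mismatch of the 3' linker, so trimming recovers every insert verbatim;
    reads violating this are resampled (real libraries carry a small
    ambiguous fraction that toy truth-recovery deliberately excludes).
    """
    return find_linker(insert + linker, linker) == (len(insert), 0)


def _gene_sampling(bundle: GenomeBundle, config: SimulationConfig, genotype: str):
    genes = bundle.genes
    weights = np.ones(len(genes))
    if genotype == "MUT":
        for i, g in enumerate(genes):
            if g.id in config.depleted_genes:
                weights[i] *= config.depleted_genes[g.id]
    if weights.sum() <= 0:
        raise ConfigurationError("all 22G sampling weights are zero")
    return weights / weights.sum()


def _valid_offsets(bundle: GenomeBundle, gene: GeneModel, read_len: int) -> np.ndarray:
    """Transcript offsets o where a read of read_len ending its 5' end at o
    lies inside the gene and starts with G (transcript base at o is C)."""
    tr = np.frombuffer(bundle.feature_seq(gene).encode(), dtype=np.uint8)
    pos = np.nonzero(tr == ord("C"))[0]
    return pos[(pos >= read_len - 1) & (pos <= gene.length - 1)]


def _antisense_read(bundle, gene, offset, read_len):
    """Insert sequence + genomic alignment of an antisense read whose 5' end
    sits at transcript offset ``offset``."""
    tr = bundle.feature_seq(gene)
    insert = revcomp(tr[offset - read_len + 1 : offset + 1])
    if gene.strand == "+":
        start = gene.start + offset - read_len + 1
        strand = "-"
    else:
        start = gene.end - 1 - offset
        strand = "+"
    return insert, start, strand


def simulate_small_rna_library(
    bundle: GenomeBundle,
    config: SimulationConfig,
    genotype: str,
    out_fastq=None,
    out_truth=None,
    library_name: str | None = None,
):
    """Simulate one small-RNA library; returns (reads, truth table).

    ``reads`` is a list of (read_id, full read sequence); the truth table is
    a DataFrame aligned 1:1 and in the same order, recording the class,
    source gene/locus, genomic placement and scaled 22G/26G position of each
    insert.  Full reads are barcode + insert + linker + random padding to
    ``read_length`` with constant 'I' qualities.
    """
    if genotype not in ("WT", "MUT"):
        raise ValueError("genotype must be WT or MUT")
    config.validate()
    name = library_name or genotype
    rng = np.random.default_rng(substream_seed(config.seed, name))

    classes = [c for c in CLASS_NAMES if config.class_mixture.get(c, 0.0) > 0]
    probs = np.array([config.class_mixture[c] for c in classes])
    if "miRNA" in classes and not bundle.mirnas:
        raise ConfigurationError("miRNA reads requested but bundle has no miRNAs")
    if "21U" in classes and not bundle.pirna_loci:
        raise ConfigurationError("21U reads requested but bundle has no 21U loci")
    if ("22G" in classes or "26G" in classes) and not bundle.genes:
        raise ConfigurationError("22G/26G reads requested but bundle has no genes")
    if "ncRNA" in classes and not bundle.ncrnas:
        raise ConfigurationError("ncRNA reads requested but bundle has no ncRNAs")

    cls_idx = rng.choice(len(classes), size=config.depth, p=probs)
    n = config.depth
    cls_arr = np.array(classes, dtype=object)[cls_idx]
    gene_id = np.full(n, "", dtype=object)
    scaled = np.full(n, np.nan)
    chrom_arr = np.full(n, "", dtype=object)
    start_arr = np.zeros(n, dtype=int)
    strand_arr = np.full(n, "", dtype=object)
    inserts = np.full(n, "", dtype=object)

    gene_probs = _gene_sampling(bundle, config, genotype)
    a, b = config.five_prime_bias.get(genotype, (5.0, 5.0))
    offsets_cache: dict[tuple[str, int], np.ndarray] = {}

    def snap(valid: np.ndarray, target: np.ndarray) -> np.ndarray:
        """Nearest valid transcript offset for each target offset."""
        j = np.clip(np.searchsorted(valid, target), 0, valid.size - 1)
        jlo = np.clip(j - 1, 0, valid.size - 1)
        return np.where(
            np.abs(valid[j] - target) <= np.abs(valid[jlo] - target), valid[j], valid[jlo]
        )

    def antisense_class(idx: np.ndarray, read_len: int, beta: tuple | None):
        gidx = rng.choice(len(bundle.genes), size=idx.size, p=gene_probs)
        if beta is None:
            s = rng.random(idx.size)
        else:
            s = rng.beta(beta[0], beta[1], size=idx.size)
        for gi in np.unique(gidx):
            gene = bundle.genes[gi]
            key = (gene.id, read_len)
            valid = offsets_cache.get(key)
            if valid is None:
                valid = _valid_offsets(bundle, gene, read_len)
                if valid.size == 0:
                    raise ConfigurationError(
                        f"{gene.id} has no valid {read_len}-nt antisense G-start position"
                    )
                offsets_cache[key] = valid
            sel = np.nonzero(gidx == gi)[0]
            target = np.clip((s[sel] * gene.length).astype(int), read_len - 1, gene.length - 1)
            pick = snap(valid, target)
            rows = idx[sel]
            for r, o in zip(rows, pick):
                o = int(o)
                ins, st, sd = _antisense_read(bundle, gene, o, read_len)
                for _ in range(60):
                    if _unambiguous(ins, config.linker):
                        break
                    s_new = rng.random() if beta is None else rng.beta(*beta)
                    o = int(
                        snap(
                            valid,
                            np.array(
                                [
                                    int(
                                        np.clip(
                                            s_new * gene.length, read_len - 1, gene.length - 1
                                        )
                                    )
                                ]
                            ),
                        )[0]
                    )
                    ins, st, sd = _antisense_read(bundle, gene, o, read_len)
                else:
                    raise ConfigurationError(
                        f"{gene.id}: no unambiguous {read_len}-nt antisense read found"
                    )
                inserts[r] = ins
                start_arr[r] = st
                strand_arr[r] = sd
                scaled[r] = o / gene.length
            gene_id[rows] = gene.id
            chrom_arr[rows] = gene.chrom

    for cname in classes:
        idx = np.nonzero(cls_arr == cname)[0]
        if idx.size == 0:
            continue
        if cname == "22G":
            antisense_class(idx, 22, (a, b))
        elif cname == "26G":
            antisense_class(idx, 26, None)
        elif cname in ("21U", "miRNA"):
            pool = bundle.pirna_loci if cname == "21U" else bundle.mirnas
            loci = [f for f in pool if _unambiguous(bundle.feature_seq(f), config.linker)]
            if not loci:
                raise ConfigurationError(f"no unambiguous {cname} locus in the bundle")
            choice = rng.integers(0, len(loci), size=idx.size)
            for r, li in zip(idx, choice):
                f = loci[li]
                inserts[r] = bundle.feature_seq(f)
                gene_id[r] = f.id
                chrom_arr[r] = f.chrom
                start_arr[r] = f.start
                strand_arr[r] = f.strand
        elif cname == "ncRNA":
            loci = rng.integers(0, len(bundle.ncrnas), size=idx.size)
            for r, li in zip(idx, loci):
                f = bundle.ncrnas[li]
                for _ in range(200):
                    length = int(rng.integers(18, min(27, f.length + 1)))
                    u = int(rng.integers(0, f.length - length + 1))
                    s0 = f.start + u
                    sd = "+" if rng.random() < 0.5 else "-"
                    raw = bundle.sequences[f.chrom][s0 : s0 + length]
                    ins = raw if sd == "+" else revcomp(raw)
                    if _unambiguous(ins, config.linker):
                        break
                else:
                    raise ConfigurationError(f"{f.id}: no unambiguous ncRNA read found")
                inserts[r] = ins
                gene_id[r] = f.id
                chrom_arr[r] = f.chrom
                start_arr[r] = s0
                strand_arr[r] = sd
        elif cname == "other":
            gaps = _intergenic_gaps(bundle, min_len=40)
            if not gaps:
                raise ConfigurationError("no intergenic space for 'other' reads")
            glens = np.array([e - s for _, s, e in gaps], dtype=float)
            gpick = rng.choice(len(gaps), size=idx.size, p=glens / glens.sum())
            for r, gi in zip(idx, gpick):
                chromg, s0, e0 = gaps[gi]
                for _ in range(200):
                    length = int(rng.integers(18, 29))
                    u = int(rng.integers(s0, e0 - length))
                    ins = bundle.sequences[chromg][u : u + length]
                    if _unambiguous(ins, config.linker):
                        break
                else:
                    raise ConfigurationError("no unambiguous intergenic read found")
                inserts[r] = ins
                chrom_arr[r] = chromg
                start_arr[r] = u
                strand_arr[r] = "+"

    read_ids = [f"{name}_{i:06d}" for i in range(n)]
    reads = []
    pad_pool = _NT[rng.integers(0, 4, size=4 * n + 64)].tobytes().decode()
    pp = 0
    for i in range(n):
        full = config.barcode + inserts[i] + config.linker
        if len(full) < config.read_length:
            need = config.read_length - len(full)
            full += pad_pool[pp : pp + need]
            pp += need
            if pp > len(pad_pool) - 40:
                pad_pool = _NT[rng.integers(0, 4, size=4 * n + 64)].tobytes().decode()
                pp = 0
        reads.append((read_ids[i], full))

    if config.error_rate > 0:
        nt = "ACGT"
        for i in range(n):
            rid, s = reads[i]
            hits = np.nonzero(rng.random(len(s)) < config.error_rate)[0]
            if hits.size:
                sl = list(s)
                for h in hits:
                    sl[h] = nt[(nt.index(sl[h]) + int(rng.integers(1, 4))) % 4]
                reads[i] = (rid, "".join(sl))

    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "class": cls_arr,
            "gene_id": gene_id,
            "scaled_pos": scaled,
            "chrom": chrom_arr,
            "start": start_arr,
            "strand": strand_arr,
            "insert": inserts,
            "genotype": genotype,
        }
    )
    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for rid, s in reads:
                fh.write(f"@{rid}\n{s}\n+\n{'I' * len(s)}\n")
    if out_truth is not None:
        truth.to_csv(out_truth, sep="\t", index=False)
    return reads, truth


def _intergenic_gaps(bundle: GenomeBundle, min_len: int = 40):
    """Maximal intervals not covered by any annotated feature."""
    gaps = []
    for chrom, seq in bundle.sequences.items():
        feats = sorted(
            (f for f in bundle.all_features() if f.chrom == chrom), key=lambda f: f.start
        )
        cur = 0
        for f in feats:
            if f.start - cur >= min_len:
                gaps.append((chrom, cur, f.start))
            cur = max(cur, f.end)
        if len(seq) - cur >= min_len:
            gaps.append((chrom, cur, len(seq)))
    return gaps


# --------------------------------------------------------------- count tables


def simulate_count_table(
    bundle_or_genes,
    n_reps: int,
    dispersion: float,
    depleted_genes: dict | None = None,
    seed: int = 0,
    mu=200.0,
):
    """Replicate NB count tables for WT and MUT genotypes.

    Counts are NB with mean mu (scalar or per-gene) and dispersion phi
    (variance = mu + phi mu^2); dispersion 0 gives Poisson counts.  Mutant
    means are multiplied by the planted fold-changes.  Returns
    (wt, mut) DataFrames of shape genes x replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if isinstance(bundle_or_genes, GenomeBundle):
        gene_ids = [g.id for g in bundle_or_genes.genes]
    else:
        gene_ids = list(bundle_or_genes)
    depleted_genes = depleted_genes or {}
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (len(gene_ids),)).copy()
    fc = np.array([depleted_genes.get(g, 1.0) for g in gene_ids])

    def draw(rng, means):
        means = np.repeat(means[:, None], n_reps, axis=1)
        if dispersion == 0:
            return rng.poisson(means)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + means))

    rng_wt = np.random.default_rng(substream_seed(seed, "counts:WT"))
    rng_mut = np.random.default_rng(substream_seed(seed, "counts:MUT"))
    cols = [f"rep{j + 1}" for j in range(n_reps)]
    wt = pd.DataFrame(draw(rng_wt, mu), index=gene_ids, columns=cols)
    mut = pd.DataFrame(draw(rng_mut, mu * fc), index=gene_ids, columns=cols)
    wt.index.name = mut.index.name = "gene_id"
    return wt, mut
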