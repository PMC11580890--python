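"""Self-contained toy datasets with the structure every stage assumes.

The generator emulates the study design at desk scale: a random genome with
boundary motifs planted where the surrogate predictor expects them, two SV
cohorts (one preferentially hitting boundaries, one placed uniformly),
loops anchored near boundaries with promoter-overlapping left anchors, peak
tracks, and an expression table.  Everything is deterministic per seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .genome import DictGenome
from .geometry import PredictorGeometry
from .intervals import Interval
from .io import (
    ensure_dir,
    write_bed,
    write_loops_bedpe,
    write_sv_tsv,
    write_sv_vcf,
)
from .predictor import DEFAULT_BOUNDARY_MOTIF, reverse_complement
from .records import LoopRecord, SVRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class FixtureSpec:
    """Parameters of the toy dataset.

    Defaults are sized so the full pipeline runs in minutes on one CPU
    while preserving the study's qualitative structure: two cohorts of 40
    variants, boundary motifs every few hundred kb, loops under the 900 kb
    window limit, and a mostly-expressed gene set.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_bp: int = 4_000_000
    motif: str = DEFAULT_BOUNDARY_MOTIF
    n_motifs_per_chrom: int = 12
    n_variants_per_cohort: int = 40
    #: DEL/DUP/INV/CPX mixture of generated variants
    type_mix: tuple[float, float, float, float] = (0.55, 0.15, 0.2, 0.1)
    min_sv_len: int = 50
    max_sv_len: int = 50_000
    #: fraction of proband variants placed over a planted boundary motif
    proband_motif_enrichment: float = 0.8
    n_loops: int = 30
    promoter_fraction: float = 0.8
    n_genes: int = 60
    expression_zero_fraction: float = 0.2
    anchor_bp: int = 5_000
    ctcf_flank_bp: int = 200
    exclusion_showcase: bool = False

    def __post_init__(self) -> None:
        if self.chrom_bp < PredictorGeometry().input_span_bp:
            raise ValueError("chrom_bp must be >= the predictor input span")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")


@dataclass
class ToyDataset:
    """In-memory fixture bundle (what the file emitter serialises)."""

    spec: FixtureSpec
    genome: DictGenome
    motifs: list[Interval]  # strand records plant orientation
    variants: list[SVRecord]
    loops: list[LoopRecord]
    genes: list[tuple[str, Interval]]
    gene_exons: list[tuple[str, Interval]]
    asd_gene_exons: list[Interval]
    ctcf_peaks: list[Interval]
    h3k27ac: list[Interval]
    h3k4me1: list[Interval]
    h3k27me3: list[Interval]
    expression: dict[str, float]


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)].copy()


def generate_toy_genome(spec: FixtureSpec) -> tuple[DictGenome, list[Interval]]:
    """Random background with the boundary motif planted at recorded,
    non-overlapping positions on random strands."""
    rng = np.random.default_rng(spec.seed)
    motif = spec.motif
    margin = 700_000  # keep motifs well inside any centred window
    sequences: dict[str, str] = {}
    motifs: list[Interval] = []
    for c in range(spec.n_chroms):
        chrom = f"chr{c + 1}"
        arr = _random_sequence(rng, spec.chrom_bp)
        placed: list[int] = []
        attempts = 0
        # keep chr1's tail motif-free when the showcase plants an N run there
        hi = spec.chrom_bp - (1_000_000 if spec.exclusion_showcase and c == 0 else margin)
        while len(placed) < spec.n_motifs_per_chrom:
            pos = int(rng.integers(margin, hi))
            if any(abs(pos - q) < 50_000 for q in placed):
                attempts += 1
                if attempts > 10_000:
                    raise RuntimeError("cannot place motifs without collisions")
                continue
            placed.append(pos)
        for pos in sorted(placed):
            strand = "+" if rng.random() < 0.5 else "-"
            planted = motif if strand == "+" else reverse_complement(motif)
            arr[pos: pos + len(motif)] = np.frombuffer(planted.encode(), dtype="S1")
            motifs.append(Interval(chrom, pos, pos + len(motif), strand))
        sequences[chrom] = arr.tobytes().decode()
    if spec.exclusion_showcase:
        # a contig too short to host any window, and an N-rich region
        rng2 = np.random.default_rng(spec.seed + 7)
        sequences["chrS"] = _random_sequence(rng2, 10_000).tobytes().decode()
        chrom1 = sequences["chr1"]
        n_start = spec.chrom_bp - 900_000
        sequences["chr1"] = chrom1[:n_start] + "N" * 80_000 + chrom1[n_start + 80_000:]
    genome = DictGenome(sequences)
    # planted motifs can be destroyed if a later plant or N-run overwrote
    # context; the generator spacing rules prevent that by construction
    return genome, motifs


def _draw_length(rng: np.random.Generator, spec: FixtureSpec) -> int:
    lo, hi = np.log(spec.min_sv_len), np.log(spec.max_sv_len)
    return int(np.exp(rng.uniform(lo, hi)))


def _draw_svtype(rng: np.random.Generator, spec: FixtureSpec) -> str:
    return ["DEL", "DUP", "INV", "CPX"][rng.choice(4, p=np.asarray(spec.type_mix))]


def generate_toy_cohort(
    spec: FixtureSpec, motifs: list[Interval], genome: DictGenome
) -> list[SVRecord]:
    """Two cohorts: proband variants preferentially span planted motifs,
    sibling variants are placed uniformly."""
    rng = np.random.default_rng(spec.seed + 1)
    geometry = PredictorGeometry()
    half = geometry.input_span_bp // 2
    variants: list[SVRecord] = []
    chroms = [c for c in genome.chromosomes() if genome.chrom_length(c) >= geometry.input_span_bp]

    def place(cohort: str, index: int, on_motif: bool) -> SVRecord:
        length = _draw_length(rng, spec)
        svtype = _draw_svtype(rng, spec)
        if on_motif and motifs:
            m = motifs[rng.integers(0, len(motifs))]
            # variant covers the motif at a random internal position
            u = rng.uniform(0.2, 0.8)
            start = int(m.midpoint - u * length)
            chrom = m.chrom
        else:
            chrom = chroms[rng.integers(0, len(chroms))]
            mid = int(rng.integers(half + 50_000, genome.chrom_length(chrom) - half - 50_000))
            start = mid - length // 2
        start = max(100, start)
        span = Interval(chrom, start, start + max(length, 1))
        alt = None
        if svtype == "CPX":
            alt_len = max(1, int(length * rng.uniform(0.5, 1.5)))
            alt = _random_sequence(rng, alt_len).tobytes().decode()
        vid = f"{cohort[0]}{index + 1}"
        return SVRecord(
            id=vid, span=span, svtype=svtype,
            subject_id=f"fam{index + 1}_{cohort[0]}", cohort=cohort, alt_sequence=alt,
        )

    for i in range(spec.n_variants_per_cohort):
        on_motif = rng.random() < spec.proband_motif_enrichment
        variants.append(place("proband", i, on_motif))
    for i in range(spec.n_variants_per_cohort):
        variants.append(place("sibling", i, False))

    if spec.exclusion_showcase:
        showcase = [
            SVRecord("x_ins", Interval("chr1", 1_000_000, 1_000_300), "UNSUPPORTED",
                     "famx1", "proband", raw_type="INS"),
            SVRecord("x_abs", Interval("chr1", 1_000_000, 1_700_001), "DEL", "famx2", "proband"),
            SVRecord("x_rel", Interval("chr1", 1_000_000, 1_699_500), "DEL", "famx3", "proband"),
            SVRecord("x_off", Interval("chrS", 4_000, 4_200), "DEL", "famx4", "proband"),
            SVRecord("x_ncon", Interval("chr1", spec.chrom_bp - 860_000, spec.chrom_bp - 859_800),
                     "DEL", "famx5", "proband"),
        ]
        variants.extend(showcase)
    return variants


def generate_toy_annotations(
    spec: FixtureSpec, motifs: list[Interval], genome: DictGenome
) -> dict:
    """Loops near boundary motifs, genes (a fraction with promoters on left
    anchors), expression, and peak tracks."""
    rng = np.random.default_rng(spec.seed + 2)
    loops: list[LoopRecord] = []
    genes: list[tuple[str, Interval]] = []
    gene_exons: list[tuple[str, Interval]] = []
    expression: dict[str, float] = {}
    anchor_w = spec.anchor_bp

    by_chrom: dict[str, list[Interval]] = {}
    for m in motifs:
        by_chrom.setdefault(m.chrom, []).append(m)

    gi = 0
    for k in range(spec.n_loops):
        chrom = f"chr{(k % spec.n_chroms) + 1}"
        ms = by_chrom.get(chrom, [])
        if not ms:
            continue
        m = ms[rng.integers(0, len(ms))]
        left_start = m.midpoint + int(rng.integers(2_000, 20_000))
        left = Interval(chrom, left_start, left_start + anchor_w)
        gap = int(rng.integers(100_000, 750_000))
        right_start = left.end + gap
        if right_start + anchor_w > genome.chrom_length(chrom) - 50_000:
            # place upstream instead, shrinking the gap to stay on-contig
            gap = min(gap, left.start - 60_000 - anchor_w)
            right_start = left.start - gap - anchor_w
            left, right = Interval(chrom, right_start, right_start + anchor_w), left
        else:
            right = Interval(chrom, right_start, right_start + anchor_w)
        loops.append(LoopRecord(left, right, [f"plac{k + 1}"]))

        if rng.random() < spec.promoter_fraction:
            # plant an expressed gene whose promoter overlaps the left anchor
            gi += 1
            name = f"GENE{gi}"
            tss = loops[-1].anchor_left.start + anchor_w // 2
            gene = Interval(chrom, tss, tss + int(rng.integers(5_000, 30_000)), "+")
            genes.append((name, gene))
            expression[name] = float(np.round(np.exp(rng.normal(2.0, 1.0)), 3))

    anchors = [a for lp in loops for a in (lp.anchor_left, lp.anchor_right)]

    def clear_of_anchors(iv: Interval) -> bool:
        probe = Interval(iv.chrom, max(0, iv.start - 3_000), iv.end + 3_000)
        return not any(probe.overlaps(a) for a in anchors)

    while gi < spec.n_genes:
        chrom = f"chr{int(rng.integers(0, spec.n_chroms)) + 1}"
        start = int(rng.integers(100_000, genome.chrom_length(chrom) - 150_000))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = Interval(chrom, start, start + int(rng.integers(5_000, 40_000)), strand)
        if not clear_of_anchors(gene):
            continue
        gi += 1
        name = f"GENE{gi}"
        genes.append((name, gene))
        expression[name] = (
            0.0 if rng.random() < spec.expression_zero_fraction
            else float(np.round(np.exp(rng.normal(2.0, 1.0)), 3))
        )

    for name, gene in genes:
        n_ex = int(rng.integers(2, 5))
        edges = np.sort(rng.integers(0, len(gene), 2 * n_ex))
        for a, b in zip(edges[::2], edges[1::2]):
            if b > a:
                gene_exons.append((name, Interval(gene.chrom, gene.start + int(a), gene.start + int(b), gene.strand)))

    # a handful of disease genes: expressed genes near boundaries
    asd_names = [name for name, _ in genes[: max(3, spec.n_genes // 10)]]
    asd_gene_exons = [iv for name, iv in gene_exons if name in asd_names]

    ctcf_peaks = [
        Interval(m.chrom, max(0, m.start - spec.ctcf_flank_bp), m.end + spec.ctcf_flank_bp)
        for m in motifs
    ]

    def random_peaks(n: int, width_lo: int, width_hi: int, salt: int) -> list[Interval]:
        r = np.random.default_rng(spec.seed + salt)
        out = []
        for _ in range(n):
            chrom = f"chr{int(r.integers(0, spec.n_chroms)) + 1}"
            start = int(r.integers(50_000, genome.chrom_length(chrom) - 60_000))
            out.append(Interval(chrom, start, start + int(r.integers(width_lo, width_hi))))
        return out

    return {
        "loops": loops,
        "genes": genes,
        "gene_exons": gene_exons,
        "asd_gene_exons": asd_gene_exons,
        "expression": expression,
        "ctcf_peaks": ctcf_peaks,
        "h3k27ac": random_peaks(40, 800, 2_500, 3),
        "h3k4me1": random_peaks(40, 800, 2_500, 4),
        "h3k27me3": random_peaks(40, 800, 2_500, 5),
    }


def generate_dataset(spec: FixtureSpec | None = None) -> ToyDataset:
    spec = spec or FixtureSpec()
    genome, motifs = generate_toy_genome(spec)
    variants = generate_toy_cohort(spec, motifs, genome)
    ann = generate_toy_annotations(spec, motifs, genome)
    return ToyDataset(
        spec=spec, genome=genome, motifs=motifs, variants=variants,
        loops=ann["loops"], genes=ann["genes"], gene_exons=ann["gene_exons"],
        asd_gene_exons=ann["asd_gene_exons"], ctcf_peaks=ann["ctcf_peaks"],
        h3k27ac=ann["h3k27ac"], h3k4me1=ann["h3k4me1"], h3k27me3=ann["h3k27me3"],
        expression=ann["expression"],
    )


def write_dataset(data: ToyDataset, outdir: str) -> dict[str, str]:
    """Serialise a toy dataset as FASTA/VCF/BEDPE/BED/TSV plus a manifest."""
    ensure_dir(outdir)
    paths = {name: os.path.join(outdir, fname) for name, fname in {
        "genome": "genome.fa",
        "motifs": "motifs.bed",
        "variants_vcf": "variants.vcf",
        "variants_tsv": "variants.tsv",
        "loops": "loops.bedpe",
        "genes": "genes.bed",
        "gene_exons": "gene_exons.bed",
        "asd_gene_exons": "asd_exons.bed",
        "ctcf_peaks": "ctcf.bed",
        "h3k27ac": "h3k27ac.bed",
        "h3k4me1": "h3k4me1.bed",
        "h3k27me3": "h3k27me3.bed",
        "expression": "expression.tsv",
        "manifest": "manifest.json",
    }.items()}

    with open(paths["genome"], "w") as fh:
        for chrom in data.genome.chromosomes():
            fh.write(f">{chrom}\n")
            seq = data.genome.fetch(chrom, 0, data.genome.chrom_length(chrom))
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")

    write_bed(data.motifs, paths["motifs"], names=[f"motif{i+1}" for i in range(len(data.motifs))])
    contigs = {c: data.genome.chrom_length(c) for c in data.genome.chromosomes()}
    write_sv_vcf(data.variants, paths["variants_vcf"], contigs)
    write_sv_tsv(data.variants, paths["variants_tsv"])
    write_loops_bedpe(data.loops, paths["loops"])
    write_bed([iv for _, iv in data.genes], paths["genes"], names=[n for n, _ in data.genes])
    write_bed([iv for _, iv in data.gene_exons], paths["gene_exons"], names=[n for n, _ in data.gene_exons])
    write_bed(data.asd_gene_exons, paths["asd_gene_exons"])
    write_bed(data.ctcf_peaks, paths["ctcf_peaks"])
    write_bed(data.h3k27ac, paths["h3k27ac"])
    write_bed(data.h3k4me1, paths["h3k4me1"])
    write_bed(data.h3k27me3, paths["h3k27me3"])
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\ttpm\n")
        for gene, tpm in data.expression.items():
            fh.write(f"{gene}\t{tpm}\n")
    manifest = {"spec": asdict(data.spec), "files": {k: os.path.basename(v) for k, v in paths.items() if k != "manifest"}}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
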