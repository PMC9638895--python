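"""Synthetic multi-species genome generator.

Emulates the inputs of the comparative screen without any download: a
reference "chromosome" carrying ncRNA genes of known category, three
related-species genomes holding homologous gene families, planted
stem-loop structures maintained across species by compensatory
substitutions, and unstructured background genes of matched composition.
Everything is emitted in the same formats the real pipeline reads
(GenBank, GFF3, FASTA, MAF) together with per-gene truth labels, so every
downstream module is testable end to end.

Divergence is modelled per species independently on a star-shaped tree;
the most divergent species plays the role of the distant relative.  A
fixed master seed fans out to per-gene child seeds, so any subset of the
data regenerates identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from ._util import revcomp_dna, rna_to_dna, rng_from, stable_seed

__all__ = [
    "PlantedStructure",
    "FamilySpec",
    "TruthLabel",
    "EvolvedHomolog",
    "ScreenSet",
    "sample_structure",
    "sample_ancestor",
    "evolve_family",
    "generate_screenset",
    "score_against_truth",
]

REF_SPECIES = "S_pombe"
DEFAULT_SPECIES_RATES = {
    # shaped like the fission-yeast clade: one clearly more divergent relative
    "S_cryophilus": 0.10,
    "S_octosporus": 0.12,
    "S_japonicus": 0.20,
}
CANONICAL_PAIR_TYPES = ("GC", "CG", "AU", "UA", "GU", "UG")
_ANCESTOR_PAIR_TYPES = ("GC", "CG", "AU", "UA")
_MIN_STEM = 3
_MIN_HAIRPIN = 3


@dataclass(frozen=True)
class PlantedStructure:
    dotbracket: str
    pairs: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        db = list(self.dotbracket)
        for i, j in self.pairs:
            if not (0 <= i < j < len(db)) or db[i] != "(" or db[j] != ")":
                raise ValueError("pairs inconsistent with dot-bracket")
            if j - i - 1 < _MIN_HAIRPIN:
                raise ValueError("hairpin below minimum")

    @property
    def paired_positions(self) -> Set[int]:
        return {p for ij in self.pairs for p in ij}

    def __len__(self) -> int:
        return len(self.dotbracket)


@dataclass(frozen=True)
class FamilySpec:
    """Evolution parameters of one 4-species family."""

    species_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_RATES)
    )
    compensatory_rate: float = 1.0
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name, r in self.species_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {name} outside [0,1]")
        if not 0.0 <= self.compensatory_rate <= 1.0:
            raise ValueError("compensatory_rate outside [0,1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate outside [0,1]")


def sample_structure(length: int, n_stems: int, seed: int) -> PlantedStructure:
    """Random nested-free arrangement of ``n_stems`` stem-loops.

    Stems are 3-10 bp, loops 3-7 nt, placed side by side with random
    spacers; leftover length is spent preferentially on stem growth so the
    paired fraction of a planted gene resembles a real structured ncRNA.
    Infeasible requests raise with the violated bound.
    """
    min_needed = n_stems * (2 * _MIN_STEM + _MIN_HAIRPIN)
    if n_stems < 1 or length < min_needed:
        raise ValueError(
            f"length {length} below minimum {min_needed} for {n_stems} stem(s)"
        )
    rng = rng_from(seed, "structure")
    stems = np.full(n_stems, _MIN_STEM)
    loops = np.full(n_stems, _MIN_HAIRPIN)
    spacers = np.zeros(n_stems + 1, dtype=int)
    budget = length - min_needed
    # spend the leftover length on random stem/loop growth and spacers
    while budget > 0:
        choice = rng.integers(0, 6)
        if choice <= 2:
            k = rng.integers(0, n_stems)
            if stems[k] < 10 and budget >= 2:
                stems[k] += 1
                budget -= 2
                continue
        if choice == 3:
            k = rng.integers(0, n_stems)
            if loops[k] < 7:
                loops[k] += 1
                budget -= 1
                continue
        k = rng.integers(0, n_stems + 1)
        spacers[k] += 1
        budget -= 1
    db: List[str] = []
    pairs: List[Tuple[int, int]] = []
    for k in range(n_stems):
        db.extend("." * spacers[k])
        open_at = len(db)
        db.extend("(" * stems[k])
        db.extend("." * loops[k])
        close_at = len(db)
        db.extend(")" * stems[k])
        for d in range(stems[k]):
            pairs.append((open_at + d, close_at + stems[k] - 1 - d))
    db.extend("." * spacers[n_stems])
    assert len(db) == length
    return PlantedStructure("".join(db), tuple(sorted(pairs)))


def sample_ancestor(structure: PlantedStructure, seed: int) -> str:
    """Random RNA compatible with the structure (all planted pairs canonical)."""
    rng = rng_from(seed, "ancestor")
    seq = [""] * len(structure)
    bases = "ACGU"
    for i in range(len(structure)):
        if structure.dotbracket[i] == ".":
            seq[i] = bases[rng.integers(0, 4)]
    for i, j in structure.pairs:
        pair = _ANCESTOR_PAIR_TYPES[rng.integers(0, len(_ANCESTOR_PAIR_TYPES))]
        seq[i], seq[j] = pair[0], pair[1]
    return "".join(seq)


@dataclass(frozen=True)
class EvolvedHomolog:
    """One species' homolog plus its true alignment to the reference."""

    species: str
    sequence: str        # ungapped, transcript orientation, RNA
    ref_gapped: str      # reference row of the true pairwise alignment
    other_gapped: str

    def __post_init__(self):
        if len(self.ref_gapped) != len(self.other_gapped):
            raise ValueError("gapped rows differ in length")


def _check_compatible(seq: str, structure: PlantedStructure) -> None:
    bad = [
        (i, j)
        for i, j in structure.pairs
        if seq[i] + seq[j] not in CANONICAL_PAIR_TYPES
    ]
    if bad:
        raise ValueError(f"ancestor incompatible with structure at pairs {bad}")


def evolve_family(
    ancestor_seq: str,
    structure: Optional[PlantedStructure],
    spec: FamilySpec,
) -> Dict[str, EvolvedHomolog]:
    """Independently evolve the ancestor into each species.

    Substitution events hit sites at each species' rate.  At a planted
    paired site the partner co-substitutes to restore a canonical pair
    with probability ``compensatory_rate`` (otherwise one side changes
    freely, breaking the pair).  Indels (1-2 nt) occur only outside
    stems.  The true alignment to the ancestor (= reference) is tracked
    column by column.
    """
    if structure is not None:
        if len(ancestor_seq) != len(structure):
            raise ValueError("ancestor length != structure length")
        _check_compatible(ancestor_seq, structure)
        pair_of = {}
        for i, j in structure.pairs:
            pair_of[i] = j
            pair_of[j] = i
    else:
        pair_of = {}
    bases = "ACGU"
    out: Dict[str, EvolvedHomolog] = {}
    for species in sorted(spec.species_rates):
        rate = spec.species_rates[species]
        rng = rng_from(spec.seed, "evolve", species)
        derived = list(ancestor_seq)
        # substitutions: visit each pair once (from its 5' side) and each
        # unpaired site once
        for i in range(len(derived)):
            j = pair_of.get(i)
            if j is not None and j < i:
                continue
            if rng.random() >= rate:
                continue
            if j is None:
                choices = [b for b in bases if b != derived[i]]
                derived[i] = choices[rng.integers(0, 3)]
            else:
                if rng.random() < spec.compensatory_rate:
                    cur = derived[i] + derived[j]
                    alts = [p for p in CANONICAL_PAIR_TYPES if p != cur]
                    new = alts[rng.integers(0, len(alts))]
                    derived[i], derived[j] = new[0], new[1]
                else:
                    side = i if rng.random() < 0.5 else j
                    choices = [b for b in bases if b != derived[side]]
                    derived[side] = choices[rng.integers(0, 3)]
        # indels outside stems, tracked as alignment columns
        ref_row: List[str] = []
        oth_row: List[str] = []
        for i, (anc, der) in enumerate(zip(ancestor_seq, derived)):
            in_stem = i in pair_of
            event = None
            if not in_stem and rng.random() < spec.indel_rate:
                event = "del" if rng.random() < 0.5 else "ins"
            if event == "del":                   # deletion in the species
                ref_row.append(anc)
                oth_row.append("-")
                continue
            ref_row.append(anc)
            oth_row.append(der)
            if event == "ins":                   # insertion after this base
                for _ in range(int(rng.integers(1, 3))):
                    ref_row.append("-")
                    oth_row.append(bases[rng.integers(0, 4)])
        seq = "".join(c for c in oth_row if c != "-")
        out[species] = EvolvedHomolog(
            species=species,
            sequence=seq,
            ref_gapped="".join(ref_row),
            other_gapped="".join(oth_row),
        )
    return out


# ---------------------------------------------------------------------------
# Screen-set generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthLabel:
    gene_id: str
    structured: bool
    category: str
    dotbracket: str = ""
    support: Tuple[str, ...] = ()


@dataclass
class _SynGene:
    gene_id: str
    length: int
    strand: str
    structured: bool
    category: str
    n_exons: int = 1
    sequence: str = ""              # transcript, RNA
    structure: Optional[PlantedStructure] = None
    homologs: Dict[str, EvolvedHomolog] = field(default_factory=dict)
    exons: List[Tuple[int, int]] = field(default_factory=list)   # genomic
    qualifier: str = ""


@dataclass
class ScreenSet:
    out_dir: Path
    genbank_path: Path
    gff3_path: Path
    genome_paths: Dict[str, Path]
    maf_paths: Dict[str, Path]
    truth_path: Path
    labels: Dict[str, TruthLabel]
    chrom_name: str = "syn_chr_I"
    # generator truth: gene_id -> species -> homolog transcript (RNA)
    homolog_truth: Dict[str, Dict[str, str]] = field(default_factory=dict)


_CANONICAL_CYCLE = ("tRNA", "rRNA", "snRNA", "snoRNA")


def generate_screenset(
    n_structured: int = 40,
    n_background: int = 160,
    n_canonical: int = 20,
    spec: Optional[FamilySpec] = None,
    seed: int = 0,
    out_dir=None,
    length_range: Tuple[int, int] = (140, 240),
    minus_strand_frac: float = 0.2,
) -> ScreenSet:
    """Emit a complete synthetic screen input bundle plus truth labels.

    Structured and canonical genes carry planted stems maintained by
    compensatory substitutions; background genes evolve at the same rates
    with ``compensatory_rate = 0`` and no planted structure.  The GenBank
    record also carries antisense CDS features, a UTR overlap and an
    extra overlapping ncRNA so the overlap classifier is exercised.
    """
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = spec or FamilySpec()
    chrom = "syn_chr_I"
    master = rng_from(seed, "screenset")

    genes: List[_SynGene] = []

    def new_genes(n, prefix, structured, categories=None, qualifier_from_cat=False):
        for k in range(n):
            cat = categories[k % len(categories)] if categories else "unconventional"
            gid = f"{prefix}.{k + 1:04d}"
            length = int(master.integers(length_range[0], length_range[1] + 1))
            strand = "-" if master.random() < minus_strand_frac else "+"
            genes.append(
                _SynGene(
                    gene_id=gid,
                    length=length,
                    strand=strand,
                    structured=structured,
                    category=cat,
                    qualifier=cat if qualifier_from_cat else "",
                )
            )

    new_genes(n_structured, "SYNSTR", True)
    new_genes(n_background, "SYNBG", False)
    new_genes(n_canonical, "SYNCAN", True, categories=_CANONICAL_CYCLE,
              qualifier_from_cat=True)
    # two pseudogene-flagged background genes (category bookkeeping only)
    for g in genes:
        if not g.structured and g.category == "unconventional":
            g.category = "pseudogene"
            g.qualifier = "pseudogene"
            break
    # a couple of two-exon genes on the plus strand
    for g in genes:
        if g.strand == "+" and g.length >= 180:
            g.n_exons = 2
            break

    # evolve every gene family
    for g in genes:
        gseed = stable_seed(seed, "gene", g.gene_id)
        if g.structured:
            n_stems = max(1, g.length // 55)
            g.structure = sample_structure(g.length, n_stems, gseed)
            g.sequence = sample_ancestor(g.structure, gseed)
            fam = FamilySpec(
                species_rates=dict(spec.species_rates),
                compensatory_rate=spec.compensatory_rate,
                indel_rate=spec.indel_rate,
                seed=gseed,
            )
        else:
            rng = rng_from(gseed, "bg")
            g.sequence = "".join("ACGU"[i] for i in rng.integers(0, 4, g.length))
            fam = FamilySpec(
                species_rates=dict(spec.species_rates),
                compensatory_rate=0.0,
                indel_rate=spec.indel_rate,
                seed=gseed,
            )
        g.homologs = evolve_family(g.sequence, g.structure, fam)

    # lay out the reference chromosome
    layout = rng_from(seed, "layout")
    ref_parts: List[str] = []
    pos = 0

    def spacer():
        nonlocal pos
        n = int(layout.integers(60, 140))
        ref_parts.append("".join("ACGT"[i] for i in layout.integers(0, 4, n)))
        pos += n

    spacer()
    for g in genes:
        tx_dna = rna_to_dna(g.sequence)
        genomic = tx_dna if g.strand == "+" else revcomp_dna(tx_dna)
        if g.n_exons == 2:
            # split the transcript in two exons with a short intron
            cut = g.length // 2
            intron = "".join("ACGT"[i] for i in layout.integers(0, 4, 45))
            if g.strand == "+":
                genomic = tx_dna[:cut] + intron + tx_dna[cut:]
                g.exons = [(pos, pos + cut), (pos + cut + 45, pos + len(genomic))]
            else:  # not generated (two-exon genes are kept on +), defensive
                raise NotImplementedError("two-exon minus-strand synthesis")
        else:
            g.exons = [(pos, pos + len(genomic))]
        ref_parts.append(genomic)
        pos += len(genomic)
        spacer()
    ref_seq = "".join(ref_parts)

    # other-species chromosomes: homologs in transcript orientation with
    # their own spacers; record each homolog's forward interval
    other_seqs: Dict[str, str] = {}
    other_pos: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for species in sorted(spec.species_rates):
        srng = rng_from(seed, "chrom", species)
        parts: List[str] = []
        cursor = 0
        positions: Dict[str, Tuple[int, int]] = {}

        def sp_spacer():
            nonlocal cursor
            n = int(srng.integers(40, 120))
            parts.append("".join("ACGT"[i] for i in srng.integers(0, 4, n)))
            cursor += n

        sp_spacer()
        for g in genes:
            hom = rna_to_dna(g.homologs[species].sequence)
            positions[g.gene_id] = (cursor, cursor + len(hom))
            parts.append(hom)
            cursor += len(hom)
            sp_spacer()
        other_seqs[species] = "".join(parts)
        other_pos[species] = positions

    # ---- write files -----------------------------------------------------
    genbank_path = out_dir / "genome.gbk"
    gff3_path = out_dir / "models.gff3"
    truth_path = out_dir / "truth.tsv"
    genome_paths = {
        REF_SPECIES: out_dir / f"{REF_SPECIES}.fa",
        **{sp: out_dir / f"{sp}.fa" for sp in sorted(spec.species_rates)},
    }
    maf_paths = {
        sp: out_dir / f"{REF_SPECIES}_vs_{sp}.maf" for sp in sorted(spec.species_rates)
    }

    extra_features = _write_genbank(genbank_path, chrom, ref_seq, genes)
    _write_gff3(gff3_path, chrom, len(ref_seq), genes, extra_features)
    _write_fasta(genome_paths[REF_SPECIES], chrom, ref_seq)
    for sp in sorted(spec.species_rates):
        _write_fasta(genome_paths[sp], f"{sp}_chr", other_seqs[sp])
        _write_maf(
            maf_paths[sp], chrom, len(ref_seq), sp, len(other_seqs[sp]),
            genes, other_pos[sp],
        )

    labels: Dict[str, TruthLabel] = {}
    support = tuple(sorted(spec.species_rates))
    for g in genes:
        labels[g.gene_id] = TruthLabel(
            gene_id=g.gene_id,
            structured=g.structured,
            category=g.category,
            dotbracket=g.structure.dotbracket if g.structure else "",
            support=support,
        )
    for feat in extra_features:
        if feat["type"] == "misc_RNA":
            labels[feat["gene_id"]] = TruthLabel(
                gene_id=feat["gene_id"], structured=False, category="unconventional"
            )
    with open(truth_path, "w") as fh:
        fh.write("gene_id\tstructured\tcategory\tdotbracket\tsupport\n")
        for gid in sorted(labels):
            lab = labels[gid]
            fh.write(
                f"{lab.gene_id}\t{int(lab.structured)}\t{lab.category}\t"
                f"{lab.dotbracket}\t{','.join(lab.support)}\n"
            )
    with open(out_dir / "spec.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "n_structured": n_structured,
                "n_background": n_background,
                "n_canonical": n_canonical,
                "species_rates": dict(spec.species_rates),
                "compensatory_rate": spec.compensatory_rate,
                "indel_rate": spec.indel_rate,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return ScreenSet(
        out_dir=out_dir,
        genbank_path=genbank_path,
        gff3_path=gff3_path,
        genome_paths=genome_paths,
        maf_paths=maf_paths,
        truth_path=truth_path,
        labels=labels,
        chrom_name=chrom,
        homolog_truth={
            g.gene_id: {sp: h.sequence for sp, h in g.homologs.items()}
            for g in genes
        },
    )


def _write_fasta(path: Path, name: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def _write_genbank(path: Path, chrom: str, ref_seq: str, genes: List[_SynGene]):
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
    from Bio import SeqIO

    record = SeqRecord(Seq(ref_seq), id=chrom, name=chrom,
                       description="synthetic reference chromosome")
    record.annotations["molecule_type"] = "DNA"
    extra = []
    for g in genes:
        strand = 1 if g.strand == "+" else -1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in g.exons]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [g.gene_id]}
        if g.qualifier:
            quals["note"] = [g.qualifier]
        record.features.append(SeqFeature(loc, type="misc_RNA", qualifiers=quals))
    # antisense CDS features over the first two plus-strand background genes
    targets = [g for g in genes if not g.structured and g.strand == "+"][:2]
    for t_i, tg in enumerate(targets):
        s, e = tg.exons[0]
        cds_s, cds_e = s + 10, min(e, s + 10 + 90)
        record.features.append(
            SeqFeature(
                SimpleLocation(cds_s, cds_e, strand=-1),
                type="CDS",
                qualifiers={"gene": [f"SYNCDS.{t_i + 1:02d}"]},
            )
        )
        extra.append(
            {"type": "CDS", "gene_id": f"SYNCDS.{t_i + 1:02d}", "start": cds_s,
             "end": cds_e, "strand": "-", "target": tg.gene_id}
        )
    # one overlapping ncRNA feature inside a third background gene
    host = [g for g in genes if not g.structured and g.strand == "+"]
    if len(host) > 2:
        hg = host[2]
        s, e = hg.exons[0]
        ov_s, ov_e = s + 5, s + 5 + max(40, (e - s) // 2)
        record.features.append(
            SeqFeature(
                SimpleLocation(ov_s, ov_e, strand=1),
                type="misc_RNA",
                qualifiers={"gene": ["SYNOVL.0001"]},
            )
        )
        extra.append(
            {"type": "misc_RNA", "gene_id": "SYNOVL.0001", "start": ov_s,
             "end": ov_e, "strand": "+", "target": hg.gene_id}
        )
    # a UTR over a fourth background gene (GFF3 only) and a free-standing CDS
    if len(host) > 3:
        hg = host[3]
        s, e = hg.exons[0]
        extra.append(
            {"type": "five_prime_UTR", "gene_id": "SYNUTR.0001", "start": s,
             "end": s + 30, "strand": "+", "target": hg.gene_id}
        )
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")
    return extra


def _write_gff3(path: Path, chrom: str, chrom_len: int, genes, extra) -> None:
    lines = ["##gff-version 3", f"##sequence-region {chrom} 1 {chrom_len}"]
    for g in genes:
        start = g.exons[0][0] + 1
        end = g.exons[-1][1]
        lines.append(
            f"{chrom}\tsynth\tncRNA_gene\t{start}\t{end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};biotype=ncRNA"
        )
        lines.append(
            f"{chrom}\tsynth\tncRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}.1;Parent={g.gene_id}"
        )
    for i, feat in enumerate(extra):
        if feat["type"] == "CDS":
            gid = feat["gene_id"]
            s, e, st = feat["start"] + 1, feat["end"], feat["strand"]
            lines.append(
                f"{chrom}\tsynth\tgene\t{s}\t{e}\t.\t{st}\t.\tID={gid}"
            )
            lines.append(
                f"{chrom}\tsynth\tmRNA\t{s}\t{e}\t.\t{st}\t.\tID={gid}.1;Parent={gid}"
            )
            lines.append(
                f"{chrom}\tsynth\tCDS\t{s}\t{e}\t.\t{st}\t0\tID={gid}.1.cds;Parent={gid}.1"
            )
        elif feat["type"] == "five_prime_UTR":
            gid = feat["gene_id"]
            s, e, st = feat["start"] + 1, feat["end"], feat["strand"]
            lines.append(
                f"{chrom}\tsynth\tfive_prime_UTR\t{s}\t{e}\t.\t{st}\t.\tID={gid}"
            )
        elif feat["type"] == "misc_RNA":
            gid = feat["gene_id"]
            s, e, st = feat["start"] + 1, feat["end"], feat["strand"]
            lines.append(
                f"{chrom}\tsynth\tncRNA\t{s}\t{e}\t.\t{st}\t.\tID={gid}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_maf(
    path: Path,
    ref_chrom: str,
    ref_src_size: int,
    species: str,
    other_src_size: int,
    genes: Sequence[_SynGene],
    other_positions: Mapping[str, Tuple[int, int]],
) -> None:
    """One block per exon per gene, reference always on the + strand.

    The species row carries the true (generator) alignment; for
    minus-strand reference genes the block is flipped to read forward on
    the reference, so the species row appears on its '-' strand with MAF
    minus-strand start coordinates.
    """
    other_chrom = f"{species}_chr"
    out = ["##maf version=1 scoring=synthetic", ""]
    for g in genes:
        hom = g.homologs[species]
        ref_row = rna_to_dna(hom.ref_gapped)
        oth_row = rna_to_dna(hom.other_gapped)
        fwd_start, fwd_end = other_positions[g.gene_id]
        # split the transcript-space alignment at exon boundaries
        exon_lengths = [e - s for s, e in g.exons]
        if g.strand == "-":
            exon_lengths = exon_lengths[::-1]
        col = 0
        tx_pos = 0
        oth_consumed = 0
        segments = []
        for ex_len in exon_lengths:
            cols = []
            taken = 0
            while taken < ex_len:
                cols.append(col)
                if ref_row[col] != "-":
                    taken += 1
                col += 1
            while col < len(ref_row) and ref_row[col] == "-":
                cols.append(col)
                col += 1
            seg_ref = "".join(ref_row[c] for c in cols)
            seg_oth = "".join(oth_row[c] for c in cols)
            segments.append((tx_pos, seg_ref, seg_oth, oth_consumed))
            tx_pos += ex_len
            oth_consumed += len(seg_oth) - seg_oth.count("-")
        for (tx0, seg_ref, seg_oth, oth0) in segments:
            seg_ref_len = len(seg_ref) - seg_ref.count("-")
            seg_oth_len = len(seg_oth) - seg_oth.count("-")
            if g.strand == "+":
                # transcript position -> genomic: walk exons
                gpos = _tx_to_genomic(g.exons, tx0)
                r_start, r_text, o_text = gpos, seg_ref, seg_oth
                o_strand = "+"
                o_start = fwd_start + oth0
            else:
                # flip to reference-forward
                r_text = revcomp_dna(seg_ref)
                o_text = revcomp_dna(seg_oth)
                tx_end = tx0 + seg_ref_len
                gpos_last = _tx_to_genomic(g.exons, tx_end - 1, minus=True)
                r_start = gpos_last
                o_strand = "-"
                o_start = other_src_size - (fwd_start + oth0 + seg_oth_len)
            out.append("a score=0.000000")
            out.append(
                f"s {REF_SPECIES}.{ref_chrom} {r_start} {seg_ref_len} + "
                f"{ref_src_size} {r_text}"
            )
            out.append(
                f"s {species}.{other_chrom} {o_start} {seg_oth_len} {o_strand} "
                f"{other_src_size} {o_text}"
            )
            out.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(out))


def _tx_to_genomic(exons, tx_pos: int, minus: bool = False) -> int:
    """Genomic coordinate of a transcript position; for minus-strand genes
    returns the coordinate such that the forward block starts there."""
    if not minus:
        remaining = tx_pos
        for s, e in exons:
            if remaining < e - s:
                return s + remaining
            remaining -= e - s
        raise IndexError("transcript position beyond gene")
    # minus strand: transcript pos 0 sits at the last exon's end - 1
    remaining = tx_pos
    for s, e in reversed(exons):
        if remaining < e - s:
            return e - 1 - remaining
        remaining -= e - s
    raise IndexError("transcript position beyond gene")


# ---------------------------------------------------------------------------
# Truth scoring
# ---------------------------------------------------------------------------

def score_against_truth(csg_gene_ids, labels: Mapping[str, TruthLabel]) -> dict:
    """Confusion summary of CSG calls against generator truth."""
    called = set(
        g.gene_id if hasattr(g, "gene_id") else g for g in csg_gene_ids
    )
    unknown = called - set(labels)
    if unknown:
        raise KeyError(f"unlabeled gene(s) in predictions: {sorted(unknown)}")
    tp = fp = fn = tn = 0
    for gid, lab in labels.items():
        hit = gid in called
        if lab.structured and hit:
            tp += 1
        elif lab.structured:
            fn += 1
        elif hit:
            fp += 1
        else:
            tn += 1
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return {
        "TP": tp, "FP": fp, "FN": fn, "TN": tn,
        "recall": recall, "precision": precision,
    }
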