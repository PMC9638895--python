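"""Primary-sequence conservation filter and cross-species family assembly.

Ingests pairwise whole-genome alignments (MAF) of the reference species
against each related species, selects ncRNA genes with at least one
aligned exonic segment of ``min_aligned_len`` (default 50) bases in at
least one species, and assembles per-gene unaligned sequence families
(reference transcript first, then species alphabetically) ready for
multiple alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import AlignIO

from ._util import dna_to_rna, revcomp_dna
from .annotation import NcRNACatalog

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseBlock",
    "AlignedSegment",
    "ConservedGeneSet",
    "Family",
    "read_pairwise_maf",
    "select_conserved_genes",
    "assemble_family",
]

DEFAULT_MIN_ALIGNED_LEN = 50


@dataclass(frozen=True)
class PairwiseBlock:
    """One MAF block, reference row normalized to the forward strand."""

    ref_chrom: str
    ref_start: int              # 0-based, forward strand
    ref_text: str               # gapped
    other_species: str
    other_text: str             # gapped, same length as ref_text
    other_strand: str = "+"
    other_start: int = 0
    other_src_size: int = 0

    def __post_init__(self):
        if len(self.ref_text) != len(self.other_text):
            raise ValueError("ref and other rows differ in length")

    @property
    def ref_len(self) -> int:
        return len(self.ref_text) - self.ref_text.count("-")

    @property
    def ref_interval(self) -> Tuple[int, int]:
        return (self.ref_start, self.ref_start + self.ref_len)


def read_pairwise_maf(maf_source, ref_species: str) -> List[PairwiseBlock]:
    """Read two-row MAF blocks, ref coordinates normalized to + strand.

    Rows belong to the reference if their source name is ``ref_species`` or
    ``ref_species.<chrom>``.  Blocks without a reference row are skipped
    with a warning; blocks with a row count other than two raise.
    """
    blocks: List[PairwiseBlock] = []
    for aln in AlignIO.parse(maf_source, "maf"):
        if len(aln) != 2:
            raise ValueError(f"MAF block with {len(aln)} rows; expected 2")
        ref_row = other_row = None
        for row in aln:
            name = row.id
            if name == ref_species or name.startswith(ref_species + "."):
                ref_row = row
            else:
                other_row = row
        if ref_row is None or other_row is None:
            logger.warning("skipping MAF block without a %s row", ref_species)
            continue
        ref_text = str(ref_row.seq).upper()
        oth_text = str(other_row.seq).upper()
        ref_start = int(ref_row.annotations["start"])
        ref_size = int(ref_row.annotations["size"])
        ref_srcsize = int(ref_row.annotations["srcSize"])
        if ref_size != len(ref_text) - ref_text.count("-"):
            raise ValueError(
                f"MAF size field {ref_size} inconsistent with row text"
            )
        oth_strand = "+" if int(other_row.annotations["strand"]) >= 0 else "-"
        oth_start = int(other_row.annotations["start"])
        oth_srcsize = int(other_row.annotations["srcSize"])
        if int(ref_row.annotations["strand"]) < 0:
            # flip the whole block so the reference reads forward
            ref_text = revcomp_dna(ref_text)
            oth_text = revcomp_dna(oth_text)
            ref_start = ref_srcsize - (ref_start + ref_size)
            oth_size = len(oth_text) - oth_text.count("-")
            oth_start = oth_srcsize - (oth_start + oth_size)
            oth_strand = "+" if oth_strand == "-" else "-"
        chrom = ref_row.id.split(".", 1)[1] if "." in ref_row.id else ref_row.id
        species = other_row.id.split(".", 1)[0]
        blocks.append(
            PairwiseBlock(
                ref_chrom=chrom,
                ref_start=ref_start,
                ref_text=ref_text,
                other_species=species,
                other_text=oth_text,
                other_strand=oth_strand,
                other_start=oth_start,
                other_src_size=oth_srcsize,
            )
        )
    return blocks


@dataclass(frozen=True)
class AlignedSegment:
    """A block clipped to one gene's exons (still in genomic orientation)."""

    species: str
    ref_text: str
    other_text: str
    aligned_len: int            # ungapped reference bases inside exons
    ref_start: int = 0          # genomic coordinate of the first kept ref base
    ref_end: int = 0


@dataclass
class ConservedGeneSet:
    entries: Dict[str, Dict[str, List[AlignedSegment]]] = field(default_factory=dict)
    selected: set = field(default_factory=set)
    min_aligned_len: int = DEFAULT_MIN_ALIGNED_LEN

    def aligned_len(self, gene_id: str, species: str) -> int:
        segs = self.entries.get(gene_id, {}).get(species, [])
        return max((s.aligned_len for s in segs), default=0)

    def supporting_species(self, gene_id: str) -> List[str]:
        return sorted(
            sp
            for sp, segs in self.entries.get(gene_id, {}).items()
            if any(s.aligned_len >= self.min_aligned_len for s in segs)
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tspecies\taligned_len\tselected\n")
            for gene_id in sorted(self.entries):
                for sp in sorted(self.entries[gene_id]):
                    fh.write(
                        f"{gene_id}\t{sp}\t{self.aligned_len(gene_id, sp)}\t"
                        f"{int(gene_id in self.selected)}\n"
                    )


def _clip_block_to_exons(
    block: PairwiseBlock, exons: Sequence[Tuple[int, int]]
) -> Optional[AlignedSegment]:
    """Keep alignment columns whose reference base lies in an exon.

    Insertion (ref-gap) columns are kept only when flanked by kept
    reference positions, so species insertions inside the gene survive the
    clip while intronic or flanking alignment is discarded.
    """
    pos = block.ref_start
    col_pos: List[Optional[int]] = []
    for ch in block.ref_text:
        if ch == "-":
            col_pos.append(None)
        else:
            col_pos.append(pos)
            pos += 1
    exon_iter = sorted(exons)

    def pos_in_exons(p: int) -> bool:
        return any(s <= p < e for s, e in exon_iter)

    keep = [p is not None and pos_in_exons(p) for p in col_pos]
    # rescue insertion columns flanked by kept columns
    prev_kept = False
    flank_left = [False] * len(keep)
    for i, (p, k) in enumerate(zip(col_pos, keep)):
        if p is not None:
            prev_kept = k
        elif prev_kept:
            flank_left[i] = True
    # at the very end of a block there is no right flank to contradict the
    # left one, so a trailing insertion after a kept base stays
    next_kept = True
    for i in range(len(keep) - 1, -1, -1):
        if col_pos[i] is not None:
            next_kept = keep[i]
        elif flank_left[i] and next_kept:
            keep[i] = True
    ref = "".join(c for c, k in zip(block.ref_text, keep) if k)
    oth = "".join(c for c, k in zip(block.other_text, keep) if k)
    aligned = len(ref) - ref.count("-")
    if aligned == 0:
        return None
    kept_pos = [p for p, k in zip(col_pos, keep) if k and p is not None]
    return AlignedSegment(
        block.other_species, ref, oth, aligned,
        ref_start=min(kept_pos), ref_end=max(kept_pos) + 1,
    )


def select_conserved_genes(
    catalog: NcRNACatalog,
    blocks: Iterable[PairwiseBlock],
    min_aligned_len: int = DEFAULT_MIN_ALIGNED_LEN,
) -> ConservedGeneSet:
    """Step [1]: keep genes with >= min_aligned_len exonic bases aligned in
    >= 1 species.  Aligned length is counted per block (genes aligned only
    by shorter segments are excluded, matching the strict "shorter than"
    cutoff: exactly min_aligned_len bases still passes)."""
    out = ConservedGeneSet(min_aligned_len=min_aligned_len)
    block_list = list(blocks)
    for record in catalog:
        per_species: Dict[str, List[AlignedSegment]] = {}
        for block in block_list:
            if block.ref_chrom != record.chrom:
                continue
            b0, b1 = block.ref_interval
            if b1 <= record.start or b0 >= record.end:
                continue
            seg = _clip_block_to_exons(block, record.exons)
            if seg is not None:
                per_species.setdefault(seg.species, []).append(seg)
        if per_species:
            out.entries[record.gene_id] = per_species
        if any(
            seg.aligned_len >= min_aligned_len
            for segs in per_species.values()
            for seg in segs
        ):
            out.selected.add(record.gene_id)
    return out


@dataclass
class Family:
    """Unaligned cross-species family: reference first, 5'->3' RNA."""

    gene_id: str
    members: List[Tuple[str, str]]    # (species, sequence)
    ref_species: str

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError(f"{self.gene_id}: family smaller than 2 members")
        if self.members[0][0] != self.ref_species:
            raise ValueError(f"{self.gene_id}: reference must come first")

    @property
    def ref_sequence(self) -> str:
        return self.members[0][1]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sp, seq in self.members:
                fh.write(f">{self.gene_id}|{sp}\n{seq}\n")


def assemble_family(
    gene_id: str,
    conserved_set: ConservedGeneSet,
    catalog: NcRNACatalog,
    ref_species: str = "S_pombe",
) -> Family:
    """Build the per-gene family from the best aligned segment per species.

    All members are oriented 5'->3' on the gene's transcribed strand and
    written in the RNA alphabet; member order is reference first, then
    species alphabetically.  Species whose retained segment is empty are
    dropped with a warning; a family shrinking below two members raises.
    """
    if gene_id not in conserved_set.selected:
        raise KeyError(f"{gene_id} was not selected by the conservation filter")
    record = catalog[gene_id]
    members: List[Tuple[str, str]] = [(ref_species, record.sequence)]
    for species in conserved_set.supporting_species(gene_id):
        segs = conserved_set.entries[gene_id][species]
        # concatenate non-overlapping segments in transcript order (a gene
        # split over several blocks, e.g. per exon, is re-joined here);
        # among overlapping alternatives the longest-aligned wins
        chosen: List[AlignedSegment] = []
        for seg in sorted(segs, key=lambda s: (-s.aligned_len, s.ref_start)):
            if all(
                seg.ref_end <= c.ref_start or seg.ref_start >= c.ref_end
                for c in chosen
            ):
                chosen.append(seg)
        chosen.sort(key=lambda s: s.ref_start, reverse=record.strand == "-")
        parts = []
        for seg in chosen:
            part = seg.other_text.replace("-", "")
            if record.strand == "-":
                part = revcomp_dna(part)
            parts.append(part)
        seq = "".join(parts)
        if not seq:
            logger.warning("%s: empty %s segment dropped", gene_id, species)
            continue
        members.append((species, dna_to_rna(seq)))
    if len(members) < 2:
        raise ValueError(f"{gene_id}: no species segment survived assembly")
    return Family(gene_id=gene_id, members=members, ref_species=ref_species)
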