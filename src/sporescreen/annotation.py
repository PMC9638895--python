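"""ncRNA catalog construction from genome annotation.

Parses GenBank chromosome records, extracts the ncRNA pool (every feature
typed ``misc_RNA``), assigns each gene to one of six categories
(tRNA / rRNA / snRNA / snoRNA / pseudogene / unconventional), loads
protein-coding gene models from GFF3, and classifies how each ncRNA
overlaps coding features — the basis for selecting CDS-free candidates.

Coordinates are 0-based half-open everywhere inside the package; the
1-based inclusive conventions of GenBank and GFF3 exist only at the I/O
boundary.  Intervals touching end-to-start do not overlap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

from ._util import dna_to_rna, percent

logger = logging.getLogger(__name__)

CATEGORIES = ("tRNA", "rRNA", "snRNA", "snoRNA", "pseudogene", "unconventional")
CANONICAL_CATEGORIES = frozenset({"tRNA", "rRNA", "snRNA", "snoRNA"})

__all__ = [
    "GeneRecord",
    "NcRNACatalog",
    "OverlapClass",
    "GeneModelIndex",
    "parse_genbank_ncrnas",
    "classify_category",
    "load_gene_models",
    "classify_overlap",
    "transcript_coords",
    "CATEGORIES",
    "CANONICAL_CATEGORIES",
]


@dataclass
class GeneRecord:
    """One ncRNA gene: spliced, strand-corrected 5'->3' RNA sequence."""

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    category: str = "unconventional"
    sequence: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if s < 0 or e <= s:
                raise ValueError(f"{self.gene_id}: bad exon interval [{s},{e})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.gene_id}: unknown category {self.category!r}")
        if self.sequence and len(self.sequence) != self.span_length:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"total exon length {self.span_length}"
            )

    @property
    def span_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def transcript_coords(record: GeneRecord) -> np.ndarray:
    """Genomic coordinate of every transcript position (5'->3')."""
    coords = np.concatenate([np.arange(s, e) for s, e in record.exons])
    return coords[::-1].copy() if record.strand == "-" else coords


@dataclass
class NcRNACatalog:
    records: Dict[str, GeneRecord] = field(default_factory=dict)

    def add(self, record: GeneRecord) -> None:
        if record.gene_id in self.records:
            raise ValueError(f"duplicate gene_id {record.gene_id!r}")
        self.records[record.gene_id] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.ordered())

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.records[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def ordered(self) -> List[GeneRecord]:
        """Deterministic order: chrom, start, gene_id."""
        return sorted(
            self.records.values(), key=lambda r: (r.chrom, r.start, r.gene_id)
        )

    @property
    def counts_by_category(self) -> Dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for r in self.records.values():
            counts[r.category] += 1
        return counts

    def merge(self, other: "NcRNACatalog") -> None:
        for r in other.records.values():
            self.add(r)

    # -- I/O ---------------------------------------------------------------

    _TSV_COLUMNS = (
        "gene_id", "chrom", "strand", "start", "end",
        "n_exons", "exons", "category", "overlap_class", "sequence",
    )

    def write_tsv(self, path, overlap_classes: Optional[Mapping[str, "OverlapClass"]] = None) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self._TSV_COLUMNS) + "\n")
            for r in self.ordered():
                oc = ""
                if overlap_classes and r.gene_id in overlap_classes:
                    oc = overlap_classes[r.gene_id].label
                exons = ";".join(f"{s}-{e}" for s, e in r.exons)
                fh.write(
                    "\t".join(
                        [
                            r.gene_id, r.chrom, r.strand, str(r.start), str(r.end),
                            str(len(r.exons)), exons, r.category, oc, r.sequence,
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "NcRNACatalog":
        cat = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != cls._TSV_COLUMNS:
                raise ValueError(f"unexpected catalog header in {path}")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                row = dict(zip(cls._TSV_COLUMNS, f))
                exons = [
                    tuple(int(x) for x in part.split("-"))
                    for part in row["exons"].split(";")
                ]
                cat.add(
                    GeneRecord(
                        gene_id=row["gene_id"],
                        chrom=row["chrom"],
                        strand=row["strand"],
                        exons=exons,
                        category=row["category"],
                        sequence=row["sequence"],
                    )
                )
        return cat

    def summary(self) -> dict:
        counts = self.counts_by_category
        total = len(self)
        canonical = sum(counts[c] for c in CANONICAL_CATEGORIES)
        out = {
            "total": total,
            "counts_by_category": counts,
        }
        if total:
            out["canonical_pct"] = percent(canonical, total)
            out["unconventional_pct"] = percent(total - canonical, total)
        return out

    def write_summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Category assignment
# ---------------------------------------------------------------------------

_QUALIFIER_KEYWORDS = (
    ("snoRNA", ("snorna", "small nucleolar")),
    ("snRNA", ("snrna", "small nuclear")),
    ("tRNA", ("trna", "transfer rna")),
    ("rRNA", ("rrna", "ribosomal rna")),
)

_NAME_PATTERNS = (
    ("tRNA", ("TRNA",)),
    ("rRNA", ("RRNA",)),
    ("snoRNA", ("SNORNA", "SNO")),
    ("snRNA", ("SNRNA", "SNU")),
)


def classify_category(record: GeneRecord, annotation_hints: Mapping[str, str]) -> str:
    """Resolve a gene's category from qualifier hints, then name patterns.

    A pseudogene qualifier wins over everything; conflicting conventional
    hints raise; ``unconventional`` is the fallback.
    """
    hint = (annotation_hints.get(record.gene_id) or "").lower()
    if "pseudogene" in hint:
        return "pseudogene"
    matched = [
        cat
        for cat, keys in _QUALIFIER_KEYWORDS
        if any(k in hint for k in keys)
    ]
    if len(matched) > 1:
        raise ValueError(
            f"{record.gene_id}: conflicting category hints {matched} in {hint!r}"
        )
    if matched:
        return matched[0]
    name = record.gene_id.upper()
    for cat, pats in _NAME_PATTERNS:
        if any(p in name for p in pats):
            return cat
    return "unconventional"


# ---------------------------------------------------------------------------
# GenBank extraction
# ---------------------------------------------------------------------------

def parse_genbank_ncrnas(genbank_source) -> NcRNACatalog:
    """Extract every ``misc_RNA`` feature into an :class:`NcRNACatalog`.

    Multi-exon ``join`` locations are spliced and minus-strand sequences
    reverse-complemented so every record carries its 5'->3' transcript.
    Features lacking a location are skipped with a logged warning; any
    other feature type is ignored.
    """
    import warnings as _warnings

    from Bio import BiopythonParserWarning

    catalog = NcRNACatalog()
    hints: Dict[str, str] = {}
    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always", BiopythonParserWarning)
            seq_records = list(SeqIO.parse(genbank_source, "genbank"))
        for w in caught:
            # truncated records (length/body disagreement) are fatal;
            # cosmetic header quirks are not
            if "Expected sequence length" in str(w.message):
                raise ValueError(str(w.message))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank input: {exc}") from exc
    for rec in seq_records:
        for feat in rec.features:
            if feat.type != "misc_RNA":
                continue
            gene_id = (
                feat.qualifiers.get("gene", [None])[0]
                or feat.qualifiers.get("locus_tag", [None])[0]
                or feat.qualifiers.get("systematic_id", [None])[0]
            )
            if feat.location is None or gene_id is None:
                logger.warning(
                    "skipping misc_RNA feature without %s in %s",
                    "location" if feat.location is None else "identifier",
                    rec.id,
                )
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            exons = sorted(
                (int(part.start), int(part.end)) for part in feat.location.parts
            )
            seq = dna_to_rna(str(feat.extract(rec.seq)))
            gr = GeneRecord(
                gene_id=gene_id,
                chrom=rec.id,
                strand=strand,
                exons=exons,
                sequence=seq,
            )
            hint_text = " ".join(
                " ".join(feat.qualifiers.get(q, []))
                for q in ("note", "product", "ncRNA_class", "standard_name")
            ).strip()
            if hint_text:
                hints[gene_id] = hint_text
            gr.category = classify_category(gr, hints)
            catalog.add(gr)
    return catalog


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_CDS_TYPES = frozenset({"CDS"})
_UTR_TYPES = frozenset({"five_prime_UTR", "three_prime_UTR", "UTR"})
_NCRNA_TYPES = frozenset(
    {"ncRNA", "misc_RNA", "tRNA", "rRNA", "snRNA", "snoRNA", "lnc_RNA",
     "ncRNA_gene", "pseudogenic_transcript"}
)
_STRUCTURAL_TYPES = frozenset(
    {"gene", "mRNA", "exon", "intron", "transcript", "region", "chromosome"}
)


@dataclass(frozen=True)
class ModelFeature:
    chrom: str
    strand: str
    start: int    # 0-based half-open
    end: int
    feature_type: str
    attr_id: str = ""


class GeneModelIndex:
    """Interval-tree index over CDS / UTR / ncRNA features by chrom+strand."""

    def __init__(self):
        self._trees: Dict[Tuple[str, str, str], IntervalTree] = {}
        self.ignored_types: Dict[str, int] = {}

    @staticmethod
    def _group(feature_type: str) -> Optional[str]:
        if feature_type in _CDS_TYPES:
            return "CDS"
        if feature_type in _UTR_TYPES:
            return "UTR"
        if feature_type in _NCRNA_TYPES:
            return "ncRNA"
        return None

    def add(self, feat: ModelFeature) -> None:
        group = self._group(feat.feature_type)
        if group is None:
            if feat.feature_type not in _STRUCTURAL_TYPES:
                self.ignored_types[feat.feature_type] = (
                    self.ignored_types.get(feat.feature_type, 0) + 1
                )
            return
        key = (feat.chrom, feat.strand, group)
        self._trees.setdefault(key, IntervalTree())[feat.start:feat.end] = feat

    def query(
        self,
        chrom: str,
        start: int,
        end: int,
        group: str,
        strand: Optional[str] = None,
    ) -> List[ModelFeature]:
        """Features of a group overlapping [start, end); half-open semantics."""
        hits: List[ModelFeature] = []
        strands = "+-" if strand is None else strand
        for st in strands:
            tree = self._trees.get((chrom, st, group))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(start, end))
        return sorted(hits, key=lambda f: (f.start, f.end, f.attr_id))


def load_gene_models(gff3_source) -> GeneModelIndex:
    """Load a GFF3 stream into an interval-queryable gene-model index.

    GFF3's 1-based inclusive coordinates become 0-based half-open here.
    Unknown feature types are ignored (counted); negative or inverted
    coordinates raise.
    """
    import gffutils

    if hasattr(gff3_source, "read"):
        data, from_string = gff3_source.read(), True
    else:
        text = Path(gff3_source)
        data, from_string = str(text), False
    index = GeneModelIndex()
    try:
        db = gffutils.create_db(
            data,
            dbfn=":memory:",
            from_string=from_string,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return index
    for feat in db.all_features():
        if feat.start < 1 or feat.end < feat.start:
            raise ValueError(
                f"bad GFF3 coordinates {feat.start}..{feat.end} for {feat.id}"
            )
        index.add(
            ModelFeature(
                chrom=feat.seqid,
                strand=feat.strand if feat.strand in "+-" else "+",
                start=feat.start - 1,
                end=feat.end,
                feature_type=feat.featuretype,
                attr_id=feat.id or "",
            )
        )
    for ftype, n in sorted(index.ignored_types.items()):
        logger.info("ignored %d GFF3 features of type %s", n, ftype)
    return index


# ---------------------------------------------------------------------------
# Overlap classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapClass:
    """How an ncRNA gene relates to protein-coding annotation.

    ``antisense_to_cds`` marks any CDS overlap on either strand (either
    disqualifies a CDS-free call); ``cds_free_utr_overlap`` marks genes
    clear of CDS but touching a UTR; ``overlaps_other_ncrna`` is an
    orthogonal flag.
    """

    value: str
    overlaps_other_ncrna: bool = False

    def __post_init__(self):
        if self.value not in ("antisense_to_cds", "cds_free", "cds_free_utr_overlap"):
            raise ValueError(f"unknown overlap class {self.value!r}")

    @property
    def label(self) -> str:
        flag = "+ncRNA_overlap" if self.overlaps_other_ncrna else ""
        return self.value + flag


def classify_overlap(record: GeneRecord, models: GeneModelIndex) -> OverlapClass:
    cds_hit = utr_hit = ncrna_hit = False
    for (s, e) in record.exons:
        if models.query(record.chrom, s, e, "CDS"):
            cds_hit = True
        if models.query(record.chrom, s, e, "UTR"):
            utr_hit = True
        for hit in models.query(record.chrom, s, e, "ncRNA"):
            own = hit.attr_id == record.gene_id or hit.attr_id.startswith(
                record.gene_id + "."
            )
            if not own:
                ncrna_hit = True
    if cds_hit:
        return OverlapClass("antisense_to_cds", ncrna_hit)
    if utr_hit:
        return OverlapClass("cds_free_utr_overlap", ncrna_hit)
    return OverlapClass("cds_free", ncrna_hit)
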