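"""Convenience wiring of the full screen from files to results."""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Tuple

from .annotation import NcRNACatalog, parse_genbank_ncrnas
from .conservation import (
    ConservedGeneSet,
    Family,
    assemble_family,
    read_pairwise_maf,
    select_conserved_genes,
)
from .screen import (
    ClassifierParams,
    MultiAlignment,
    ScreenConfig,
    build_alignment,
    run_screen,
)

__all__ = ["build_families", "build_alignments", "screen_from_files"]


def build_families(
    catalog: NcRNACatalog,
    maf_paths: Mapping[str, object],
    ref_species: str = "S_pombe",
    min_aligned_len: int = 50,
) -> Tuple[ConservedGeneSet, Dict[str, Family]]:
    """MAF ingestion + conservation filter + family assembly for all genes."""
    blocks = []
    for _species, path in sorted(maf_paths.items()):
        blocks.extend(read_pairwise_maf(path, ref_species))
    conserved = select_conserved_genes(catalog, blocks, min_aligned_len)
    families: Dict[str, Family] = {}
    for gene_id in sorted(conserved.selected):
        families[gene_id] = assemble_family(gene_id, conserved, catalog, ref_species)
    return conserved, families


def build_alignments(
    families: Mapping[str, Family], catalog: NcRNACatalog, mode: str = "builtin"
) -> Dict[str, MultiAlignment]:
    return {
        gid: build_alignment(fam, mode=mode, catalog=catalog)
        for gid, fam in sorted(families.items())
    }


def screen_from_files(
    genbank_path,
    maf_paths: Mapping[str, object],
    cfg: Optional[ScreenConfig] = None,
    params: Optional[ClassifierParams] = None,
    ref_species: str = "S_pombe",
):
    """GenBank + MAFs -> (catalog, conserved set, alignments, screen result)."""
    cfg = cfg or ScreenConfig()
    catalog = parse_genbank_ncrnas(str(genbank_path))
    conserved, families = build_families(
        catalog, maf_paths, ref_species, cfg.min_aligned_len
    )
    alignments = build_alignments(families, catalog)
    result = run_screen(catalog, alignments.values(), cfg, params)
    return catalog, conserved, alignments, result
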