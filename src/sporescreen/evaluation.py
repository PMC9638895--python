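"""Shuffle-null evaluation of the screen: false discovery rate, detection
sensitivity on canonical ncRNAs, the cutoff trade-off table, and the
mating-efficiency statistic used to quantify the hyper-mating phenotype.

FDR here is the fraction of input genes still called conserved after
their sequences are randomized; DS is the fraction of canonical ncRNAs
(tRNA/rRNA/snRNA/snoRNA) the screen recovers.  Percentages are rounded
half-up to one decimal only at the report boundary and always travel with
their raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from ._util import percent, rng_from
from .annotation import CANONICAL_CATEGORIES, NcRNACatalog
from .screen import (
    CSG,
    ClassifierParams,
    MultiAlignment,
    ScreenConfig,
    call_csms,
    map_csgs,
    screen_alignment,
)

__all__ = [
    "MatingCounts",
    "EvalReport",
    "randomize_alignment",
    "estimate_fdr",
    "detection_sensitivity",
    "threshold_tradeoff",
    "mating_efficiency",
]


@dataclass(frozen=True)
class MatingCounts:
    zygotes: int
    unmated: int

    def __post_init__(self):
        if self.zygotes < 0 or self.unmated < 0:
            raise ValueError("counts must be non-negative")


def mating_efficiency(counts: MatingCounts) -> float:
    """2Z / (2Z + U): each zygote arises from two mated cells."""
    z, u = counts.zygotes, counts.unmated
    if z + u == 0:
        raise ValueError("mating efficiency undefined for zero cells")
    return 2 * z / (2 * z + u)


def randomize_alignment(
    aln: MultiAlignment, mode: str = "ref_row", seed: int = 0
) -> MultiAlignment:
    """Destroy secondary-structure signal while preserving composition.

    ``ref_row`` permutes the reference row's nucleotides among its non-gap
    positions (gap pattern and all other rows untouched) — the reading of
    the written procedure.  ``columns`` permutes whole alignment columns
    (with the coordinate map), the behaviour of the alignment-shuffling
    tool the procedure cites.  Both are seeded and reproducible.
    """
    rng = rng_from(seed, "randomize", mode, aln.gene_id)
    if mode == "ref_row":
        rows = list(aln.rows)
        sp, text = rows[aln.ref_index]
        chars = [c for c in text if c != "-"]
        perm = rng.permutation(len(chars))
        shuffled = [chars[i] for i in perm]
        it = iter(shuffled)
        new_text = "".join(next(it) if c != "-" else "-" for c in text)
        rows[aln.ref_index] = (sp, new_text)
        return MultiAlignment(
            gene_id=aln.gene_id,
            rows=rows,
            ref_index=aln.ref_index,
            colmap=aln.colmap.copy(),
        )
    if mode == "columns":
        perm = rng.permutation(aln.n_cols)
        rows = [(sp, "".join(text[c] for c in perm)) for sp, text in aln.rows]
        return MultiAlignment(
            gene_id=aln.gene_id,
            rows=rows,
            ref_index=aln.ref_index,
            colmap=aln.colmap[perm].copy(),
        )
    raise ValueError(f"unknown randomization mode {mode!r}")


@dataclass
class EvalReport:
    fdr: Optional[float] = None
    fdr_counts: Tuple[int, int] = (0, 0)
    ds: Optional[float] = None
    ds_counts: Tuple[int, int] = (0, 0)
    per_cutoff: List[dict] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "fdr_pct": self.fdr,
            "fdr_counts": list(self.fdr_counts),
            "ds_pct": self.ds,
            "ds_counts": list(self.ds_counts),
            "per_cutoff": self.per_cutoff,
        }


def fdr_from_counts(positives_after_shuffle: int, n_input_genes: int) -> float:
    """The pure ratio contract: 100 * positives / input genes, one decimal."""
    if n_input_genes == 0:
        raise ValueError("FDR undefined with zero input genes")
    return percent(positives_after_shuffle, n_input_genes)


def ds_from_counts(canonical_recovered: int, canonical_total: int) -> float:
    if canonical_total == 0:
        raise ValueError("DS undefined without canonical genes")
    return percent(canonical_recovered, canonical_total)


def estimate_fdr(
    alignments: Iterable[MultiAlignment],
    catalog: NcRNACatalog,
    cfg: ScreenConfig,
    params: ClassifierParams,
    seed: int = 0,
    mode: str = "ref_row",
    repeats: int = 1,
) -> Tuple[float, Tuple[int, int]]:
    """Shuffle every gene's alignment, re-run the full screen (window ->
    CSM -> CSG re-calling), and report the fraction of input genes still
    called conserved.

    One shuffle per gene by default; ``repeats`` averages the positive
    count over several independent shuffles.
    """
    alns = list(alignments)
    if not alns:
        raise ValueError("FDR undefined with zero input genes")
    pos_counts = []
    for r in range(repeats):
        scored = []
        for aln in alns:
            shuffled = randomize_alignment(aln, mode=mode, seed=seed * 1000 + r)
            scored.extend(screen_alignment(shuffled, cfg, params))
        csms = call_csms(scored, cfg)
        csgs = map_csgs(csms, catalog)
        pos_counts.append(len(csgs))
    positives = int(round(float(np.mean(pos_counts))))
    return fdr_from_counts(positives, len(alns)), (positives, len(alns))


def detection_sensitivity(
    csgs: Iterable, catalog: NcRNACatalog
) -> Tuple[float, Tuple[int, int]]:
    """Fraction of the catalog's canonical ncRNAs recovered as CSGs."""
    canonical = {
        r.gene_id for r in catalog if r.category in CANONICAL_CATEGORIES
    }
    if not canonical:
        raise ValueError("no canonical (tRNA/rRNA/snRNA/snoRNA) genes in catalog")
    called = {getattr(g, "gene_id", g) for g in csgs}
    recovered = len(canonical & called)
    return ds_from_counts(recovered, len(canonical)), (recovered, len(canonical))


def threshold_tradeoff(
    real_max_p: Mapping[str, float],
    shuffled_max_p: Mapping[str, float],
    canonical_ids: Set[str],
    cutoffs: Sequence[float] = (0.5, 0.9),
) -> List[dict]:
    """FDR/DS at several selection thresholds from per-gene max-P lists.

    Computed once from the stored probabilities (no re-screening); rows
    are emitted for both comparator semantics — the strict ``P > cutoff``
    used by the default screen and the inclusive ``P >= cutoff`` used when
    quoting raised thresholds — and ordered by cutoff.
    """
    if len(cutoffs) == 0:
        raise ValueError("empty cutoff list")
    n_input = len(shuffled_max_p)
    canon_present = sorted(canonical_ids & set(real_max_p))
    rows = []
    for cutoff in sorted(cutoffs):
        for comparator in (">", ">="):
            if comparator == ">":
                passes = lambda p: p > cutoff
            else:
                passes = lambda p: p >= cutoff
            shuf_pos = sum(1 for p in shuffled_max_p.values() if passes(p))
            ds_pos = sum(1 for g in canon_present if passes(real_max_p[g]))
            row = {
                "cutoff": cutoff,
                "comparator": comparator,
                "fdr_pct": percent(shuf_pos, n_input) if n_input else None,
                "fdr_counts": [shuf_pos, n_input],
                "ds_pct": percent(ds_pos, len(canon_present))
                if canon_present
                else None,
                "ds_counts": [ds_pos, len(canon_present)],
            }
            rows.append(row)
    return rows
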