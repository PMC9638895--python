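"""Windowed structure screen: align families, digest into 120-column
windows with 80-column overlap, score each window on the four criteria the
classifier weighs (thermodynamic z, structure conservation index, mean
pairwise identity, row count), call conserved secondary structure motifs
(CSMs) by fusing significant windows, and map them onto genes (CSGs).

The window classifier is a calibrated logistic decision function over the
four criteria; its probabilities are therefore on the package's own
calibrated scale, not on the scale of any externally trained model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import Align, AlignIO

from ._util import stable_seed
from .annotation import NcRNACatalog, transcript_coords
from .conservation import Family
from . import thermo
from .thermo import EnergyModel, SIMPLE_MODEL

logger = logging.getLogger(__name__)

__all__ = [
    "MultiAlignment",
    "AlignmentWindow",
    "WindowScore",
    "ScoredWindow",
    "CSM",
    "CSG",
    "ScreenConfig",
    "ClassifierParams",
    "build_alignment",
    "window_alignment",
    "filter_window",
    "score_window",
    "classify_structural",
    "calibrate_classifier",
    "call_csms",
    "map_csgs",
    "run_screen",
    "screen_alignment",
    "default_classifier",
]


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class MultiAlignment:
    """Gapped multi-species alignment with a reference coordinate map.

    ``colmap[c]`` is the genomic coordinate of the reference base in
    column ``c`` (or -1 for reference-gap columns).
    """

    gene_id: str
    rows: List[Tuple[str, str]]          # (species, gapped text)
    ref_index: int = 0
    colmap: Optional[np.ndarray] = None

    def __post_init__(self):
        lengths = {len(t) for _, t in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: ragged alignment rows")
        if self.colmap is None:
            n = len(self.rows[0][1]) if self.rows else 0
            self.colmap = np.full(n, -1, dtype=np.int64)
            ref = self.rows[self.ref_index][1]
            pos = 0
            for c, ch in enumerate(ref):
                if ch != "-":
                    self.colmap[c] = pos
                    pos += 1
        if len(self.colmap) != len(self.rows[0][1]):
            raise ValueError(f"{self.gene_id}: colmap length mismatch")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def texts(self) -> List[str]:
        return [t for _, t in self.rows]

    @property
    def species(self) -> List[str]:
        return [s for s, _ in self.rows]

    @property
    def ref_species(self) -> str:
        return self.rows[self.ref_index][0]

    def ungapped_ref(self) -> str:
        return self.rows[self.ref_index][1].replace("-", "")


# ---------------------------------------------------------------------------
# build_alignment: reference-anchored star alignment (builtin) or ingestion
# ---------------------------------------------------------------------------

def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


def _pair_align(ref: str, other: str) -> Tuple[str, str]:
    aln = _pairwise_aligner().align(ref, other)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


def build_alignment(
    family: Family,
    mode: str = "builtin",
    external_path=None,
    external_format: str = "clustal",
    catalog: Optional[NcRNACatalog] = None,
) -> MultiAlignment:
    """Multiple alignment of a family.

    ``builtin`` aligns every member globally to the reference (affine gaps)
    and merges the pairwise alignments on reference coordinates — a
    reference-anchored star alignment, deterministic by construction.
    ``external`` ingests a CLUSTAL/FASTA alignment and validates that its
    ungapped rows reproduce the family sequences.
    """
    if mode == "external":
        aln = AlignIO.read(external_path, external_format)
        by_seq = {seq.replace("-", ""): None for _, seq in family.members}
        rows: List[Tuple[str, str]] = []
        family_map = {sp: seq for sp, seq in family.members}
        for rec in aln:
            sp = rec.id.split("|")[-1]
            text = str(rec.seq).upper().replace("T", "U")
            if sp not in family_map:
                raise ValueError(f"external alignment row {rec.id!r} not in family")
            if text.replace("-", "") != family_map[sp]:
                raise ValueError(
                    f"external alignment row {rec.id!r} does not match the "
                    f"family sequence for {sp}"
                )
            rows.append((sp, text))
        order = {sp: i for i, (sp, _) in enumerate(family.members)}
        rows.sort(key=lambda r: order[r[0]])
    elif mode == "builtin":
        ref_sp, ref_seq = family.members[0]
        others = family.members[1:]
        L = len(ref_seq)
        # per-member: gap runs inserted before each ref position (L+1 slots)
        inserts = np.zeros((len(others), L + 1), dtype=int)
        aligned_rows: List[Tuple[str, str]] = []
        for m, (sp, seq) in enumerate(others):
            a_ref, a_oth = _pair_align(ref_seq, seq)
            aligned_rows.append((a_ref, a_oth))
            p = 0
            run = 0
            for ch in a_ref:
                if ch == "-":
                    run += 1
                else:
                    inserts[m, p] = run
                    run = 0
                    p += 1
            inserts[m, L] = run
        max_ins = inserts.max(axis=0) if others else np.zeros(L + 1, dtype=int)

        def lay_out(a_ref: str, a_oth: str, member: int) -> str:
            out = []
            p = 0
            buf = []
            for rc, oc in zip(a_ref, a_oth):
                if rc == "-":
                    buf.append(oc)
                else:
                    out.append("".join(buf) + "-" * (max_ins[p] - len(buf)))
                    buf = []
                    out.append(oc)
                    p += 1
            out.append("".join(buf) + "-" * (max_ins[L] - len(buf)))
            return "".join(out)

        ref_text_parts = []
        for p in range(L):
            ref_text_parts.append("-" * max_ins[p])
            ref_text_parts.append(ref_seq[p])
        ref_text_parts.append("-" * max_ins[L])
        rows = [(ref_sp, "".join(ref_text_parts))]
        for m, (sp, _) in enumerate(others):
            a_ref, a_oth = aligned_rows[m]
            rows.append((sp, lay_out(a_ref, a_oth, m)))
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    colmap = None
    if catalog is not None and family.gene_id in catalog:
        coords = transcript_coords(catalog[family.gene_id])
        ref_text = rows[0][1]
        colmap = np.full(len(ref_text), -1, dtype=np.int64)
        pos = 0
        for c, ch in enumerate(ref_text):
            if ch != "-":
                colmap[c] = coords[pos]
                pos += 1
    return MultiAlignment(gene_id=family.gene_id, rows=rows, ref_index=0, colmap=colmap)


# ---------------------------------------------------------------------------
# Configuration and windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenConfig:
    """All screen thresholds in one place.

    Window geometry follows the 120-column / 80-column-overlap digestion
    (step = 40); significance is the strict ``P > p_cutoff``; only the
    forward orientation of alignments is ever evaluated.
    """

    window_len: int = 120
    window_overlap: int = 80
    min_aligned_len: int = 50
    p_cutoff: float = 0.5
    forward_only: bool = True
    max_row_gap_frac: float = 0.25
    min_rows: int = 2
    n_shuffles: int = 20
    seed: int = 0
    merge_gap: int = 0
    covariance_bonus: float = 2.0
    inconsistency_penalty: float = 1.0
    model: EnergyModel = SIMPLE_MODEL

    def __post_init__(self):
        if not (0 < self.window_overlap < self.window_len):
            raise ValueError("need 0 < overlap < window_len")
        if not (0.0 <= self.p_cutoff <= 1.0):
            raise ValueError("p_cutoff must lie in [0, 1]")

    @property
    def step(self) -> int:
        return self.window_len - self.window_overlap

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["model"] = {"mode": self.model.mode, "min_hairpin": self.model.min_hairpin}
        return d


@dataclass
class AlignmentWindow:
    """A [col_start, col_end) slice of a MultiAlignment.

    ``row_indices`` lists the rows surviving the gap filter (all rows for a
    freshly cut window).
    """

    parent: MultiAlignment
    col_start: int
    col_end: int
    row_indices: List[int] = field(default_factory=list)

    def __post_init__(self):
        if self.col_end - self.col_start > self.parent.n_cols:
            raise ValueError("window longer than alignment")
        if not self.row_indices:
            self.row_indices = list(range(len(self.parent.rows)))

    @property
    def n_cols(self) -> int:
        return self.col_end - self.col_start

    def row_text(self, idx: int) -> str:
        return self.parent.rows[idx][1][self.col_start:self.col_end]

    @property
    def texts(self) -> List[str]:
        return [self.row_text(i) for i in self.row_indices]

    @property
    def species(self) -> List[str]:
        return [self.parent.rows[i][0] for i in self.row_indices]

    @property
    def ref_interval(self) -> Tuple[int, int]:
        cm = self.parent.colmap[self.col_start:self.col_end]
        coords = cm[cm >= 0]
        if coords.size == 0:
            return (0, 0)
        return (int(coords.min()), int(coords.max()) + 1)


def window_alignment(aln: MultiAlignment, cfg: ScreenConfig) -> List[AlignmentWindow]:
    """Digest an alignment into fixed-length windows.

    Regular windows start every ``step`` columns; alignments shorter than
    ``window_len`` give one full-length window when at least
    ``min_aligned_len`` columns exist; a final end-anchored window covers
    any trailing columns the regular grid would miss.
    """
    L = aln.n_cols
    if L < cfg.window_len:
        if L >= cfg.min_aligned_len:
            return [AlignmentWindow(aln, 0, L)]
        return []
    windows = []
    s = 0
    while s + cfg.window_len <= L:
        windows.append(AlignmentWindow(aln, s, s + cfg.window_len))
        s += cfg.step
    if windows[-1].col_end < L:
        windows.append(AlignmentWindow(aln, L - cfg.window_len, L))
    return windows


def filter_window(
    window: AlignmentWindow, cfg: ScreenConfig
) -> Optional[AlignmentWindow]:
    """Drop gappy rows; reject windows that lose the reference, fall below
    ``min_rows`` rows, or retain fewer than ``min_aligned_len`` ungapped
    reference bases."""
    survivors = []
    for idx in window.row_indices:
        text = window.row_text(idx)
        if text.count("-") / len(text) <= cfg.max_row_gap_frac:
            survivors.append(idx)
    if window.parent.ref_index not in survivors:
        return None
    if len(survivors) < cfg.min_rows:
        return None
    ref_text = window.row_text(window.parent.ref_index)
    if len(ref_text) - ref_text.count("-") < cfg.min_aligned_len:
        return None
    return AlignmentWindow(
        window.parent, window.col_start, window.col_end, row_indices=survivors
    )


# ---------------------------------------------------------------------------
# Window scoring and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowScore:
    z_mean: float
    sci: float
    mpi: float
    n_seq: int
    p: float

    @property
    def features(self) -> np.ndarray:
        return np.array([self.z_mean, self.sci, self.mpi, self.n_seq / 4.0])


@dataclass
class ScoredWindow:
    window: AlignmentWindow
    score: WindowScore

    @property
    def gene_id(self) -> str:
        return self.window.parent.gene_id

    @property
    def ref_interval(self) -> Tuple[int, int]:
        return self.window.ref_interval

    @property
    def supporting_species(self) -> Set[str]:
        ref = self.window.parent.ref_species
        return {sp for sp in self.window.species if sp != ref}


def mean_pairwise_identity(texts: Sequence[str]) -> float:
    """Mean over row pairs of identical columns / non-double-gap columns."""
    vals = []
    for a_i in range(len(texts)):
        for b_i in range(a_i + 1, len(texts)):
            a, b = texts[a_i], texts[b_i]
            comparable = ident = 0
            for x, y in zip(a, b):
                if x == "-" and y == "-":
                    continue
                comparable += 1
                if x == y:
                    ident += 1
            vals.append(ident / comparable if comparable else 0.0)
    return float(np.mean(vals)) if vals else 0.0


@dataclass(frozen=True)
class ClassifierParams:
    """Calibrated logistic decision function over (z_mean, sci, mpi, n/4)."""

    weights: Tuple[float, float, float, float]
    bias: float
    provenance: str = ""

    def __post_init__(self):
        arr = np.array(self.weights + (self.bias,))
        if not np.all(np.isfinite(arr)):
            raise ValueError("classifier parameters must be finite")

    def to_json(self) -> dict:
        return {
            "weights": list(self.weights),
            "bias": self.bias,
            "provenance": self.provenance,
        }

    @classmethod
    def from_json(cls, d: Mapping) -> "ClassifierParams":
        return cls(tuple(d["weights"]), float(d["bias"]), d.get("provenance", ""))


def default_classifier() -> ClassifierParams:
    """The calibration artifact shipped with the package."""
    text = resources.files("sporescreen.data").joinpath(
        "default_classifier.json"
    ).read_text()
    return ClassifierParams.from_json(json.loads(text))


def classify_structural(features, params: Optional[ClassifierParams]) -> float:
    """RNA-class probability P in [0, 1] via the calibrated logistic."""
    if params is None:
        raise ValueError("classifier parameters are not calibrated")
    if isinstance(features, WindowScore):
        x = features.features
    else:
        x = np.asarray(features, dtype=float)
    z = float(np.dot(params.weights, x) + params.bias)
    return float(1.0 / (1.0 + np.exp(-z)))


def calibrate_classifier(
    positive_features: Sequence[Sequence[float]],
    negative_features: Sequence[Sequence[float]],
    seed: int = 0,
) -> Tuple[ClassifierParams, dict]:
    """Fit the logistic decision function on labelled window features.

    Deterministic (lbfgs); returns the parameters plus a calibration report
    with training error rates and class separation.
    """
    from sklearn.linear_model import LogisticRegression

    pos = np.asarray(positive_features, dtype=float)
    neg = np.asarray(negative_features, dtype=float)
    if len(pos) < 50 or len(neg) < 50:
        raise ValueError("calibration needs >= 50 examples per class")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    clf = LogisticRegression(
        C=10.0, solver="lbfgs", max_iter=5000, tol=1e-10, random_state=seed
    )
    clf.fit(X, y)
    params = ClassifierParams(
        tuple(float(w) for w in clf.coef_[0]),
        float(clf.intercept_[0]),
        provenance=f"calibrate_classifier(seed={seed}, n_pos={len(pos)}, n_neg={len(neg)})",
    )
    p = clf.predict_proba(X)[:, 1]
    report = {
        "n_pos": int(len(pos)),
        "n_neg": int(len(neg)),
        "train_error": float(np.mean((p > 0.5) != y)),
        "false_positive_rate": float(np.mean(p[y == 0] > 0.5)),
        "false_negative_rate": float(np.mean(p[y == 1] <= 0.5)),
        "median_p_pos": float(np.median(p[y == 1])),
        "median_p_neg": float(np.median(p[y == 0])),
    }
    return params, report


def score_window(
    window: AlignmentWindow,
    cfg: ScreenConfig,
    params: Optional[ClassifierParams],
) -> WindowScore:
    """The four classifier criteria plus P for one filtered window.

    Per-row z-scores use child seeds derived from the screen seed and the
    window's identity, so rescoring the same inputs is bit-reproducible.
    Only the forward orientation is evaluated.
    """
    texts = window.texts
    zs = []
    for sp, text in zip(window.species, texts):
        seq = text.replace("-", "")
        seed = stable_seed(cfg.seed, window.parent.gene_id, window.col_start, sp)
        zs.append(
            thermo.shuffle_zscore(seq, cfg.model, n_shuffles=cfg.n_shuffles, seed=seed)
        )
    z_mean = float(np.mean(zs))
    sci_val = thermo.sci(
        texts, cfg.model, cfg.covariance_bonus, cfg.inconsistency_penalty
    )
    mpi = mean_pairwise_identity(texts)
    score = WindowScore(z_mean, sci_val, mpi, len(texts), p=0.0)
    p = classify_structural(score, params) if params is not None else 0.0
    return replace(score, p=p)


# ---------------------------------------------------------------------------
# CSM / CSG calling
# ---------------------------------------------------------------------------

@dataclass
class CSM:
    """Conserved secondary structure motif: fused significant windows."""

    gene_id: str
    ref_interval: Tuple[int, int]
    member_windows: List[ScoredWindow]
    max_p: float
    supporting_species: Set[str]

    @property
    def length(self) -> int:
        return self.ref_interval[1] - self.ref_interval[0]


@dataclass
class CSG:
    """Gene carrying >= 1 CSM supported by >= 1 non-reference species."""

    gene_id: str
    csms: List[CSM]
    n_support_species: int

    @property
    def supporting_species(self) -> Set[str]:
        out: Set[str] = set()
        for c in self.csms:
            out |= c.supporting_species
        return out

    @property
    def max_p(self) -> float:
        return max(c.max_p for c in self.csms)


def call_csms(scored: Iterable[ScoredWindow], cfg: ScreenConfig) -> List[CSM]:
    """Fuse significant windows (strict P > cutoff) of a gene whose
    reference projections overlap or abut (merge gap defaults to 0)."""
    by_gene: Dict[str, List[ScoredWindow]] = {}
    for sw in scored:
        if sw.score.p > cfg.p_cutoff:
            by_gene.setdefault(sw.gene_id, []).append(sw)
    csms: List[CSM] = []
    for gene_id in sorted(by_gene):
        wins = sorted(by_gene[gene_id], key=lambda w: w.ref_interval)
        cluster: List[ScoredWindow] = []
        cur_end = None
        for w in wins:
            s, e = w.ref_interval
            if cluster and s > cur_end + cfg.merge_gap:
                csms.append(_make_csm(gene_id, cluster))
                cluster = []
                cur_end = None
            cluster.append(w)
            cur_end = e if cur_end is None else max(cur_end, e)
        if cluster:
            csms.append(_make_csm(gene_id, cluster))
    return csms


def _make_csm(gene_id: str, cluster: List[ScoredWindow]) -> CSM:
    start = min(w.ref_interval[0] for w in cluster)
    end = max(w.ref_interval[1] for w in cluster)
    species: Set[str] = set()
    for w in cluster:
        species |= w.supporting_species
    return CSM(
        gene_id=gene_id,
        ref_interval=(start, end),
        member_windows=cluster,
        max_p=max(w.score.p for w in cluster),
        supporting_species=species,
    )


def map_csgs(csms: Iterable[CSM], catalog: NcRNACatalog) -> List[CSG]:
    """One CSG per gene owning a CSM with non-reference species support."""
    by_gene: Dict[str, List[CSM]] = {}
    for csm in csms:
        if csm.gene_id not in catalog:
            raise KeyError(f"CSM references unknown gene {csm.gene_id!r}")
        by_gene.setdefault(csm.gene_id, []).append(csm)
    csgs = []
    for gene_id in sorted(by_gene):
        gene_csms = [c for c in by_gene[gene_id] if c.supporting_species]
        if not gene_csms:
            continue
        support: Set[str] = set()
        for c in gene_csms:
            support |= c.supporting_species
        csgs.append(CSG(gene_id=gene_id, csms=gene_csms, n_support_species=len(support)))
    return csgs


# ---------------------------------------------------------------------------
# End-to-end screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    windows: List[ScoredWindow]
    csms: List[CSM]
    csgs: List[CSG]
    manifest: dict

    @property
    def csg_gene_ids(self) -> Set[str]:
        return {g.gene_id for g in self.csgs}

    def max_p_by_gene(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for sw in self.windows:
            g = sw.gene_id
            out[g] = max(out.get(g, 0.0), sw.score.p)
        return out


def screen_alignment(
    aln: MultiAlignment, cfg: ScreenConfig, params: ClassifierParams
) -> List[ScoredWindow]:
    """Window, filter and score one alignment (forward orientation only)."""
    scored = []
    for window in window_alignment(aln, cfg):
        kept = filter_window(window, cfg)
        if kept is None:
            continue
        try:
            score = score_window(kept, cfg, params)
        except Exception as exc:
            raise RuntimeError(
                f"scoring failed for {aln.gene_id} window "
                f"[{window.col_start},{window.col_end}): {exc}"
            ) from exc
        scored.append(ScoredWindow(kept, score))
    return scored


def run_screen(
    catalog: NcRNACatalog,
    alignments: Iterable[MultiAlignment],
    cfg: ScreenConfig,
    params: Optional[ClassifierParams] = None,
) -> ScreenResult:
    """Steps [2]-[5] end to end, deterministic given the config seed."""
    if params is None:
        params = default_classifier()
    all_scored: List[ScoredWindow] = []
    digest = hashlib.sha256()
    alns = sorted(alignments, key=lambda a: a.gene_id)
    for aln in alns:
        digest.update(aln.gene_id.encode())
        for sp, text in aln.rows:
            digest.update(sp.encode())
            digest.update(text.encode())
        all_scored.extend(screen_alignment(aln, cfg, params))
    csms = call_csms(all_scored, cfg)
    csgs = map_csgs(csms, catalog)
    manifest = {
        "config": cfg.to_jsonable(),
        "classifier": params.to_json(),
        "n_genes_in": len(alns),
        "n_windows_scored": len(all_scored),
        "n_csms": len(csms),
        "n_csgs": len(csgs),
        "input_digest": digest.hexdigest(),
    }
    return ScreenResult(all_scored, csms, csgs, manifest)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_windows_tsv(result: ScreenResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tcol_start\tcol_end\tref_start\tref_end\t"
            "z_mean\tsci\tmpi\tn_seq\tp\n"
        )
        for sw in result.windows:
            (rs, re_) = sw.ref_interval
            s = sw.score
            fh.write(
                f"{sw.gene_id}\t{sw.window.col_start}\t{sw.window.col_end}\t"
                f"{rs}\t{re_}\t{s.z_mean:.6f}\t{s.sci:.6f}\t{s.mpi:.6f}\t"
                f"{s.n_seq}\t{s.p:.6f}\n"
            )


def write_csms_bed(result: ScreenResult, catalog: NcRNACatalog, path) -> None:
    """CSMs as BED6 (0-based half-open, score = round(1000 * max_p))."""
    with open(path, "w") as fh:
        for i, csm in enumerate(result.csms):
            rec = catalog[csm.gene_id]
            fh.write(
                f"{rec.chrom}\t{csm.ref_interval[0]}\t{csm.ref_interval[1]}\t"
                f"{csm.gene_id}.csm{i}\t{round(1000 * csm.max_p)}\t{rec.strand}\n"
            )


def write_csgs_tsv(result: ScreenResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_csms\tn_support_species\tsupporting_species\tmax_p\n")
        for g in result.csgs:
            fh.write(
                f"{g.gene_id}\t{len(g.csms)}\t{g.n_support_species}\t"
                f"{','.join(sorted(g.supporting_species))}\t{g.max_p:.6f}\n"
            )


def write_manifest(result: ScreenResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
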