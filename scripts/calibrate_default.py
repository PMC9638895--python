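"""Produce the packaged default window-classifier calibration artifact.

Positives are windows cut from planted-structure families across a range
of divergences; negatives are windows from structureless background
families plus reference-row-shuffled copies of the positives.  The fitted
logistic parameters and the calibration report are written to
src/sporescreen/data/default_classifier.json.

Run from the repository root:  python scripts/calibrate_default.py
"""

import json
from pathlib import Path

from sporescreen import annotation, pipeline, synth
from sporescreen.evaluation import randomize_alignment
from sporescreen.screen import (
    ScreenConfig,
    calibrate_classifier,
    filter_window,
    score_window,
    window_alignment,
)

SEED = 20260922
OUT = Path(__file__).resolve().parent.parent / "src" / "sporescreen" / "data"


def window_features(aln, cfg):
    feats = []
    for win in window_alignment(aln, cfg):
        kept = filter_window(win, cfg)
        if kept is not None:
            feats.append(list(score_window(kept, cfg, params=None).features))
    return feats


def main():
    cfg = ScreenConfig(seed=SEED)
    pos, neg = [], []
    for i, divergence in enumerate((0.05, 0.10, 0.15, 0.20)):
        spec = synth.FamilySpec(
            species_rates={
                "S_cryophilus": divergence,
                "S_octosporus": divergence,
                "S_japonicus": min(1.0, divergence * 1.7),
            },
        )
        ss = synth.generate_screenset(
            n_structured=20,
            n_background=20,
            n_canonical=0,
            spec=spec,
            seed=SEED + i,
            out_dir=Path("scratch") / f"calib_{i}",
        )
        catalog = annotation.parse_genbank_ncrnas(str(ss.genbank_path))
        _, families = pipeline.build_families(catalog, ss.maf_paths)
        alignments = pipeline.build_alignments(families, catalog)
        for gid, aln in alignments.items():
            label = ss.labels.get(gid)
            if label is None:
                continue
            if label.structured:
                pos.extend(window_features(aln, cfg))
                neg.extend(
                    window_features(
                        randomize_alignment(aln, "ref_row", seed=SEED + i), cfg
                    )
                )
            else:
                neg.extend(window_features(aln, cfg))
    params, report = calibrate_classifier(pos, neg, seed=SEED)
    artifact = params.to_json()
    artifact["report"] = report
    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "default_classifier.json", "w") as fh:
        json.dump(artifact, fh, indent=2)
        fh.write("\n")
    print(json.dumps(artifact, indent=2))


if __name__ == "__main__":
    main()
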