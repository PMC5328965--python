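"""Generate the synthetic paired study used throughout the analysis.

Emulates the study design: 25 subjects, two resting-state sessions each
(pre- and post-training), 116 atlas regions, 180 acquired frames at
TR = 2 s, with 20 planted edges whose correlation increases by 0.3 after
training. Writes per-subject/session time-series TSVs, motion traces
with occasional spikes, the pairing manifest, and the ground-truth edge
list under scratch/simulated_study/ (bulky per-subject files stay out of
results/, which holds only summary tables).
"""

from pathlib import Path

import numpy as np

from connmvpa import generate_motion_trace, generate_paired_study
from connmvpa.experiments import draw_random_effect
from connmvpa.io import (
    ManifestRow,
    StudyManifest,
    write_manifest,
    write_motion_txt,
    write_timeseries_tsv,
    write_truth_json,
)

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "scratch" / "simulated_study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    effect = draw_random_effect(n_edges=20, n_regions=116, delta_r=0.3, rng=rng)
    # 180 acquired frames; the pipeline discards the first 5 -> 175 retained
    study = generate_paired_study(
        n_subjects=25, n_regions=116, n_frames=180, tr=2.0, effect=effect,
        seed=SEED,
    )
    rows = []
    for session, store, label in (("pre", study.pre, -1), ("post", study.post, 1)):
        for k, subj in enumerate(study.subjects):
            ts_path = f"{subj}_{session}.tsv"
            write_timeseries_tsv(store[subj], OUT / ts_path)
            motion_path = f"{subj}_{session}_motion.txt"
            spike = (40 + 3 * k,) if k % 5 == 0 else ()
            trace = generate_motion_trace(
                n_frames=180, spike_frames=spike, spike_translation_mm=0.8,
                baseline_sd=0.005, seed=SEED + 100 * k + (label + 1) // 2,
            )
            write_motion_txt(trace, OUT / motion_path)
            rows.append(ManifestRow(subj, session, label, ts_path, motion_path))
    write_manifest(StudyManifest(rows=tuple(rows)), OUT / "manifest.tsv")
    write_truth_json(effect, OUT / "truth.json")
    print(f"planted {effect.n_edges} edges with delta_r = +0.3:")
    print("  " + ", ".join(f"({i},{j})" for i, j in effect.edges))
    print(f"wrote {len(rows)} time-series files + manifest + truth to {OUT}")


if __name__ == "__main__":
    main()
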