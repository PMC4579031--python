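"""Detection-event templates: what the gaze held just before the press.

Locks each detection sample at the fused gaze position 200 ms before the
simulated button press (window -1,000..-200 ms), aligns by gaze
direction, and runs PCA and the rail-diagram line fit on the pooled
samples of both observers.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, SEED, load_trials

from chasescan.pipeline import DETECTION_SPEC, detection_locks, substream
from chasescan.preproc import preprocess
from chasescan.synthgaze import ObserverParams, simulate_observer
from chasescan.templates import extract_samples, fit_lines, pca_templates, rail_diagram

OBSERVERS = {
    "group": ObserverParams(strategy="group", noise_sd=0.1),
    "single": ObserverParams(strategy="single_agent", noise_sd=0.1),
}


def main():
    trials = load_trials()
    locks = []
    for name, op in OBSERVERS.items():
        gazes = [simulate_observer(tr, op, substream(SEED, f"{name}:{k}"))
                 for k, tr in enumerate(trials)]
        fused = [preprocess(g.time, g.left_xy, g.right_xy, tr.n_frames)
                 for g, tr in zip(gazes, trials)]
        locks += detection_locks(gazes, trials, fused, DETECTION_SPEC)
    samples = extract_samples(locks, DETECTION_SPEC)
    if len(samples) < 4:
        raise SystemExit("too few detections; increase N_TRIALS")
    pca = pca_templates(samples, k=min(5, len(samples)))
    rail = rail_diagram(pca.movies[0], t_rel=pca.t_rel, pixel_size=0.25,
                        halfwidth=5.0)
    fit = fit_lines(rail, 2)
    out = {
        "n_samples": len(samples),
        "var_percent": (100 * pca.var_frac).tolist(),
        "lines": [list(l) for l in fit.lines],
        "line_offset_difference": abs(fit.lines[0][0] - fit.lines[1][0]),
        "correlation": fit.correlation,
    }
    (RESULTS / "detection_templates.json").write_text(
        json.dumps(out, indent=1, default=float))
    print(f"{len(samples)} detection samples; "
          f"PC1 explains {out['var_percent'][0]:.1f}% of variance")
    print("two-line fit (p, v, s):",
          [[round(u, 2) for u in l] for l in fit.lines])


if __name__ == "__main__":
    main()
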