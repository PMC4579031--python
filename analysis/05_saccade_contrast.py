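"""SVM classification movies: exploration vs first catch-up saccades.

Builds ES and CS1 samples from the recovered events (saccade target as
positional lock, saccade onset as time lock, -400..+400 ms window,
dominant-direction alignment), renders them at a coarse pixel size, and
trains the linear-SVM contrast with its chance level.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, SEED, load_trials

from chasescan.contrast import train_contrast
from chasescan.events_basic import segment_basic
from chasescan.events_complex import extract_complex, label_saccades
from chasescan.pipeline import substream
from chasescan.preproc import preprocess
from chasescan.synthgaze import ObserverParams, simulate_observer
from chasescan.templates import Lock, SampleSpec, extract_samples, render_sample

SPEC = SampleSpec(lock_kind="saccade_onset", t_lo=-0.4, t_hi=0.4)


def main():
    trials = load_trials()
    op = ObserverParams(strategy="group", noise_sd=0.1)
    es_locks, cs1_locks = [], []
    for k, tr in enumerate(trials):
        lg = simulate_observer(tr, op, substream(SEED, f"group:{k}"))
        fg = preprocess(lg.time, lg.left_xy, lg.right_xy, tr.n_frames)
        evs = segment_basic(fg, tr)
        labels = label_saccades(evs, extract_complex(evs))
        for lab in labels:
            sac = lab.saccade
            end = min(sac.end, tr.n_frames - 1)
            target = fg.xy[end]
            if not np.all(np.isfinite(target)):
                continue
            lock = Lock(traj=tr, frame=sac.start, pos=np.asarray(target))
            if lab.label == "ES":
                es_locks.append(lock)
            elif lab.label == "CS" and lab.cs_order == 1:
                cs1_locks.append(lock)
    es = extract_samples(es_locks, SPEC)
    cs1 = extract_samples(cs1_locks, SPEC)
    print(f"ES samples: {len(es)}, CS1 samples: {len(cs1)}")
    render = lambda ss: [render_sample(s, pixel_size=0.5) for s in ss]
    res = train_contrast(render(es), render(cs1), folds=5, seed=SEED)
    out = {"n_ES": len(es), "n_CS1": len(cs1),
           "cv_accuracy": res.cv_accuracy,
           "chance_accuracy": res.chance_accuracy,
           "best_C": res.best_C}
    (RESULTS / "contrast.json").write_text(json.dumps(out, indent=1))
    print(f"cross-validated accuracy {res.cv_accuracy:.1f}% "
          f"(chance {res.chance_accuracy:.1f}%)")


if __name__ == "__main__":
    main()
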