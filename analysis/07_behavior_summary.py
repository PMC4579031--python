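"""Detection-time and accuracy summaries of the synthetic observers.

Log-normal fits of the detection times (per observer and condition),
Bernoulli detection rates with bootstrap intervals, and the rolling
ten-trial accuracy the experiment fed back to its subjects.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, SEED

from chasescan.behavior import fit_bernoulli, fit_lognormal, rolling_accuracy


def main():
    path = RESULTS / "behavior.csv"
    if not path.exists():
        raise SystemExit("run analysis/02_synthetic_observers.py first")
    df = pd.read_csv(path)
    out = {}
    for (obs, cond), grp in df.groupby(["observer", "condition"]):
        entry = {"n": len(grp),
                 "detection_rate": fit_bernoulli(grp.correct, seed=SEED)}
        times = grp.loc[grp.correct & grp.time_s.notna(), "time_s"]
        if len(times) >= 2:
            fit = fit_lognormal(times, seed=SEED)
            entry["mean_detection_time_s"] = fit.mean_time
            entry["mean_detection_time_ci"] = list(fit.ci)
        out[f"{obs}/{cond}"] = entry
    for obs, grp in df.groupby("observer"):
        out.setdefault("rolling_accuracy", {})[obs] = rolling_accuracy(
            grp.sort_values("trial").correct.to_numpy()).tolist()
    (RESULTS / "behavior_summary.json").write_text(
        json.dumps(out, indent=1, default=float))
    for key, entry in out.items():
        if key == "rolling_accuracy":
            continue
        t = entry.get("mean_detection_time_s")
        print(f"{key}: rate {entry['detection_rate']['rate']:.2f}"
              + (f", mean time {t:.1f} s" if t else ""))


if __name__ == "__main__":
    main()
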