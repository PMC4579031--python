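"""Shared paths and settings for the numbered analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
TRAJ_DIR = RESULTS / "trajectories"

SEED = 11
N_TRIALS = 20          # 18 DC / 2 NC at the 36:4 design ratio


def load_trials():
    from chasescan import fileio
    paths = sorted(TRAJ_DIR.glob("trial*.txt"))
    if not paths:
        raise SystemExit("run analysis/01_simulate_stimuli.py first")
    return [fileio.read_trajectory(p) for p in paths]
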