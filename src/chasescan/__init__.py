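"""chasescan: chase-detection stimuli, gaze events, and spatiotemporal template analyses.

The package simulates chasing displays (one heat-seeking chaser pursuing a
randomly moving chasee among random distractors), generates synthetic
binocular gaze recordings of an observer searching such displays, segments
gaze into oculomotor events (fixations, saccades, slow/fast smooth movement,
pursuit, exploration), and runs template analyses -- PCA movies, averaged
templates, rail diagrams, line fits, SVM classification movies and an
ideal-observer analysis -- that characterise the motion patterns each event
class targets.
"""

from chasescan.stimulus import (
    StimulusParams,
    TrialTrajectory,
    generate_trial,
    generate_batch,
    step_direction,
    chaser_heading,
    reflect_off_wall,
    nearest_neighbor_stats,
)
from chasescan.synthgaze import ObserverParams, LabeledGaze, simulate_observer, density_saccade_target
from chasescan.preproc import FusedGaze, smooth_axis, fill_gaps, fuse_eyes, derive_kinematics, preprocess
from chasescan.events_basic import EventThresholds, BasicEvent, segment_basic, fsm_agent_check, focus_set_slow
from chasescan.events_complex import (
    ComplexEvent,
    SaccadeLabel,
    extract_complex,
    label_saccades,
    compare_streams,
)
from chasescan.templates import (
    SampleSpec,
    TemplateMovie,
    LineFitResult,
    dominant_direction,
    extract_samples,
    render_movie,
    npr_template,
    pca_templates,
    rail_diagram,
    fit_lines,
)
from chasescan.contrast import ContrastResult, chance_level, train_contrast
from chasescan.ideal import io_samples, io_analysis
from chasescan.behavior import LogNormalFit, fit_lognormal, fit_bernoulli, rolling_accuracy

__version__ = "0.1.0"

__all__ = [
    "StimulusParams", "TrialTrajectory", "generate_trial", "generate_batch",
    "step_direction", "chaser_heading", "reflect_off_wall", "nearest_neighbor_stats",
    "ObserverParams", "LabeledGaze", "simulate_observer", "density_saccade_target",
    "FusedGaze", "smooth_axis", "fill_gaps", "fuse_eyes", "derive_kinematics", "preprocess",
    "EventThresholds", "BasicEvent", "segment_basic", "fsm_agent_check", "focus_set_slow",
    "ComplexEvent", "SaccadeLabel", "extract_complex", "label_saccades", "compare_streams",
    "SampleSpec", "TemplateMovie", "LineFitResult", "dominant_direction", "extract_samples",
    "render_movie", "npr_template", "pca_templates", "rail_diagram", "fit_lines",
    "ContrastResult", "chance_level", "train_contrast",
    "io_samples", "io_analysis",
    "LogNormalFit", "fit_lognormal", "fit_bernoulli", "rolling_accuracy",
]
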