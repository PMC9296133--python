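import numpy as np
import pytest

from nedyn import importdyn, synth


@pytest.fixture(scope="session")
def import_roundtrip():
    """Zero-noise embryo time lapse and the trace recovered from it.

    Import kinetics: k_in = 0.02/s, plateau factor 3, 60 frames at 20 s —
    the closed-form truth table comes straight from the generator.
    """
    params = synth.SynthImportParams(noise_sd=0.0, n_frames=60)
    stack, truth = synth.gen_embryo_timelapse(params)
    cyto, bg = synth.default_boxes(params)
    trace = importdyn.import_trace(
        stack, "reporter", "chromatin", ("anaphase_onset", 0), cyto, bg)
    return params, stack, truth, trace


@pytest.fixture(scope="session")
def delayed_import_trace():
    """Noisy (2% of cytoplasm) time lapse with import starting at frame 10."""
    params = synth.SynthImportParams(noise_sd=2.0, n_frames=40,
                                     import_start_s=200.0, seed=11)
    stack, truth = synth.gen_embryo_timelapse(params)
    cyto, bg = synth.default_boxes(params)
    trace = importdyn.import_trace(
        stack, "reporter", "chromatin", ("anaphase_onset", 0), cyto, bg)
    return params, truth, trace
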