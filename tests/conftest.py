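"""Shared fixtures: expensive simulated volumes are built once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from pvocta.angio import compute_angiography
from pvocta.phantom import Saccade, make_preset_phantom, simulate_volume
from pvocta.reconstruct import reconstruct_volume


def measure_fwhm_px(profile: np.ndarray, min_index: int = 100) -> float:
    """Half-maximum width of the dominant peak beyond ``min_index``
    (skipping the DC lobe at zero path difference), with linear
    interpolation of the crossings."""
    p = np.abs(np.asarray(profile)).astype(float)
    p[:min_index] = 0.0
    i = int(np.argmax(p))
    h = p[i] / 2.0
    lo = i
    while lo > 0 and p[lo] > h:
        lo -= 1
    hi = i
    while hi < p.size - 1 and p[hi] > h:
        hi += 1
    lx = lo + (h - p[lo]) / (p[lo + 1] - p[lo]) if p[lo + 1] != p[lo] else lo
    rx = hi - 1 + (p[hi - 1] - h) / (p[hi - 1] - p[hi]) \
        if p[hi - 1] != p[hi] else hi
    return rx - lx


@pytest.fixture(scope="session")
def mirror_chirped():
    """Mirror phantom with injected sweep nonlinearity and dispersion."""
    spec, source, protocol = make_preset_phantom("mirror")
    source = dataclasses.replace(source, chirp2=0.25, chirp3=0.1,
                                 dispersion_a2=25.0, dispersion_a3=5.0)
    raw, truth = simulate_volume(spec, source, protocol, seed=1)
    return {"spec": spec, "source": source, "protocol": protocol,
            "raw": raw, "truth": truth}


@pytest.fixture(scope="session")
def retina_run():
    """retina_small with three injected saccades, processed to angio."""
    spec, source, protocol = make_preset_phantom("retina_small")
    spec.saccades = [Saccade(10), Saccade(33), Saccade(50)]
    raw, truth = simulate_volume(spec, source, protocol, seed=11)
    cv = reconstruct_volume(raw)
    av = compute_angiography(cv)
    return {"spec": spec, "source": source, "protocol": protocol,
            "raw": raw, "truth": truth, "cv": cv, "av": av}


@pytest.fixture(scope="session")
def retina_clean_run():
    """retina_small without saccades, with corrected and uncorrected
    angiography passes."""
    spec, source, protocol = make_preset_phantom("retina_small")
    raw, truth = simulate_volume(spec, source, protocol, seed=12)
    cv = reconstruct_volume(raw)
    av = compute_angiography(cv)
    av_nc = compute_angiography(cv, correct_bulk=False)
    return {"spec": spec, "source": source, "protocol": protocol,
            "raw": raw, "truth": truth, "cv": cv, "av": av, "av_nc": av_nc}


@pytest.fixture(scope="session")
def flowbar_run():
    """flow_bar phantom processed to angio."""
    spec, source, protocol = make_preset_phantom("flow_bar")
    raw, truth = simulate_volume(spec, source, protocol, seed=7)
    cv = reconstruct_volume(raw)
    av = compute_angiography(cv)
    return {"spec": spec, "source": source, "protocol": protocol,
            "raw": raw, "truth": truth, "cv": cv, "av": av}
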