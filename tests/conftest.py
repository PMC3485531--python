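import numpy as np
import pytest

from dyssync.curves import SEGMENT_NAMES, EndSystoleTable, SegmentalCurveSet, TimeVolumeCurve
from dyssync.metrics import DyssynchronyReport
from dyssync.synth import RAISED_COSINE, SegmentParams, StudyParams, make_study


@pytest.fixture
def study_factory():
    """Build a 16-segment synthetic study from per-segment delays/amplitudes."""

    def build(
        delays,
        amplitudes=None,
        v_min=8.0,
        noise_sd=0.0,
        reference_es_time=40.0,
        n_samples=201,
        seed=0,
        waveform=RAISED_COSINE,
    ):
        delays = np.asarray(delays, dtype=float)
        assert delays.size == 16
        amps = np.full(16, 2.5) if amplitudes is None else np.asarray(amplitudes, dtype=float)
        segs = tuple(
            SegmentParams(
                v_min=v_min,
                amplitude=float(a),
                delay=float(d),
                noise_sd=noise_sd,
                waveform=waveform,
            )
            for a, d in zip(amps, delays)
        )
        return make_study(
            StudyParams(
                segments=segs,
                reference_es_time=reference_es_time,
                n_samples=n_samples,
                seed=seed,
            )
        )

    return build


@pytest.fixture
def set_from_volumes():
    """Build a SegmentalCurveSet from a shared grid and 16 volume arrays."""

    def build(times, volume_rows, study_id="hand"):
        times = np.asarray(times, dtype=float)
        segments = {
            name: TimeVolumeCurve(times, np.asarray(v, dtype=float), name)
            for name, v in zip(SEGMENT_NAMES, volume_rows)
        }
        return SegmentalCurveSet(segments, study_id=study_id)

    return build


def fake_report(study_id="p", **overrides):
    """Minimal DyssynchronyReport carrying only the scalar metrics, for
    cohort-statistics tests that do not need curves."""
    values = dict(
        edv=180.0, esv=150.0, ef=16.7, sdi=8.0, le=30.0,
        pre_stv=20.0, post_stv=5.0, total_stv=25.0,
    )
    values.update(overrides)
    return DyssynchronyReport(
        study_id=study_id,
        entries=(),
        es_table=EndSystoleTable(40.0, values["esv"], {}, {}),
        **values,
    )
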