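"""End-to-end extraction: recording -> filtered channels -> fiducials ->
selected beats -> per-subject mean indices.

This is the glue the command-line interface and the validation tests
share. Each subject is processed independently; subjects with no
qualifying beats raise and are reported as exclusions by the caller.
"""

from __future__ import annotations

import numpy as np

from . import delineate as dl
from . import indices as ix
from . import preprocess as pp

__all__ = ["extract_subject"]


def extract_subject(
    recording: pp.SyncRecording,
    subject_id: str = "S0000",
    group: str = "control",
    n_required: int = 30,
    phase_tolerance: float = pp.DEFAULT_PHASE_TOLERANCE,
    amp_variation_max: float = pp.AMP_VARIATION_MAX,
    snr_min_db: float = pp.SNR_MIN_DB,
    demographics: dict | None = None,
) -> ix.SubjectRecord:
    """Run the full pipeline on one synchronized recording.

    Filters both channels, rejects artifact windows, delineates all
    fiducials, gates beats to end-expiration, selects the earliest run of
    ``n_required`` consecutive clean beats, and averages the per-beat
    indices. Raises ``ValueError`` if no beat qualifies.
    """
    ecg_f = pp.bandpass_ecg(recording.ecg, recording.ecg_fs)
    pcg_f = pp.bandpass_pcg(recording.pcg, recording.pcg_fs)
    filtered = pp.SyncRecording(
        ecg=ecg_f,
        pcg=pcg_f,
        ecg_fs=recording.ecg_fs,
        pcg_fs=recording.pcg_fs,
        resp_phase=recording.resp_phase,
    )
    mask = pp.detect_artifacts(
        filtered,
        amp_variation_max=amp_variation_max,
        snr_min_db=snr_min_db,
        prefiltered=True,
    )
    ann = dl.delineate_recording(ecg_f, pcg_f, recording.ecg_fs, recording.pcg_fs)
    if ann.empty:
        raise ValueError(f"{subject_id}: no beats detected")
    resp_flags = pp.respiratory_gate(
        filtered, ann["r_peak_ms"].to_numpy(), phase_tolerance=phase_tolerance
    )
    selected = dl.select_beats(ann, mask, resp_flags, n_required=n_required)
    beats = []
    for _, row in selected.iterrows():
        try:
            beats.append(ix.beat_indices(row))
        except ValueError:
            continue
    return ix.subject_summary(
        beats, subject_id=subject_id, group=group, demographics=demographics
    )
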