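"""The five acoustic-electrocardiographic timing indices.

Per beat:

* S2 splitting (ms) = P2 peak - A2 peak,
* S1-S2 (ms) = S2 (A2) peak - S1 peak,
* S1-S2/RR (%) = S1-S2 / RR x 100,
* EMAT (ms) = Q onset (ECG) - first S1 peak (PCG),
* EMAT/RR (%) = EMAT / RR x 100.

Ratios are computed per beat and then averaged over the selected beats
(mean of ratios, not ratio of means), matching the per-beat derivation
of the acquisition protocol. RR is the beat's own interval, current R to
next R (configurable upstream by how ``rr_ms`` is populated).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["BeatIndices", "SubjectRecord", "beat_indices", "subject_summary",
           "subjects_to_table"]

INDEX_NAMES = ["s2_split_ms", "s1s2_ms", "s1s2_rr_pct", "emat_ms", "emat_rr_pct"]


@dataclass
class BeatIndices:
    s2_split_ms: float
    s1s2_ms: float
    s1s2_rr_pct: float
    emat_ms: float
    emat_rr_pct: float

    def __post_init__(self):
        vals = asdict(self)
        if not all(np.isfinite(v) for v in vals.values()):
            raise ValueError("indices must be finite")
        if self.s2_split_ms < 0:
            raise ValueError("s2_split_ms must be >= 0")
        for name in ("s1s2_rr_pct", "emat_rr_pct"):
            v = vals[name]
            if not 0 < v < 100:
                raise ValueError(f"{name}={v} outside (0, 100)")


@dataclass
class SubjectRecord:
    """Per-subject mean indices with group label and demographics."""

    subject_id: str
    group: str
    indices: BeatIndices
    n_valid_beats: int
    demographics: dict | None = None
    asd_size_mm: float | None = None
    rvedvi_ml_m2: float | None = None

    def __post_init__(self):
        if self.group not in ("ASD", "control"):
            raise ValueError("group must be 'ASD' or 'control'")
        if self.n_valid_beats < 1:
            raise ValueError("need at least one valid beat")


def beat_indices(annotation) -> BeatIndices:
    """Compute the five indices for one annotated beat.

    ``annotation`` is any mapping or object with fields ``q_onset_ms``,
    ``s1_peak_ms``, ``a2_peak_ms``, ``p2_peak_ms`` and ``rr_ms``.
    """
    get = (
        annotation.get
        if hasattr(annotation, "get")
        else lambda k, d=None: getattr(annotation, k, d)
    )
    rr = get("rr_ms")
    if rr is None or not np.isfinite(rr) or rr <= 0:
        raise ValueError("rr_ms must be positive")
    needed = {k: get(k) for k in ("q_onset_ms", "s1_peak_ms", "a2_peak_ms", "p2_peak_ms")}
    for k, v in needed.items():
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing fiducial {k}")
    split = needed["p2_peak_ms"] - needed["a2_peak_ms"]
    s1s2 = needed["a2_peak_ms"] - needed["s1_peak_ms"]
    emat = needed["s1_peak_ms"] - needed["q_onset_ms"]
    return BeatIndices(
        s2_split_ms=split,
        s1s2_ms=s1s2,
        s1s2_rr_pct=s1s2 / rr * 100.0,
        emat_ms=emat,
        emat_rr_pct=emat / rr * 100.0,
    )


def subject_summary(
    beat_indices_list,
    subject_id: str = "S0000",
    group: str = "control",
    demographics: dict | None = None,
    asd_size_mm: float | None = None,
    rvedvi_ml_m2: float | None = None,
) -> SubjectRecord:
    """Arithmetic mean of each index over the valid beats of one subject."""
    items = list(beat_indices_list)
    if not items:
        raise ValueError("no valid beats to summarize")
    means = {
        name: float(np.mean([getattr(b, name) for b in items])) for name in INDEX_NAMES
    }
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        indices=BeatIndices(**means),
        n_valid_beats=len(items),
        demographics=demographics,
        asd_size_mm=asd_size_mm,
        rvedvi_ml_m2=rvedvi_ml_m2,
    )


def subjects_to_table(records) -> pd.DataFrame:
    """Subject records -> cohort table (one row per subject)."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group,
               "n_valid_beats": r.n_valid_beats}
        row.update(asdict(r.indices))
        if r.demographics:
            row.update(r.demographics)
        if r.asd_size_mm is not None:
            row["asd_size_mm"] = r.asd_size_mm
        if r.rvedvi_ml_m2 is not None:
            row["rvedvi_ml_m2"] = r.rvedvi_ml_m2
        rows.append(row)
    return pd.DataFrame(rows)
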